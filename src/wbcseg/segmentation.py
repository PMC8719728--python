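"""From enhancement map to leukocyte count.

Binarization of the rescaled ``|omega|`` map, deletion of small objects,
separation of overlapping nuclei by erasing gradient/chromatic border
pixels inside large components, and 8-connected component counting.

Thresholds follow the reference operating point: ``delta_omega = 37`` on
the [0, 255]-rescaled map, ``delta_I = 0.2`` on the [0, 1]-normalized map
(Prewitt gradient), ``delta_theta = 2.5`` degrees for the angular
difference of adjacent unit color vectors, and the area cutoffs 3500 /
13,000 px (small images, 1368x1712) or 5000 / 21,000 px (large images,
1944x2592), optionally auto-scaled with image area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .hue_pca import DegenerateModelError, ProjectionMap, enhance

# classical (unnormalized) Prewitt derivative masks
_PREWITT_X = np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]], dtype=np.float64)
_PREWITT_Y = _PREWITT_X.T


@dataclass
class SegmentationConfig:
    """Operating point of the counting pipeline.

    ``min_area_px``/``split_area_px`` are expressed at ``reference_area_px``
    (default: the 1368x1712 small-image preset) and, when ``autoscale_area``
    is on, scaled linearly with the processed image's pixel count.
    """

    space: str = "lab"
    delta_omega: float = 37.0           # on |omega| rescaled to [0, 255]
    delta_I: float = 0.2                # Prewitt gradient, omega in [0, 1]
    delta_theta_deg: float = 2.5        # angular difference threshold
    min_area_px: int = 3500             # delete objects smaller than this
    split_area_px: int = 13_000         # separate objects larger than this
    reference_area_px: int = 1368 * 1712
    autoscale_area: bool = True
    separate: bool = True               # overlap separation stage on/off
    border_combine: str = "and"         # Eq-8 condition combination
    delta_lambda: float | None = None   # override of the axis-selection rule
    connectivity: int = 2               # skimage connectivity; 2 = 8-connected

    def __post_init__(self) -> None:
        if self.delta_omega <= 0 or self.delta_I <= 0 or self.delta_theta_deg <= 0:
            raise ValueError("all thresholds must be positive")
        if self.min_area_px >= self.split_area_px:
            raise ValueError("min_area_px must be below split_area_px")
        if self.border_combine not in ("and", "or"):
            raise ValueError("border_combine must be 'and' or 'or'")

    def scaled_areas(self, image_shape: tuple[int, int]) -> tuple[int, int]:
        """Effective (min_area, split_area) for an image of the given shape."""
        if not self.autoscale_area:
            return self.min_area_px, self.split_area_px
        factor = (image_shape[0] * image_shape[1]) / self.reference_area_px
        return (int(round(self.min_area_px * factor)),
                int(round(self.split_area_px * factor)))


PRESETS: dict[str, SegmentationConfig] = {
    "allidb-small": SegmentationConfig(
        min_area_px=3500, split_area_px=13_000,
        reference_area_px=1368 * 1712, autoscale_area=False),
    "allidb-large": SegmentationConfig(
        min_area_px=5000, split_area_px=21_000,
        reference_area_px=1944 * 2592, autoscale_area=False),
}


@dataclass
class SegmentationResult:
    """Final mask plus every retrievable intermediate of the pipeline."""

    labels: np.ndarray              # (H, W) int, 0 = background
    count: int
    pmap: ProjectionMap
    binary_raw: np.ndarray          # after thresholding
    binary_clean: np.ndarray        # after small-object removal
    borders: np.ndarray             # detected border pixels

    @property
    def binary(self) -> np.ndarray:
        return self.labels > 0


def _relabel(binary: np.ndarray, connectivity: int = 2) -> np.ndarray:
    return measure.label(binary, connectivity=connectivity)


def binarize(pmap: ProjectionMap | np.ndarray, delta_omega: float = 37.0) -> np.ndarray:
    """Threshold the rescaled ``|omega|`` map: foreground iff value >= threshold."""
    rescaled = pmap.omega_rescaled if isinstance(pmap, ProjectionMap) else np.asarray(pmap)
    return rescaled >= delta_omega


def remove_small(mask: np.ndarray, min_area_px: int, connectivity: int = 2) -> np.ndarray:
    """Delete components strictly smaller than ``min_area_px`` (area ==
    cutoff survives)."""
    mask = np.asarray(mask, dtype=bool)
    labels = _relabel(mask, connectivity)
    if labels.max() == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area_px
    keep[0] = False
    return keep[labels]


def detect_borders(pmap: ProjectionMap, phi_hat: np.ndarray | None = None,
                   delta_I: float = 0.2, delta_theta_deg: float = 2.5,
                   combine: str = "and") -> np.ndarray:
    """Border pixels from the intensity gradient and chromatic differences.

    A pixel is a border where the Prewitt gradient magnitude of the
    [0, 1]-normalized ``omega`` map exceeds ``delta_I`` and the angles
    between its unit color vector and the next pixel's, both down a row
    (theta_x) and along a column (theta_y), exceed ``delta_theta``.  The
    last row/column reuse the clamped neighbor (angle 0 there).  Dot
    products are clipped to [-1, 1] before arccos to absorb rounding.
    """
    if phi_hat is None:
        phi_hat = pmap.phi_hat
    if phi_hat is None:
        raise ValueError("phi_hat field required for border detection")
    omega01 = pmap.omega_rescaled / 255.0
    gx = ndimage.convolve(omega01, _PREWITT_X, mode="reflect")
    gy = ndimage.convolve(omega01, _PREWITT_Y, mode="reflect")
    grad = np.hypot(gx, gy)

    theta_x = np.zeros(omega01.shape)
    theta_y = np.zeros(omega01.shape)
    dot_x = np.sum(phi_hat[:-1, :, :] * phi_hat[1:, :, :], axis=-1)
    dot_y = np.sum(phi_hat[:, :-1, :] * phi_hat[:, 1:, :], axis=-1)
    # zero vectors (norm 0) give dot 0 -> would fake a 90 deg angle; treat as 0
    zx = (np.linalg.norm(phi_hat[:-1], axis=-1) == 0) | \
         (np.linalg.norm(phi_hat[1:], axis=-1) == 0)
    zy = (np.linalg.norm(phi_hat[:, :-1], axis=-1) == 0) | \
         (np.linalg.norm(phi_hat[:, 1:], axis=-1) == 0)
    theta_x[:-1, :] = np.where(zx, 0.0, np.arccos(np.clip(dot_x, -1.0, 1.0)))
    theta_y[:, :-1] = np.where(zy, 0.0, np.arccos(np.clip(dot_y, -1.0, 1.0)))

    delta_theta = np.deg2rad(delta_theta_deg)
    conds = (grad > delta_I, theta_x > delta_theta, theta_y > delta_theta)
    if combine == "and":
        return conds[0] & conds[1] & conds[2]
    if combine == "or":
        return conds[0] | conds[1] | conds[2]
    raise ValueError("combine must be 'and' or 'or'")


def separate_overlaps(mask: np.ndarray, borders: np.ndarray,
                      split_area_px: int, connectivity: int = 2,
                      min_fragment_px: int = 0) -> np.ndarray:
    """Erase border pixels inside components larger than ``split_area_px``.

    Components at or below the cutoff pass through untouched.  Because the
    detected border band sits partly inside a cell, erasing it can shave
    thin skin slivers off a component; fragments smaller than
    ``min_fragment_px`` are therefore discarded (the largest fragment of
    each split component is always kept).  Never increases foreground area
    and never decreases component count.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = _relabel(mask, connectivity)
    out = mask.copy()
    for region in measure.regionprops(labels):
        if region.area <= split_area_px:
            continue
        comp = labels == region.label
        erased = comp.copy()
        erased[borders] = False
        pieces = _relabel(erased, connectivity)
        if pieces.max() == 0:       # border covered everything: keep as-is
            continue
        areas = np.bincount(pieces.ravel())
        areas[0] = 0
        keep = areas >= min_fragment_px
        keep[0] = False
        keep[areas.argmax()] = True
        out[comp] = keep[pieces[comp]]
    return out


def count(mask: np.ndarray, connectivity: int = 2) -> int:
    """Number of connected foreground components (8-connected by default)."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return int(_relabel(mask, connectivity).max())
    return int(len(np.unique(mask[mask > 0])))


def counting_precision(detected: np.ndarray, truth: np.ndarray,
                       connectivity: int = 2) -> tuple[float | None, int, int]:
    """Fraction of detected components that correspond to true cells.

    A detected component counts as correct when it is greedily matched
    one-to-one to the ground-truth cell with which its pixel overlap is
    maximal and that overlap covers at least half of the smaller of the
    two objects.  Returns ``(Cp, N, M)`` with ``Cp = N / M * 100``;
    ``Cp`` is None (undefined) when nothing was detected.
    """
    det = np.asarray(detected)
    tru = np.asarray(truth)
    if det.shape != tru.shape:
        raise ValueError("detected and truth masks must share dimensions")
    det_lab = _relabel(det > 0, connectivity) if det.dtype == bool or det.max() <= 1 \
        else det.astype(np.int64)
    tru_lab = tru.astype(np.int64)
    if tru.dtype == bool or (tru_lab.max() <= 1 and tru_lab.min() >= 0):
        tru_lab = _relabel(tru > 0, connectivity)

    m = int(det_lab.max())
    if m == 0:
        return None, 0, 0
    det_areas = np.bincount(det_lab.ravel())
    tru_areas = np.bincount(tru_lab.ravel())
    # overlap counts between every (detected, truth) label pair
    both = (det_lab > 0) & (tru_lab > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        keys = det_lab[both].astype(np.int64) * (tru_lab.max() + 1) + tru_lab[both]
        uniq, cnt = np.unique(keys, return_counts=True)
        for k, c in zip(uniq, cnt):
            pairs[(int(k // (tru_lab.max() + 1)), int(k % (tru_lab.max() + 1)))] = int(c)

    candidates = sorted(pairs.items(), key=lambda kv: kv[1], reverse=True)
    used_det: set[int] = set()
    used_tru: set[int] = set()
    n_correct = 0
    for (d, t), ov in candidates:
        if d in used_det or t in used_tru:
            continue
        smaller = min(det_areas[d], tru_areas[t])
        if ov >= 0.5 * smaller:
            used_det.add(d)
            used_tru.add(t)
            n_correct += 1
    return n_correct / m * 100.0, n_correct, m


def segment_and_count(img: np.ndarray,
                      config: SegmentationConfig | None = None) -> SegmentationResult:
    """Full pipeline: enhance, binarize, clean, separate overlaps, count."""
    if config is None:
        config = SegmentationConfig()
    pmap = enhance(img, config.space, config.delta_lambda)
    min_area, split_area = config.scaled_areas(pmap.omega.shape)
    binary_raw = binarize(pmap, config.delta_omega)
    binary_clean = remove_small(binary_raw, min_area, config.connectivity)
    if config.separate:
        borders = detect_borders(pmap, delta_I=config.delta_I,
                                 delta_theta_deg=config.delta_theta_deg,
                                 combine=config.border_combine)
        separated = separate_overlaps(binary_clean, borders, split_area,
                                      config.connectivity,
                                      min_fragment_px=min_area)
    else:
        borders = np.zeros_like(binary_clean)
        separated = binary_clean
    labels = _relabel(separated, config.connectivity)
    return SegmentationResult(
        labels=labels,
        count=int(labels.max()),
        pmap=pmap,
        binary_raw=binary_raw,
        binary_clean=binary_clean,
        borders=borders,
    )
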