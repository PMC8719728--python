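"""Chromaticity enhancement by cascaded principal component analysis.

The core of the method.  Per-pixel hue 2-vectors (``(a, b)`` in L*a*b* or
``(cos h, sin h)`` in HSV) are projected onto their own principal
components; the projections are substituted back into the mapped image as
its new hue, the result is mapped to RGB and normalized to unit vectors,
and a second 3-D PCA on those unit vectors yields, along a selected axis,
a scalar field ``omega`` in which leukocyte pixels — the chromatic
outliers — have large magnitude.

Eigenvalues are stored in *descending* order (the top component first);
the axis-selection rule operates on variance fractions and is therefore
independent of ordering conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import colorspaces

DELTA_LAMBDA = {"lab": 0.9, "hsv": 0.75, "rgb": 0.75}

_DEGENERATE_TOL = 1e-12


class DegenerateModelError(ValueError):
    """Raised when the chromaticity of an image carries no variance
    (uniform color): there is nothing to segment."""


@dataclass
class EigenModel:
    """Mean, orthonormal basis and variances of a PCA fit.

    ``basis`` columns are unit eigenvectors sorted by descending variance;
    the sign of each is fixed so its largest-magnitude entry is positive,
    which removes eigensolver sign nondeterminism.
    """

    mean: np.ndarray        # (d,)
    basis: np.ndarray       # (d, d), columns = eigenvectors
    variances: np.ndarray   # (d,), descending, >= 0
    degenerate: bool = False

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass
class SubstitutedColorField:
    """RGB vectors after hue substitution (``phi_star``) and their
    unit-normalized counterparts (``phi_hat``); zero vectors stay zero."""

    phi_star: np.ndarray    # (H, W, 3) float
    phi_hat: np.ndarray     # (H, W, 3) float, rows unit norm or zero


@dataclass
class ProjectionMap:
    """Scalar enhancement map ``omega`` plus the provenance needed by the
    later segmentation stages."""

    omega: np.ndarray                 # (H, W) float, mean ~ 0
    selected_axis: int                # 0 = top eigenvector, 1 = second
    phi_hat: np.ndarray | None = None
    hue_model: EigenModel | None = None
    color_model: EigenModel | None = None

    @property
    def omega_rescaled(self) -> np.ndarray:
        """``|omega|`` min-max rescaled to [0, 255].

        The binarization threshold (default 37) is expressed on this
        8-bit-like scale; with unit color vectors the raw ``|omega|`` never
        exceeds 2, so the rescale is what makes the threshold meaningful.
        """
        a = np.abs(self.omega)
        m = a.max()
        if m <= 0:
            return np.zeros_like(a)
        return a * (255.0 / m)


def fit_pca(vectors: np.ndarray) -> EigenModel:
    """Fit a PCA model (population covariance, 1/n) to row vectors.

    Parameters
    ----------
    vectors : (n, d) array
        At least d+1 samples.

    Returns
    -------
    EigenModel
        Degenerate (flagged, identity basis) when the covariance is ~0.
    """
    x = np.asarray(vectors, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (n, d) array of row vectors")
    n, d = x.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} vectors to fit a {d}-D model")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / n
    if np.trace(cov) <= _DEGENERATE_TOL:
        return EigenModel(mean=mean, basis=np.eye(d),
                          variances=np.zeros(d), degenerate=True)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(d):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return EigenModel(mean=mean, basis=evecs, variances=evals)


def project(vectors: np.ndarray, model: EigenModel) -> np.ndarray:
    """Project row vectors to the eigenspace: ``y = basis.T @ (x - mean)``.

    Output has ~zero mean and diagonal sample covariance; a degenerate
    model maps everything to zero.
    """
    x = np.asarray(vectors, dtype=np.float64)
    if x.shape[-1] != model.dim:
        raise ValueError(
            f"dimension mismatch: vectors are {x.shape[-1]}-D, "
            f"model is {model.dim}-D")
    if model.degenerate:
        return np.zeros_like(x)
    return (x - model.mean) @ model.basis


def hue_angle_from_projection(y: np.ndarray) -> np.ndarray:
    """Angle in [0, 2*pi) of 2-vectors via the six-branch piecewise arctangent.

    The quadrant-resolved form used to re-express projected hue vectors as
    HSV hue angles: ``atan(y/x)`` corrected per quadrant, with ``pi/2`` and
    ``3*pi/2`` on the positive/negative y-axis.  The zero vector maps to 0
    (hue undefined; fixed convention).
    """
    v = np.asarray(y, dtype=np.float64)
    x = v[..., 0]
    yy = v[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.arctan(np.where(x != 0, yy / np.where(x != 0, x, 1.0), 0.0))
        t_abs = np.arctan(np.where(x != 0, np.abs(yy / np.where(x != 0, x, 1.0)), 0.0))
    ang = np.select(
        [
            (x > 0) & (yy > 0),
            (x < 0) & (yy > 0),
            (x < 0) & (yy < 0),
            (x > 0) & (yy < 0),
            (x == 0) & (yy > 0),
            (x == 0) & (yy < 0),
            (x > 0) & (yy == 0),
            (x < 0) & (yy == 0),
        ],
        [
            t,                      # Q1: atan(y/x)
            np.pi - t_abs,          # Q2: pi - atan(y/|x|)
            np.pi + t,              # Q3: pi + atan(y/x)
            2 * np.pi - t_abs,      # Q4: 2pi - atan(|y|/x)
            np.full_like(t, np.pi / 2),
            np.full_like(t, 3 * np.pi / 2),
            np.zeros_like(t),       # positive x-axis (not enumerated in the
            np.full_like(t, np.pi), # six branches; atan2 convention)
        ],
        default=0.0,                # origin -> 0, degenerate
    )
    return ang if ang.shape else float(ang)


def extract_hue(img: np.ndarray, space: str) -> np.ndarray:
    """Per-pixel hue 2-vectors ``psi`` for the requested color space.

    lab -> ``(a, b)``; hsv -> ``(cos h, sin h)`` (unit vectors); rgb ->
    the normalized RGB directions centered and reduced to their top two
    principal components (the RGB path has no native 2-D hue; see
    :func:`enhance`, which skips this stage for rgb).
    """
    if space == "lab":
        lab = colorspaces.rgb_to_lab(img)
        return lab[..., 1:3].copy()
    if space == "hsv":
        h = colorspaces.rgb_to_hsv(img)[..., 0]
        return np.stack([np.cos(h), np.sin(h)], axis=-1)
    if space == "rgb":
        phi_hat = _normalize_rows(np.asarray(img, dtype=np.float64))
        flat = phi_hat.reshape(-1, 3)
        model = fit_pca(flat)
        y = project(flat, model)[:, :2]
        return y.reshape(img.shape[:2] + (2,))
    raise ValueError(f"unknown color space {space!r}; expected lab, hsv or rgb")


def _normalize_rows(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, v / np.where(norm > 0, norm, 1.0), 0.0)
    return out


def substitute_hue(mapped_img: np.ndarray, psi_star: np.ndarray,
                   space: str) -> SubstitutedColorField:
    """Replace the hue of a mapped image by projected hue vectors.

    lab: ``(a, b)`` replaced by ``psi_star`` with L kept; hsv: hue angle
    recovered from ``psi_star`` via :func:`hue_angle_from_projection` with
    s, v kept.  The substituted image is mapped to RGB (clamped there) and
    unit-normalized; zero RGB vectors remain zero.
    """
    if space == "lab":
        lab = mapped_img.copy()
        lab[..., 1:3] = psi_star
        rgb = colorspaces.lab_to_rgb(lab, as_uint8=False)
    elif space == "hsv":
        hsv = mapped_img.copy()
        hsv[..., 0] = hue_angle_from_projection(psi_star)
        rgb = colorspaces.hsv_to_rgb(hsv, as_uint8=False)
    else:
        raise ValueError(f"substitute_hue undefined for space {space!r}")
    return SubstitutedColorField(phi_star=rgb, phi_hat=_normalize_rows(rgb))


def select_axis(model: EigenModel, space: str,
                delta_lambda: float | None = None) -> int:
    """Index of the projecting eigenvector.

    The top eigenvector is used when its variance fraction reaches the
    space-dependent threshold (0.9 for L*a*b*, 0.75 for RGB/HSV);
    otherwise the second.
    """
    if model.degenerate:
        raise DegenerateModelError(
            "uniform chromaticity, nothing to segment")
    if delta_lambda is None:
        delta_lambda = DELTA_LAMBDA[space]
    frac = model.variances[0] / model.variances.sum()
    return 0 if frac >= delta_lambda else 1


def enhance(img: np.ndarray, space: str = "lab",
            delta_lambda: float | None = None) -> ProjectionMap:
    """Run the full chromaticity-enhancement cascade on an RGB image.

    Steps: map to the working space, extract hue 2-vectors, PCA-project
    them, substitute the projections back as hue, map to RGB and
    normalize, fit the second (3-D) PCA and project along the selected
    axis.  For ``space='rgb'`` the 2-D hue stage is skipped and the second
    PCA runs directly on the normalized RGB vectors.

    Raises
    ------
    DegenerateModelError
        If the image chromaticity is uniform.
    """
    if space not in ("lab", "hsv", "rgb"):
        raise ValueError(f"unknown color space {space!r}")
    shape = np.asarray(img).shape[:2]
    hue_model: EigenModel | None = None

    if space == "rgb":
        phi = np.asarray(img, dtype=np.float64)
        sub = SubstitutedColorField(phi_star=phi, phi_hat=_normalize_rows(phi))
    else:
        if space == "lab":
            mapped = colorspaces.rgb_to_lab(img)
        else:
            mapped = colorspaces.rgb_to_hsv(img)
        psi = extract_hue(img, space)
        flat = psi.reshape(-1, 2)
        hue_model = fit_pca(flat)
        if hue_model.degenerate:
            raise DegenerateModelError("uniform chromaticity, nothing to segment")
        psi_star = project(flat, hue_model).reshape(psi.shape)
        sub = substitute_hue(mapped, psi_star, space)

    flat_hat = sub.phi_hat.reshape(-1, 3)
    color_model = fit_pca(flat_hat)
    axis = select_axis(color_model, space, delta_lambda)
    v_p = color_model.basis[:, axis]
    omega = (flat_hat - color_model.mean) @ v_p
    return ProjectionMap(
        omega=omega.reshape(shape),
        selected_axis=axis,
        phi_hat=sub.phi_hat,
        hue_model=hue_model,
        color_model=color_model,
    )
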