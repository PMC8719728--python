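"""Seeded generator of blood-smear-like images with exact ground truth.

Emulates stained peripheral-smear appearance: dark purple-violet
leukocyte nuclei (irregular ellipses, per-cell hue/brightness jitter from
variable staining), a field of pale pink red cells with central pallor,
a bright warm background with an illumination gradient, and optional
deliberately fused leukocyte pairs.  The ground-truth label mask is the
exact pre-noise geometric coverage of each nucleus — no anti-aliasing
leaks into it — and overlapping cells keep distinct ids (the later cell
overwrites the earlier one where they intersect, as the upper cell does
optically).

Fused pairs are rendered with the optics of real overlaps: the two cells
stain slightly differently (hues from opposite halves of the leukocyte
band), the overlap lens accumulates stain (deeper, darker), and a dark
desaturated contact seam runs where the dense periphery of each nucleus
crosses the other.  The seam transmits little light and little color, so
its normalized chromatic direction swings back toward the field average —
exactly the intensity-gradient / chromatic-angle border that the
overlap-separation operator is designed to detect.  Being the darkest
structure, it also carries the largest angular sensor-noise, which keeps
the angular conditions alive where the seam runs parallel to the pixel
grid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from scipy import ndimage

from .colorspaces import hsv_to_rgb

_TWO_PI = 2.0 * np.pi


@dataclass
class SmearSpec:
    """Parameters of one synthetic smear image.

    Hue values are HSV angles in degrees; the leukocyte band (~270-290)
    approximates Giemsa-type nuclear staining, red cells sit in the pale
    pink band (~340-360) and the background is a bright warm tint.
    ``seed`` fully determines the output.
    """

    shape: tuple[int, int] = (1368, 1712)
    n_wbc: int = 6
    wbc_radius_px: tuple[float, float] = (58.0, 4.0)     # mean, sd
    wbc_hue_deg: tuple[float, float] = (280.0, 10.0)     # mean, half-range
    wbc_sat: tuple[float, float] = (0.66, 0.05)
    wbc_val: tuple[float, float] = (0.45, 0.06)
    # stain accumulation where two nuclei overlap: deeper hue, more
    # saturated, darker (two layers of stain)
    overlap_stain: tuple[float, float, float] = (-30.0, 1.0, 0.55)
    # chromatin of two superposed nuclei is strongly heterogeneous: extra
    # per-pixel hue jitter (deg, sd) inside the overlap lens
    overlap_texture_deg: float = 20.0
    # dark contact seam where the dense periphery of one nucleus crosses
    # the other: (hue shift deg, saturation factor, brightness factor,
    # half-width px)
    overlap_seam: tuple[float, float, float, int] = (0.0, 0.20, 0.30, 5)
    rbc_density: float = 0.45         # fraction of area covered by red cells
    rbc_radius_px: tuple[float, float] = (40.0, 5.0)
    rbc_hue_deg: tuple[float, float] = (348.0, 3.0)
    rbc_sat: tuple[float, float] = (0.12, 0.02)
    rbc_val: tuple[float, float] = (0.88, 0.03)
    background_hue_deg: float = 348.0   # stain-tinted, same warm family as RBCs
    background_sat: float = 0.07
    background_val: float = 0.92
    illumination_gradient: float = 0.08   # relative brightness drop across frame
    overlap_pairs: int = 0
    overlap_frac: tuple[float, float] = (0.10, 0.40)     # of the summed radii
    blur_sigma: float = 1.2           # optical point-spread blur, px
    noise_sd: float = 3.5             # 8-bit counts, per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wbc < 0 or self.overlap_pairs < 0:
            raise ValueError("cell counts must be non-negative")
        if 2 * self.overlap_pairs > self.n_wbc:
            raise ValueError("more overlap pairs than cells")


def _outline_params(rng) -> dict:
    """Random shape of a nucleus outline: ellipse aspect/tilt plus a
    low-order radial (lobed) perturbation."""
    return {
        "aspect": rng.uniform(0.75, 1.0),
        "tilt": rng.uniform(0, np.pi),
        "n_lobes": int(rng.integers(2, 5)),
        "amp": rng.uniform(0.04, 0.10),
        "phase": rng.uniform(0, _TWO_PI),
    }


def _irregular_ellipse_mask(shape, cy, cx, r, params):
    """Boolean coverage of a nucleus: exact point-in-region test of an
    ellipse with a lobed radial perturbation (no anti-aliasing)."""
    aspect = params["aspect"]
    tilt = params["tilt"]
    n_lobes = params["n_lobes"]
    amp = params["amp"]
    phase = params["phase"]

    pad = int(np.ceil(r * 1.3)) + 2
    y0, y1 = max(0, int(cy) - pad), min(shape[0], int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(shape[1], int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = (yy - cy).astype(np.float64)
    dx = (xx - cx).astype(np.float64)
    # rotate into ellipse frame
    u = np.cos(tilt) * dx + np.sin(tilt) * dy
    v = -np.sin(tilt) * dx + np.cos(tilt) * dy
    rho = np.hypot(u / 1.0, v / aspect)
    ang = np.arctan2(v, u)
    boundary = r * (1.0 + amp * np.cos(n_lobes * ang + phase))
    local = rho <= boundary
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = local
    return mask


def _place_cells(spec: SmearSpec, rng) -> list[dict]:
    """Choose centers/radii: singles kept disjoint, pairs deliberately fused."""
    h, w = spec.shape
    r_mean, r_sd = spec.wbc_radius_px
    placed: list[dict] = []

    def radius():
        # clip keeps singles above the small-object cutoff and below the
        # overlap-separation cutoff of the matching size preset
        return float(np.clip(rng.normal(r_mean, r_sd),
                             0.78 * r_mean, 1.18 * r_mean))

    def far_enough(cy, cx, r):
        for c in placed:
            if np.hypot(cy - c["cy"], cx - c["cx"]) < 1.35 * (r + c["r"]):
                return False
        return True

    margin = 1.3
    n_single = spec.n_wbc - 2 * spec.overlap_pairs
    for _ in range(spec.overlap_pairs):
        for attempt in range(3000):
            r1, r2 = radius(), radius()
            f = rng.uniform(*spec.overlap_frac)
            d = (1.0 - f) * (r1 + r2)
            ang = rng.uniform(0, _TWO_PI)
            cy1 = rng.uniform(margin * r1, h - margin * r1)
            cx1 = rng.uniform(margin * r1, w - margin * r1)
            cy2 = cy1 + d * np.sin(ang)
            cx2 = cx1 + d * np.cos(ang)
            if not (margin * r2 <= cy2 <= h - margin * r2
                    and margin * r2 <= cx2 <= w - margin * r2):
                continue
            if far_enough(cy1, cx1, r1 + d) and far_enough(cy2, cx2, r2 + d):
                placed.append({"cy": cy1, "cx": cx1, "r": r1, "pair": "low",
                               "outline": _outline_params(rng)})
                placed.append({"cy": cy2, "cx": cx2, "r": r2, "pair": "high",
                               "outline": _outline_params(rng)})
                break
        else:
            raise RuntimeError("could not place fused pair; too many cells for area")
    for _ in range(n_single):
        for attempt in range(3000):
            r = radius()
            cy = rng.uniform(margin * r, h - margin * r)
            cx = rng.uniform(margin * r, w - margin * r)
            if far_enough(cy, cx, r):
                placed.append({"cy": cy, "cx": cx, "r": r, "pair": None,
                               "outline": _outline_params(rng)})
                break
        else:
            raise RuntimeError("could not place cell; too many cells for area")
    return placed


def generate(spec: SmearSpec) -> tuple[np.ndarray, np.ndarray, int]:
    """Render one smear.

    Returns
    -------
    image : (H, W, 3) uint8
    truth : (H, W) int32 label mask, one id per drawn cell (1..n_wbc)
    true_count : int, the number of cells drawn
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape

    hsv = np.zeros((h, w, 3), dtype=np.float64)
    hsv[..., 0] = np.deg2rad(spec.background_hue_deg)
    hsv[..., 1] = spec.background_sat
    # smooth illumination gradient across the frame, random direction
    gdir = rng.uniform(0, _TWO_PI)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (np.cos(gdir) * xx / w + np.sin(gdir) * yy / h)
    ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-9)
    hsv[..., 2] = spec.background_val * (1.0 - spec.illumination_gradient * ramp)

    # red cells: pale pink discs with central pallor, may overlap each other
    area = h * w
    r_rbc, sd_rbc = spec.rbc_radius_px
    n_rbc = int(spec.rbc_density * area / (np.pi * r_rbc ** 2))
    for _ in range(n_rbc):
        r = float(np.clip(rng.normal(r_rbc, sd_rbc), 0.5 * r_rbc, 1.5 * r_rbc))
        cy = rng.uniform(-r, h + r)
        cx = rng.uniform(-r, w + r)
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        if y0 >= y1 or x0 >= x1:
            continue
        gy, gx = np.mgrid[y0:y1, x0:x1]
        rho = np.hypot(gy - cy, gx - cx) / r
        disc = rho <= 1.0
        hue = np.deg2rad(rng.normal(spec.rbc_hue_deg[0], spec.rbc_hue_deg[1])) % _TWO_PI
        sat = max(rng.normal(spec.rbc_sat[0], spec.rbc_sat[1]), 0.02)
        val = np.clip(rng.normal(spec.rbc_val[0], spec.rbc_val[1]), 0.5, 1.0)
        # central pallor: saturation fades toward the disc center
        pallor = np.clip(1.0 - 0.7 * (1.0 - rho) ** 2, 0.0, 1.0)
        sub = hsv[y0:y1, x0:x1]
        sub[..., 0][disc] = hue
        sub[..., 1][disc] = (sat * pallor)[disc]
        sub[..., 2][disc] = val

    # leukocyte nuclei; truth mask is the exact geometric coverage
    truth = np.zeros((h, w), dtype=np.int32)
    cells = _place_cells(spec, rng)
    masks = [_irregular_ellipse_mask((h, w), c["cy"], c["cx"], c["r"],
                                     c["outline"]) for c in cells]
    # guarantee each deliberate pair truly intersects: the lobed outline can
    # shrink the touching radii, so pull the second cell in until it fuses
    for p in range(spec.overlap_pairs):
        a, b = 2 * p, 2 * p + 1
        ca, cb = cells[a], cells[b]
        min_overlap = int(0.02 * np.pi * min(ca["r"], cb["r"]) ** 2)
        for step in range(20):
            if (masks[a] & masks[b]).sum() >= max(min_overlap, 16):
                break
            cb["cy"] = ca["cy"] + 0.93 * (cb["cy"] - ca["cy"])
            cb["cx"] = ca["cx"] + 0.93 * (cb["cx"] - ca["cx"])
            masks[b] = _irregular_ellipse_mask((h, w), cb["cy"], cb["cx"],
                                               cb["r"], cb["outline"])
    hue_mid, hue_half = spec.wbc_hue_deg
    for idx, (cell, mask) in enumerate(zip(cells, masks), start=1):
        if cell["pair"] == "low":       # differential staining within a pair
            hue = rng.uniform(hue_mid - hue_half, hue_mid - 0.5 * hue_half)
            val = spec.wbc_val[0] - 1.2 * spec.wbc_val[1]
        elif cell["pair"] == "high":
            hue = rng.uniform(hue_mid + 0.5 * hue_half, hue_mid + hue_half)
            val = spec.wbc_val[0] + 1.2 * spec.wbc_val[1]
        else:
            hue = rng.uniform(hue_mid - hue_half, hue_mid + hue_half)
            val = rng.normal(spec.wbc_val[0], spec.wbc_val[1])
        sat = np.clip(rng.normal(spec.wbc_sat[0], spec.wbc_sat[1]), 0.3, 0.9)
        val = float(np.clip(val, 0.2, 0.75))
        # chromatin texture: per-pixel brightness speckle plus chromatic
        # granularity (hue/saturation jitter, smoothed later by the PSF blur)
        npx = int(mask.sum())
        tex = 1.0 + 0.05 * rng.standard_normal(npx)
        hue_tex = np.deg2rad(6.0) * rng.standard_normal(npx)
        sat_tex = 0.015 * rng.standard_normal(npx)
        hsv[..., 0][mask] = (np.deg2rad(hue) + hue_tex) % _TWO_PI
        hsv[..., 1][mask] = np.clip(sat + sat_tex, 0.2, 0.95)
        hsv[..., 2][mask] = np.clip(val * tex, 0.1, 0.9)
        truth[mask] = idx

    # stain accumulation in the overlap lens of each fused pair
    hue_shift, sat_f, val_f = spec.overlap_stain
    for p in range(spec.overlap_pairs):
        lens = masks[2 * p] & masks[2 * p + 1]
        jitter = np.deg2rad(spec.overlap_texture_deg) \
            * rng.standard_normal(int(lens.sum()))
        hsv[..., 0][lens] = (hsv[..., 0][lens] + np.deg2rad(hue_shift)
                             + jitter) % _TWO_PI
        hsv[..., 1][lens] = np.clip(hsv[..., 1][lens] * sat_f, 0.0, 0.95)
        hsv[..., 2][lens] = np.clip(hsv[..., 2][lens] * val_f, 0.1, 0.9)
        # dark contact seam: each nucleus's dense rim where it crosses the
        # other cell
        s_hue, s_sat, s_val, s_hw = spec.overlap_seam
        rim = np.zeros_like(lens)
        for m_self, m_other in ((masks[2 * p], masks[2 * p + 1]),
                                (masks[2 * p + 1], masks[2 * p])):
            edge = m_self & ~ndimage.binary_erosion(m_self, iterations=s_hw)
            rim |= edge & ndimage.binary_dilation(m_other, iterations=s_hw)
        rim &= masks[2 * p] | masks[2 * p + 1]
        hsv[..., 0][rim] = (hsv[..., 0][rim] + np.deg2rad(s_hue)) % _TWO_PI
        hsv[..., 1][rim] = np.clip(hsv[..., 1][rim] * s_sat, 0.0, 0.95)
        hsv[..., 2][rim] = np.clip(hsv[..., 2][rim] * s_val, 0.08, 0.9)

    rgb = hsv_to_rgb(hsv, as_uint8=False) * 255.0
    if spec.blur_sigma > 0:   # optical point-spread; masks stay pre-blur exact
        rgb = ndimage.gaussian_filter(rgb, sigma=(spec.blur_sigma,
                                                  spec.blur_sigma, 0))
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)
    img = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return img, truth, len(cells)


def generate_suite(base_spec: SmearSpec, n_images: int, out_dir: str | Path,
                   seed: int = 0,
                   brightness_range: tuple[float, float] = (0.9, 1.05),
                   hue_shift_deg: float = 4.0,
                   scale_range: tuple[float, float] = (0.9, 1.1)) -> Path:
    """Write a dataset of varied smears: images, masks and a manifest CSV.

    Per image the background brightness, staining hue shift and cell
    scale are jittered within the given ranges; everything derives from
    ``seed``.  Layout: ``img_###.png``, ``img_###_mask.png`` and
    ``manifest.csv`` (filename, mask, true count, spec parameters).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_images):
        bright = rng.uniform(*brightness_range)
        shift = rng.uniform(-hue_shift_deg, hue_shift_deg)
        scale = rng.uniform(*scale_range)
        spec = replace(
            base_spec,
            background_val=float(np.clip(base_spec.background_val * bright, 0.5, 0.98)),
            wbc_hue_deg=(base_spec.wbc_hue_deg[0] + shift, base_spec.wbc_hue_deg[1]),
            wbc_radius_px=(base_spec.wbc_radius_px[0] * scale,
                           base_spec.wbc_radius_px[1]),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        img, truth, n = generate(spec)
        name = f"img_{i:03d}.png"
        mask_name = f"img_{i:03d}_mask.png"
        iio.imwrite(out / name, img)
        iio.imwrite(out / mask_name, truth.astype(np.uint8 if n < 256 else np.uint16))
        rows.append({
            "filename": name, "mask": mask_name, "true_count": n,
            "rows": spec.shape[0], "cols": spec.shape[1],
            "n_wbc": spec.n_wbc, "overlap_pairs": spec.overlap_pairs,
            "background_val": round(spec.background_val, 4),
            "wbc_hue_deg": round(spec.wbc_hue_deg[0], 2),
            "wbc_radius_px": round(spec.wbc_radius_px[0], 2),
            "seed": spec.seed,
        })
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()) if rows else
                                ["filename", "mask", "true_count"])
        writer.writeheader()
        writer.writerows(rows)
    return out
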