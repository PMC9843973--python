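"""AFM-IR map corrections, segmentation and log-ratio maps.

Correction chain for a scene (a set of topography / deflection / absorption
maps acquired at a few QCL wavenumbers):

1. topography leveling — robust plane (or higher-order surface) fit plus
   per-scan-line median subtraction,
2. contact-loss repair on absorption maps — dropout pixels replaced by the
   mean of clean neighbours,
3. drift compensation — rigid registration of each wavenumber's topography
   against the fixed wavenumber, transform applied to all three roles,
4. topography rescaling to non-negative µm with a 5th-percentile floor,
5. absorption normalisation by the laser-power background spectrum.

Segmentation then clusters pixels (k-means, k=2) on all maps jointly and the
log10 ratio maps (TAG 1742 / FFA 1708 against the 1600 cm^-1 reference, and
absorption over topography) are computed on the hypha foreground only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from skimage.registration import phase_cross_correlation
from skimage.transform import EuclideanTransform, warp
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .preprocess import SGParams, emsc_fit_correct, savitzky_golay_collection
from .spectral_core import AFMIRMapSet, LaserPowerSpectrum, SpectrumCollection, WavenumberAxis

__all__ = [
    "RigidTransform",
    "PointSpectrumGroup",
    "ThickSampleError",
    "level_topography",
    "repair_contact_loss",
    "register_maps",
    "apply_rigid",
    "rescale_topography",
    "normalize_absorption",
    "correct_mapset",
    "segment_afmir",
    "log_ratio_maps",
    "preprocess_point_spectra",
]

MAD_SCALE = 1.4826
THICK_SAMPLE_LIMIT_UM = 2.0


class ThickSampleError(RuntimeError):
    """Raised for samples too thick in z for reliable AFM-IR contact."""


def _refuse_thick(meta: dict) -> None:
    if meta.get("thick_sample"):
        raise ThickSampleError(
            "sample flagged as too thick in z-direction (> 2-3 um): the AFM tip "
            "tends to lose contact with the probed surface, so AFM-IR maps of "
            "such samples (e.g. yeast-like cells) cannot be processed reliably"
        )


@dataclass
class RigidTransform:
    """In-plane rigid motion: translation (dx right, dy down, px) and CCW
    rotation theta (degrees) about the image centre, applied after rotation."""

    dx: float
    dy: float
    theta: float
    applied: bool = False

    def is_identity(self, tol_px: float = 0.02, tol_deg: float = 0.01) -> bool:
        # transforms below interpolation resolution are treated as identity
        return abs(self.dx) <= tol_px and abs(self.dy) <= tol_px and abs(self.theta) <= tol_deg

    def as_dict(self) -> dict:
        return {"dx": self.dx, "dy": self.dy, "theta_deg": self.theta, "applied": self.applied}


@dataclass
class PointSpectrumGroup:
    """Repeat AFM-IR point spectra from one acquisition point."""

    point_id: str
    repeats: list  # list of 1-D arrays on a shared axis
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        reps = [np.asarray(r, dtype=float) for r in self.repeats]
        if not reps:
            raise ValueError("group needs at least one repeat spectrum")
        for r in reps:
            if r.shape != (len(self.axis),):
                raise ValueError("all repeats must share the group axis")
        self.repeats = reps

    def average(self) -> np.ndarray:
        return np.mean(self.repeats, axis=0)


# ---------------------------------------------------------------------------
# Topography corrections


def _poly_surface_basis(shape: tuple[int, int], order: int) -> np.ndarray:
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols]
    # normalised coordinates for conditioning
    xn = (x / max(cols - 1, 1) * 2 - 1).ravel()
    yn = (y / max(rows - 1, 1) * 2 - 1).ravel()
    cols_ = [xn**i * yn**j for i in range(order + 1) for j in range(order + 1 - i)]
    return np.column_stack(cols_)


def level_topography(topo: np.ndarray, poly_order: int = 1, n_robust: int = 3) -> np.ndarray:
    """Remove scanner background: surface fit then per-line median shifts.

    The polynomial surface (default order 1, a plane) is fitted robustly:
    after each pass, pixels protruding more than 2 scaled MADs above the fit
    (the sample itself) are excluded, so the fit tracks the substrate rather
    than the hyphae sitting on it. Per-scan-line median subtraction then
    removes z-piezo jumps between lines.
    """
    topo = np.asarray(topo, dtype=float)
    if topo.ndim != 2 or min(topo.shape) < 3:
        raise ValueError("topography must be at least 3x3")
    basis = _poly_surface_basis(topo.shape, poly_order)
    if basis.shape[1] >= topo.size:
        raise ValueError(f"polynomial order {poly_order} too high for map size {topo.shape}")
    z = topo.ravel()
    scale_floor = 1e-9 * max(1.0, float(np.abs(z).max()))
    keep = np.ones(z.size, dtype=bool)
    fit = np.zeros_like(z)
    min_keep = max(3 * basis.shape[1], int(0.05 * z.size))
    for _ in range(n_robust + 1):
        coef, *_ = np.linalg.lstsq(basis[keep], z[keep], rcond=None)
        fit = basis @ coef
        resid = z - fit
        med = np.median(resid[keep])
        sigma = max(MAD_SCALE * np.median(np.abs(resid[keep] - med)), scale_floor)
        # one-sided: exclude only protrusions (the sample on the substrate)
        new_keep = resid - med <= 2.0 * sigma
        if new_keep.sum() < min_keep:
            break
        keep = new_keep
    out = (z - fit).reshape(topo.shape)
    # per-line medians over substrate pixels only: a hypha crossing a full
    # scan line must not be subtracted as a height shift
    keep2 = keep.reshape(topo.shape)
    line_med = np.zeros((topo.shape[0], 1))
    for r in range(topo.shape[0]):
        sel = keep2[r]
        # rows fully covered by sample have no substrate reference; leave them
        line_med[r, 0] = np.median(out[r, sel]) if sel.any() else 0.0
    return out - line_med


def rescale_topography(topo: np.ndarray, floor_percentile: float = 5.0) -> np.ndarray:
    """Shift heights non-negative and clamp the lowest tail.

    The minimum is shifted to zero and values below the ``floor_percentile``
    (linear-interpolation convention) are replaced by that percentile, which
    suppresses spurious deep pits from imperfect z-positioning. Input and
    output are in µm.
    """
    topo = np.asarray(topo, dtype=float)
    shifted = topo - topo.min()
    floor = np.percentile(shifted, floor_percentile)
    return np.maximum(shifted, floor)


# ---------------------------------------------------------------------------
# Absorption corrections


def repair_contact_loss(
    absorption: np.ndarray, n_mad: float = 3.0, spread_fraction: float = 0.1
) -> np.ndarray:
    """Repair dropout pixels caused by temporary tip-sample contact loss.

    Contact loss collapses the photothermal signal, so dropouts appear as
    pixels far *below* their local surroundings. Detection runs on the
    residual against a 3x3 median filter (so smooth genuine features such as
    lipid droplets are not flagged): a pixel is a dropout when its residual is
    below -max(n_mad * scaled-MAD of its scan line's residuals,
    spread_fraction * robust map range). Maps with zero residual scale
    (noiseless and feature-free) are returned unchanged. Flagged pixels are
    replaced by the mean of their unflagged 8-neighbours, sweeping until none
    remain.
    """
    a = np.asarray(absorption, dtype=float)
    if a.ndim != 2 or min(a.shape) < 3:
        raise ValueError("absorption map must be at least 3x3")
    detail = a - median_filter(a, size=3, mode="nearest")
    line_sigma = MAD_SCALE * np.median(np.abs(detail), axis=1, keepdims=True)
    spread = float(np.percentile(a, 99) - np.percentile(a, 1))
    threshold = np.maximum(n_mad * line_sigma, spread_fraction * spread)
    threshold = np.where(threshold > 0, threshold, np.inf)
    flags = detail < -threshold
    if np.all(flags.sum(axis=1) == a.shape[1]):
        raise ValueError("an entire scan line is flagged as contact loss; map unusable")
    if flags.all(axis=1).any():
        bad = np.nonzero(flags.all(axis=1))[0]
        raise ValueError(f"entire scan lines flagged as contact loss: rows {bad.tolist()}")
    if not flags.any():
        return a
    out = a.copy()
    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    rows, cols = a.shape
    for _ in range(10):
        if not flags.any():
            break
        acc = np.zeros_like(out)
        cnt = np.zeros_like(out)
        clean = ~flags
        for di, dj in offsets:
            sr = slice(max(di, 0), rows + min(di, 0))
            sc = slice(max(dj, 0), cols + min(dj, 0))
            dr = slice(max(-di, 0), rows + min(-di, 0))
            dc = slice(max(-dj, 0), cols + min(-dj, 0))
            acc[dr, dc] += np.where(clean[sr, sc], out[sr, sc], 0.0)
            cnt[dr, dc] += clean[sr, sc]
        reachable = flags & (cnt > 0)
        out[reachable] = acc[reachable] / cnt[reachable]
        flags = flags & ~reachable
    return out


def normalize_absorption(
    absorption: np.ndarray, wavenumber: float, power: LaserPowerSpectrum
) -> np.ndarray:
    """Divide an absorption map by the QCL power at its wavenumber."""
    p = power.at(wavenumber)
    return np.asarray(absorption, dtype=float) / p


# ---------------------------------------------------------------------------
# Drift registration


def _rigid_tform(shape: tuple[int, int], t: RigidTransform) -> EuclideanTransform:
    center = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])  # (x, y)
    return (
        EuclideanTransform(translation=-center)
        + EuclideanTransform(rotation=np.deg2rad(t.theta))
        + EuclideanTransform(translation=center + np.array([t.dx, t.dy]))
    )


def apply_rigid(
    image: np.ndarray, t: RigidTransform, inverse: bool = False, cval: float = np.nan
) -> np.ndarray:
    """Apply (or undo) a rigid transform with bilinear interpolation.

    Out-of-frame pixels become ``cval`` (NaN by default) so they can be
    excluded from statistics downstream. Identity transforms short-circuit to
    an exact copy.
    """
    image = np.asarray(image, dtype=float)
    if t.is_identity():
        return image.copy()
    tform = _rigid_tform(image.shape, t)
    mapping = tform if inverse else tform.inverse
    # warp's inverse_map goes output -> input: passing tform.inverse applies t forward
    return warp(image, mapping, order=1, cval=cval, preserve_range=True)


def _translation_error(fixed: np.ndarray, moving: np.ndarray) -> tuple[np.ndarray, float]:
    # plain (non-whitened) cross-correlation: robust for smooth AFM maps
    shift, error, _ = phase_cross_correlation(
        fixed, moving, upsample_factor=20, normalization=None
    )
    return shift, float(error)


def register_maps(
    fixed: np.ndarray,
    moving: np.ndarray,
    max_rotation: float = 10.0,
    coarse_step: float = 1.0,
    fine_step: float = 0.25,
) -> RigidTransform:
    """Estimate the rigid motion carrying ``fixed`` onto ``moving``.

    Rotation is found by a coarse-to-fine grid search (each candidate:
    derotate the moving image, score the residual of the FFT cross-correlation
    translation fit) with a final parabolic refinement; translation comes from
    subpixel phase correlation at the best angle. The returned transform is
    such that ``apply_rigid(fixed, t)`` reproduces ``moving`` and
    ``apply_rigid(moving, t, inverse=True)`` undoes the drift.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving maps must share a shape")
    if fixed.std() == 0 or moving.std() == 0:
        raise ValueError("flat image: registration similarity has no unique peak")

    def score(theta: float) -> tuple[float, np.ndarray]:
        derot = apply_rigid(moving, RigidTransform(0.0, 0.0, theta), inverse=True, cval=0.0)
        shift, err = _translation_error(fixed, derot)
        return err, shift

    thetas = np.arange(-max_rotation, max_rotation + coarse_step / 2, coarse_step)
    errs = np.array([score(t)[0] for t in thetas])
    t0 = thetas[int(np.argmin(errs))]
    fine = np.arange(t0 - coarse_step, t0 + coarse_step + fine_step / 2, fine_step)
    fine_errs = np.array([score(t)[0] for t in fine])
    k = int(np.argmin(fine_errs))
    theta = float(fine[k])
    if 0 < k < len(fine) - 1:  # parabolic sub-step refinement
        y0, y1, y2 = fine_errs[k - 1], fine_errs[k], fine_errs[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            theta += float(0.5 * (y0 - y2) / denom) * fine_step

    _, shift = score(theta)
    # cross-correlation yields the residual translation in the derotated frame;
    # rotate it back to get the translation component of the forward transform
    dy_r, dx_r = -shift[0], -shift[1]
    c, s = np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))
    dx = dx_r * c - dy_r * s
    dy = dx_r * s + dy_r * c

    # local intensity-based refinement: minimise the masked, plane-projected
    # SSD between the fixed image and the un-drifted moving image around the
    # correlation seed. Both images are lightly smoothed first so that the
    # shift-dependent noise attenuation of bilinear resampling cannot bias
    # the optimum; frame edges (content cut by the scan window) are excluded,
    # and a residual plane is projected out because independent per-map
    # leveling leaves slightly different background planes.
    from scipy.ndimage import binary_erosion, gaussian_filter
    from scipy.optimize import minimize

    smooth_sigma = 1.0
    fixed_s = gaussian_filter(fixed, smooth_sigma)
    margin = int(np.ceil(max(abs(dx), abs(dy)))) + 2
    interior = np.zeros_like(fixed, dtype=bool)
    interior[margin:-margin or None, margin:-margin or None] = True
    yy, xx = np.mgrid[0 : fixed.shape[0], 0 : fixed.shape[1]].astype(float)
    plane_basis = np.column_stack(
        [np.ones(fixed.size), xx.ravel() / fixed.shape[1], yy.ravel() / fixed.shape[0]]
    )

    def ssd(p: np.ndarray) -> float:
        undone = apply_rigid(moving, RigidTransform(p[0], p[1], p[2]), inverse=True)
        valid = binary_erosion(~np.isnan(undone), iterations=3) & interior
        if valid.sum() < 0.25 * fixed.size:
            return np.inf
        r = gaussian_filter(np.nan_to_num(undone, nan=0.0), smooth_sigma)[valid] - fixed_s[valid]
        B = plane_basis[valid.ravel()]
        coef, *_ = np.linalg.lstsq(B, r, rcond=None)
        r = r - B @ coef
        return float(np.mean(r * r))

    res = minimize(
        ssd,
        np.array([dx, dy, theta]),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-14, "maxiter": 500},
    )
    if res.fun < ssd(np.array([dx, dy, theta])):
        dx, dy, theta = res.x
    return RigidTransform(float(dx), float(dy), float(theta))


# ---------------------------------------------------------------------------
# Full chain


def correct_mapset(
    mapset: AFMIRMapSet,
    fixed_wavenumber: float = 1600.0,
    level_order: int = 1,
    max_rotation: float = 10.0,
) -> tuple[AFMIRMapSet, dict[float, RigidTransform]]:
    """Run the full correction chain on a scene.

    Returns the corrected set (topography leveled + rescaled to µm,
    absorption repaired + normalised, all wavenumbers registered to the fixed
    one) and the estimated per-wavenumber drift transforms.
    """
    _refuse_thick(mapset.meta)
    if float(fixed_wavenumber) not in [float(w) for w in mapset.wavenumbers]:
        raise ValueError(f"fixed wavenumber {fixed_wavenumber} not acquired {mapset.wavenumbers}")

    leveled: dict[float, dict[str, np.ndarray]] = {}
    for w in mapset.wavenumbers:
        topo = mapset.get(w, "topography")
        if mapset.meta.get("height_units", "um") == "nm":
            topo = topo / 1000.0
        leveled[w] = {
            "topography": level_topography(topo, poly_order=level_order),
            "deflection": mapset.get(w, "deflection").copy(),
            "absorption": repair_contact_loss(mapset.get(w, "absorption")),
        }

    transforms: dict[float, RigidTransform] = {}
    out: dict[float, dict[str, np.ndarray]] = {}
    fixed_topo = leveled[float(fixed_wavenumber)]["topography"]
    for w in mapset.wavenumbers:
        if w == float(fixed_wavenumber):
            t = RigidTransform(0.0, 0.0, 0.0)
        else:
            t = register_maps(fixed_topo, leveled[w]["topography"], max_rotation=max_rotation)
        t.applied = not t.is_identity()
        transforms[w] = t
        entry = {}
        for role in ("topography", "deflection", "absorption"):
            entry[role] = apply_rigid(leveled[w][role], t, inverse=True)
        entry["topography"] = rescale_topography(np.nan_to_num(entry["topography"], nan=0.0))
        oof = np.isnan(entry["absorption"]) | np.isnan(entry["deflection"])
        entry["absorption"] = normalize_absorption(
            np.nan_to_num(entry["absorption"], nan=0.0), w, mapset.laser_power
        )
        entry["absorption"][oof] = np.nan
        entry["deflection"] = np.nan_to_num(entry["deflection"], nan=0.0)
        entry["absorption"] = np.nan_to_num(entry["absorption"], nan=np.nan)  # keep NaN marker
        out[w] = entry

    # NaN markers are not storable in the validated container; keep a shared
    # validity mask in meta and zero the marked pixels.
    valid = np.ones(mapset.shape, dtype=bool)
    for w in mapset.wavenumbers:
        valid &= ~np.isnan(out[w]["absorption"])
    for w in mapset.wavenumbers:
        out[w]["absorption"] = np.where(valid, out[w]["absorption"], 0.0)
    meta = {**mapset.meta, "corrected": True}
    corrected = AFMIRMapSet(out, mapset.scan_size, mapset.laser_power, meta=meta)
    corrected.meta["valid_mask"] = valid
    return corrected, transforms


# ---------------------------------------------------------------------------
# Segmentation and ratio maps


@dataclass
class AFMIRSegmentation:
    foreground: np.ndarray  # hypha pixels
    valid: np.ndarray  # pixels inside every registered frame

    @property
    def n_foreground(self) -> int:
        return int(self.foreground.sum())


def segment_afmir(mapset: AFMIRMapSet, seed: int = 0) -> AFMIRSegmentation:
    """k-means (k=2) on all maps jointly; hypha = higher-topography cluster.

    Features per pixel: topography, deflection and absorption at every
    acquired wavenumber, standardised. Pixels outside the registered common
    frame are excluded and assigned to background.
    """
    _refuse_thick(mapset.meta)
    valid = mapset.meta.get("valid_mask")
    if valid is None:
        valid = np.ones(mapset.shape, dtype=bool)
    feats = []
    for w in mapset.wavenumbers:
        for role in ("topography", "deflection", "absorption"):
            feats.append(mapset.get(w, role).reshape(-1))
    F = np.column_stack(feats)
    v = valid.reshape(-1)
    keep_cols = F[v].std(axis=0) > 0
    if not keep_cols.any():
        raise ValueError("all features constant; clustering degenerate")
    Z = StandardScaler().fit_transform(F[v][:, keep_cols])
    labels = KMeans(n_clusters=2, init="k-means++", n_init=10, random_state=seed).fit_predict(Z)
    topo = mapset.get(mapset.wavenumbers[0], "topography").reshape(-1)[v]
    means = {c: topo[labels == c].mean() for c in (0, 1)}
    fg_cluster = max(means, key=means.get)
    fg = np.zeros(mapset.shape[0] * mapset.shape[1], dtype=bool)
    fg[np.nonzero(v)[0][labels == fg_cluster]] = True
    return AFMIRSegmentation(fg.reshape(mapset.shape), np.asarray(valid, dtype=bool))


@dataclass
class LogRatioMap:
    kind: str  # "absorption_ratio" or "absorption_over_topography"
    numerator: float
    denominator: float | None
    values: np.ndarray  # log10 ratio, NaN outside foreground / masked pixels
    n_masked: int  # foreground pixels masked for nonpositive operands


def log_ratio_maps(
    mapset: AFMIRMapSet,
    mask: AFMIRSegmentation,
    pairs: tuple[tuple[float, float], ...] = ((1742.0, 1600.0), (1708.0, 1600.0)),
) -> list[LogRatioMap]:
    """log10 ratios between absorption maps and absorption over topography.

    Foreground only; pixels with a nonpositive numerator or denominator are
    masked (NaN), never clipped, and counted in ``n_masked``.
    """
    out = []
    fg = mask.foreground
    for num, den in pairs:
        a, b = mapset.get(num, "absorption"), mapset.get(den, "absorption")
        ok = fg & (a > 0) & (b > 0)
        vals = np.full(mapset.shape, np.nan)
        vals[ok] = np.log10(a[ok] / b[ok])
        out.append(LogRatioMap("absorption_ratio", num, den, vals, int((fg & ~ok).sum())))
    for w in mapset.wavenumbers:
        a, t = mapset.get(w, "absorption"), mapset.get(w, "topography")
        ok = fg & (a > 0) & (t > 0)
        vals = np.full(mapset.shape, np.nan)
        vals[ok] = np.log10(a[ok] / t[ok])
        out.append(LogRatioMap("absorption_over_topography", w, None, vals, int((fg & ~ok).sum())))
    return out


# ---------------------------------------------------------------------------
# Point spectra


def preprocess_point_spectra(
    groups: list[PointSpectrumGroup],
    sg: SGParams = SGParams(15, 1, 0),
    second_derivative: bool = False,
) -> SpectrumCollection:
    """Average, smooth and EMSC-correct AFM-IR point spectra.

    Per acquisition point the repeats are averaged; all averaged spectra are
    Savitzky-Golay smoothed (window 15, polynomial order 1 by default) and
    EMSC-corrected against the group-set mean. ``second_derivative=True``
    instead applies an SG second derivative (window 15, order 2) after the
    EMSC step, the variant used to sharpen overlapping carbonyl bands.
    """
    if not groups:
        raise ValueError("no point-spectrum groups given")
    axis = groups[0].axis
    for g in groups[1:]:
        if g.axis != axis:
            raise ValueError("all groups must share the QCL axis")
    mat = np.vstack([g.average() for g in groups])
    meta = pd.DataFrame({"point_id": [g.point_id for g in groups], "n_repeats": [len(g.repeats) for g in groups]})
    coll = SpectrumCollection(axis, mat, meta)
    coll = savitzky_golay_collection(coll, sg)
    if len(groups) > 1:
        coll, _ = emsc_fit_correct(coll, reference="mean", poly_order=2)
    if second_derivative:
        coll = savitzky_golay_collection(coll, SGParams(15, 2, 2))
    return coll
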