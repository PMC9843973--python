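"""FPA-FTIR hyperspectral processing.

Pipeline stages, in acquisition order: trim the cube to the informative
3200-1000 cm^-1 window, flag and repair outlier pixels with a scaled-MAD
criterion, segment hyphae from slide background (standardise 7 marker bands,
PCA to 99% variance, k-means with k=2), apply an EMSC-based descattering
correction to foreground spectra, and export band images plus
lipid-to-protein ratio maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .preprocess import SGParams, emsc_fit_correct, savitzky_golay_collection
from .spectral_core import HyperspectralCube, SpectrumCollection, WavenumberAxis
import pandas as pd

__all__ = [
    "SEGMENTATION_BANDS",
    "OutlierMask",
    "SegmentationMask",
    "RatioMap",
    "trim_cube",
    "flag_outliers",
    "repair_outliers",
    "segment_cube",
    "descatter",
    "band_and_ratio_maps",
]

#: Marker bands (cm^-1) used for segmentation: lipid CH/C=O bands + amide I.
SEGMENTATION_BANDS: tuple[float, ...] = (3010.0, 2955.0, 2925.0, 2855.0, 1742.0, 1708.0, 1650.0)

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma under normality
WORKING_RANGE = (1000.0, 3200.0)
AMIDE_I = 1650.0


@dataclass
class OutlierMask:
    per_band: np.ndarray  # (rows, cols, bands) boolean
    global_pixels: np.ndarray  # (rows, cols) boolean
    global_fraction: float

    @property
    def n_flagged(self) -> int:
        return int(self.per_band.sum())


@dataclass
class SegmentationMask:
    foreground: np.ndarray  # (rows, cols) boolean
    cluster_means: pd.DataFrame  # per cluster, per segmentation band

    @property
    def n_foreground(self) -> int:
        return int(self.foreground.sum())


@dataclass
class RatioMap:
    numerator: float
    denominator: float
    values: np.ndarray  # (rows, cols), NaN off foreground / at flagged pixels
    flagged: np.ndarray  # (rows, cols) boolean: denominator below floor

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def trim_cube(cube: HyperspectralCube, lo: float = WORKING_RANGE[0], hi: float = WORKING_RANGE[1]) -> HyperspectralCube:
    """Drop bands outside the working range (water band above, noise below)."""
    mask = (cube.axis.values >= lo) & (cube.axis.values <= hi)
    if np.count_nonzero(mask) < 2:
        raise ValueError(f"no bands inside working range {lo}-{hi} cm^-1")
    return HyperspectralCube(
        cube.values[:, :, mask], WavenumberAxis(cube.axis.values[mask]), cube.pixel_size
    )


def _neighbor_median(img: np.ndarray) -> np.ndarray:
    """Median of the 8 neighbours of each pixel, self excluded (edge-padded)."""
    padded = np.pad(img, 1, mode="edge")
    rows, cols = img.shape
    stack = np.empty((8, rows, cols))
    i = 0
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if (di, dj) == (0, 0):
                continue
            stack[i] = padded[1 + di : 1 + di + rows, 1 + dj : 1 + dj + cols]
            i += 1
    return np.median(stack, axis=0)


def flag_outliers(
    cube: HyperspectralCube,
    n_mad: float = 3.0,
    global_fraction: float = 0.5,
    max_cluster: int | None = 12,
) -> OutlierMask:
    """Scaled-MAD outlier flags per spectral map, plus globally bad pixels.

    A pixel is flagged in a band when |x - median| > n_mad * 1.4826 * MAD of
    that band's image; a pixel flagged in more than ``global_fraction`` of all
    bands is a global outlier (dead/hot detector element). Bands with zero MAD
    fall back to a standard-deviation criterion with a warning.

    The artifacts this targets — dead pixels and noisy spectra — are
    spatially isolated, whereas strongly absorbing cell regions can also sit
    far from a band's median. Flagged 8-connected clusters larger than
    ``max_cluster`` pixels are therefore treated as genuine structure and
    released (set ``max_cluster=None`` for the raw criterion).
    """
    if cube.n_pixels < 9:
        raise ValueError("need at least 9 pixels per band for robust statistics")
    X = cube.values.reshape(-1, len(cube.axis))
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    sigma = MAD_SCALE * mad
    zero = sigma == 0
    if np.any(zero):
        warnings.warn(
            f"{np.count_nonzero(zero)} bands have zero MAD; using standard deviation",
            stacklevel=2,
        )
        sigma = sigma.copy()
        sigma[zero] = X[:, zero].std(axis=0)
        sigma[sigma == 0] = np.inf  # fully constant band: nothing can be an outlier
    flags = np.abs(X - med) > n_mad * sigma
    per_band = flags.reshape(cube.rows, cube.cols, -1)
    if max_cluster is not None:
        from scipy.ndimage import label

        structure = np.ones((3, 3), dtype=int)
        for k in range(per_band.shape[2]):
            band_flags = per_band[:, :, k]
            if not band_flags.any():
                continue
            labels, n = label(band_flags, structure=structure)
            sizes = np.bincount(labels.ravel())
            big = np.nonzero(sizes > max_cluster)[0]
            big = big[big != 0]
            if big.size:
                # within a large cluster, keep only pixels that are spikes
                # against their own neighbourhood (a dead pixel inside a
                # bright region is still an artifact)
                img = cube.values[:, :, k]
                detail = img - _neighbor_median(img)
                dsigma = MAD_SCALE * np.median(np.abs(detail))
                local_spike = np.abs(detail) > n_mad * dsigma if dsigma > 0 else detail != 0
                in_big = np.isin(labels, big)
                per_band[:, :, k] &= ~in_big | local_spike
    frac = per_band.mean(axis=2)
    return OutlierMask(per_band, frac > global_fraction, global_fraction)


def expected_false_positive_rate(n_mad: float = 3.0) -> float:
    """Two-sided normal tail probability for the MAD criterion on clean data."""
    return float(2 * norm.cdf(-n_mad))


def repair_outliers(
    cube: HyperspectralCube, mask: OutlierMask, max_iter: int = 200
) -> HyperspectralCube:
    """Replace flagged values with the mean of clean 8-neighbours, band-wise.

    Pixels whose neighbourhoods are all flagged are filled on a later sweep
    once neighbours have been repaired; an error lists pixels that remain
    unrecoverable after ``max_iter`` sweeps. Global outlier pixels are
    repaired in every band.
    """
    values = cube.values.copy()
    flags = mask.per_band | mask.global_pixels[:, :, None]
    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    rows, cols, nb = values.shape
    for _ in range(max_iter):
        if not flags.any():
            break
        acc = np.zeros_like(values)
        cnt = np.zeros_like(values)
        clean = ~flags
        for di, dj in offsets:
            src_r = slice(max(di, 0), rows + min(di, 0))
            src_c = slice(max(dj, 0), cols + min(dj, 0))
            dst_r = slice(max(-di, 0), rows + min(-di, 0))
            dst_c = slice(max(-dj, 0), cols + min(-dj, 0))
            acc[dst_r, dst_c] += np.where(clean[src_r, src_c], values[src_r, src_c], 0.0)
            cnt[dst_r, dst_c] += clean[src_r, src_c]
        reachable = flags & (cnt > 0)
        values[reachable] = acc[reachable] / cnt[reachable]
        flags = flags & ~reachable
    if flags.any():
        bad = np.argwhere(flags.any(axis=2))[:20]
        raise ValueError(f"unrecoverable outlier pixels (row, col): {bad.tolist()}")
    return HyperspectralCube(values, cube.axis, cube.pixel_size)


def segment_cube(
    cube: HyperspectralCube,
    bands: tuple[float, ...] = SEGMENTATION_BANDS,
    variance_keep: float = 0.99,
    seed: int = 0,
    band_tol: float = 4.0,
) -> SegmentationMask:
    """Separate cell pixels from slide background.

    Per-pixel features are the absorbances at the marker bands (nearest grid
    point within ``band_tol`` cm^-1), standardised per band; PCA keeps the
    leading components reaching ``variance_keep`` cumulative variance, and
    k-means (k=2, k-means++ with fixed seed, 10 restarts) splits the pixels.
    The cluster with the higher mean amide-I (1650 cm^-1) absorbance is the
    foreground: cells carry protein, the slide does not.
    """
    features, kept = [], []
    for w in bands:
        img = cube.band_image(w, tol=band_tol)
        if img.std() == 0:
            warnings.warn(f"band {w:g} cm^-1 constant; dropped from segmentation", stacklevel=2)
            continue
        features.append(img.reshape(-1))
        kept.append(w)
    if not features:
        raise ValueError("all segmentation bands are constant")
    F = np.column_stack(features)
    Z = StandardScaler().fit_transform(F)
    pca = PCA(n_components=variance_keep, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(Z)
    km = KMeans(n_clusters=2, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(scores)

    amide = cube.band_image(AMIDE_I, tol=band_tol).reshape(-1)
    means = {c: amide[labels == c].mean() for c in (0, 1)}
    fg_cluster = max(means, key=means.get)
    foreground = (labels == fg_cluster).reshape(cube.rows, cube.cols)
    cluster_means = pd.DataFrame(
        {f"{w:g}": [F[labels == c, k].mean() for c in (0, 1)] for k, w in enumerate(kept)},
        index=["cluster0", "cluster1"],
    )
    cluster_means["foreground"] = [fg_cluster == 0, fg_cluster == 1]
    return SegmentationMask(foreground, cluster_means)


def descatter(
    cube: HyperspectralCube,
    mask: SegmentationMask,
    sg: SGParams = SGParams(5, 2, 0),
    min_foreground: int = 10,
) -> HyperspectralCube:
    """Scatter correction of foreground spectra.

    Foreground pixel spectra are EMSC-corrected against their mean with a
    quadratic baseline term, then Savitzky-Golay smoothed. Background pixels
    pass through untouched. The interface accepts any drop-in replacement
    operating on a (pixels x bands) matrix, e.g. a learned descattering model.
    """
    fg = mask.foreground.reshape(-1)
    if fg.sum() < min_foreground:
        warnings.warn(f"only {int(fg.sum())} foreground pixels; descattering skipped", stacklevel=2)
        return cube
    X = cube.as_pixel_matrix()
    coll = SpectrumCollection(cube.axis, X[fg], pd.DataFrame(index=range(int(fg.sum()))))
    corrected, _ = emsc_fit_correct(coll, reference="mean", poly_order=2)
    smoothed = savitzky_golay_collection(corrected, sg)
    out = X.copy()
    out[fg] = smoothed.matrix
    return HyperspectralCube(
        out.reshape(cube.values.shape), cube.axis, cube.pixel_size
    )


def band_and_ratio_maps(
    cube: HyperspectralCube,
    mask: SegmentationMask,
    bands: tuple[float, ...] = SEGMENTATION_BANDS,
    ratio_pairs: tuple[tuple[float, float], ...] = ((1742.0, 1650.0),),
    denominator_floor: float = 1e-3,
    band_tol: float = 4.0,
) -> tuple[dict[float, np.ndarray], list[RatioMap]]:
    """Nearest-band images and foreground ratio maps.

    Ratio pixels whose denominator absorbance is below ``denominator_floor``
    are masked (NaN) and counted in the RatioMap's flag image rather than
    divided, so detector noise cannot fabricate extreme ratios.
    """
    band_images = {w: cube.band_image(w, tol=band_tol).copy() for w in bands}
    ratio_maps = []
    fg = mask.foreground
    for num, den in ratio_pairs:
        a_num = cube.band_image(num, tol=band_tol)
        a_den = cube.band_image(den, tol=band_tol)
        flagged = fg & (a_den < denominator_floor)
        values = np.full(a_num.shape, np.nan)
        ok = fg & ~flagged
        values[ok] = a_num[ok] / a_den[ok]
        ratio_maps.append(RatioMap(num, den, values, flagged))
    return band_images, ratio_maps
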