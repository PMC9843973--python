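"""Spectral preprocessing: absorbance, Savitzky-Golay filtering, EMSC,
region selection and replicate averaging.

EMSC (extended multiplicative signal correction) models each spectrum as an
affine-plus-polynomial distortion of a reference spectrum m:

    s(v) ~= a + b * m(v) + d1 * t(v) + d2 * t(v)^2

where t is the wavenumber axis mapped affinely onto [-1, 1] for conditioning.
The corrected spectrum is (s - a - d1 t - d2 t^2) / b, which removes baseline
offset, multiplicative scaling, and low-order baseline curvature while
preserving chemical band structure relative to the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectral_core import Spectrum, SpectrumCollection, WavenumberAxis

__all__ = [
    "SGParams",
    "EMSCModel",
    "SpectralRegion",
    "REGION_PRESETS",
    "compute_absorbance",
    "savitzky_golay",
    "emsc_fit_correct",
    "select_region",
    "average_replicates",
]


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay filter parameters (window in points)."""

    window: int = 15
    polyorder: int = 2
    deriv_order: int = 0

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("SG window must be odd")
        if self.window <= self.polyorder:
            raise ValueError("SG window must exceed the polynomial order")
        if not (0 <= self.deriv_order <= self.polyorder):
            raise ValueError("derivative order must be in [0, polyorder]")


@dataclass
class EMSCModel:
    """Fitted EMSC basis and per-spectrum coefficients.

    ``coefficients`` has one row per spectrum with columns ``b`` (multiplicative),
    ``a`` (offset) and ``d1``..``dk`` (polynomial terms in the mapped axis);
    ``valid`` is False where |b| fell below tolerance and the spectrum was left
    uncorrected.
    """

    reference: Spectrum
    poly_order: int
    coefficients: pd.DataFrame
    b_tol: float = 1e-8

    @property
    def valid(self) -> np.ndarray:
        return self.coefficients["valid"].to_numpy(dtype=bool)


class SpectralRegion:
    """A union of closed wavenumber intervals, normalised on construction."""

    def __init__(self, intervals: Iterable[tuple[float, float]]):
        ivs = sorted((min(a, b), max(a, b)) for a, b in intervals)
        if not ivs:
            raise ValueError("region must contain at least one interval")
        merged = [ivs[0]]
        for lo, hi in ivs[1:]:
            if lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
            else:
                merged.append((lo, hi))
        self.intervals: tuple[tuple[float, float], ...] = tuple(merged)

    def mask(self, axis: WavenumberAxis) -> np.ndarray:
        m = np.zeros(len(axis), dtype=bool)
        for lo, hi in self.intervals:
            m |= (axis.values >= lo) & (axis.values <= hi)
        return m

    def contains(self, other: "SpectralRegion") -> bool:
        return all(
            any(lo >= slo and hi <= shi for slo, shi in self.intervals)
            for lo, hi in other.intervals
        )

    def __repr__(self) -> str:
        parts = ", ".join(f"{lo:g}-{hi:g}" for lo, hi in self.intervals)
        return f"SpectralRegion({parts} cm^-1)"


#: Named analysis regions (cm^-1) used across the bulk pipeline.
REGION_PRESETS: dict[str, SpectralRegion] = {
    "full": SpectralRegion([(700.0, 4000.0)]),
    "lipid_combined": SpectralRegion([(2800.0, 3050.0), (1700.0, 1800.0)]),
    "protein": SpectralRegion([(1500.0, 1700.0)]),
    "mixed": SpectralRegion([(1200.0, 1500.0)]),
    "polysaccharide": SpectralRegion([(700.0, 1200.0)]),
}


def compute_absorbance(
    sample: np.ndarray, background: np.ndarray, axis: WavenumberAxis, meta: dict | None = None
) -> Spectrum:
    """Absorbance from single-beam sample and background intensities.

    A(v) = -log10(S(v) / B(v)).
    """
    sample = np.asarray(sample, dtype=float)
    background = np.asarray(background, dtype=float)
    if sample.shape != background.shape or sample.shape != (len(axis),):
        raise ValueError("sample, background and axis lengths must agree")
    if np.any(background <= 0):
        raise ValueError("background intensity must be strictly positive")
    if np.any(sample <= 0):
        raise ValueError("sample intensity must be strictly positive")
    return Spectrum(axis, -np.log10(sample / background), dict(meta or {}))


def _savgol_matrix(matrix: np.ndarray, p: SGParams, delta: float) -> np.ndarray:
    if matrix.shape[-1] < p.window:
        raise ValueError(f"SG window {p.window} exceeds spectrum length {matrix.shape[-1]}")
    return savgol_filter(
        matrix, p.window, p.polyorder, deriv=p.deriv_order, delta=delta, mode="nearest", axis=-1
    )


def savitzky_golay(sp: Spectrum, p: SGParams) -> Spectrum:
    """SG smoothing / differentiation; derivatives are per cm^-1.

    The local polynomial is fitted in physical axis units (delta = grid step),
    so deriv_order=2 on a*v^2 returns the constant 2a. Edges use nearest-point
    extension to keep the output length equal to the input.
    """
    out = _savgol_matrix(sp.intensities, p, sp.axis.resolution)
    return Spectrum(sp.axis, out, dict(sp.meta))


def savitzky_golay_collection(coll: SpectrumCollection, p: SGParams) -> SpectrumCollection:
    return coll.with_matrix(_savgol_matrix(coll.matrix, p, coll.axis.resolution))


def _emsc_basis(axis: WavenumberAxis, reference: np.ndarray, poly_order: int) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, len(axis))
    cols = [reference] + [t**k for k in range(poly_order + 1)]
    return np.column_stack(cols)


def emsc_fit_correct(
    coll: SpectrumCollection,
    reference: Spectrum | str = "mean",
    poly_order: int = 2,
    b_tol: float = 1e-8,
) -> tuple[SpectrumCollection, EMSCModel]:
    """Fit and apply EMSC to every spectrum in the collection.

    ``reference`` defaults to the collection mean. Spectra whose multiplicative
    coefficient |b| falls below ``b_tol`` (flat/degenerate) are flagged and
    returned uncorrected.
    """
    if not (0 <= poly_order <= 2):
        raise ValueError("poly_order must be 0, 1 or 2")
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be a Spectrum or 'mean'")
        ref = coll.mean_spectrum()
    else:
        if reference.axis != coll.axis:
            raise ValueError("reference axis must equal the collection axis")
        ref = reference
    if np.ptp(ref.intensities) == 0:
        raise ValueError("EMSC reference must be nonconstant")

    basis = _emsc_basis(coll.axis, ref.intensities, poly_order)
    # columns: [m, 1, t, t^2][: poly_order + 2]
    coefs, *_ = np.linalg.lstsq(basis, coll.matrix.T, rcond=None)
    coefs = coefs.T  # (n_spectra, n_terms)
    b = coefs[:, 0]
    valid = np.abs(b) >= b_tol
    if not np.all(valid):
        warnings.warn(
            f"{np.count_nonzero(~valid)} spectra with |b| < {b_tol} left uncorrected",
            stacklevel=2,
        )
    baseline = coefs[:, 1:] @ basis[:, 1:].T  # additive part per spectrum
    corrected = coll.matrix.copy()
    corrected[valid] = (coll.matrix[valid] - baseline[valid]) / b[valid, None]

    names = ["b", "a"] + [f"d{k}" for k in range(1, poly_order + 1)]
    table = pd.DataFrame(coefs, columns=names)
    table["valid"] = valid
    model = EMSCModel(ref, poly_order, table, b_tol)
    return coll.with_matrix(corrected), model


def select_region(coll: SpectrumCollection, region: SpectralRegion) -> SpectrumCollection:
    """Restrict the collection to the union of the region's intervals."""
    mask = region.mask(coll.axis)
    if np.count_nonzero(mask) < 2:
        raise ValueError(f"{region} does not intersect the axis {coll.axis.span}")
    axis = WavenumberAxis(coll.axis.values[mask])
    return SpectrumCollection(axis, coll.matrix[:, mask], coll.metadata.copy())


def average_replicates(coll: SpectrumCollection, by: Sequence[str]) -> SpectrumCollection:
    """One mean spectrum per group of the metadata factors in ``by``.

    The output metadata keeps the grouping factors plus ``n_averaged``.
    """
    by = list(by)
    missing = [f for f in by if f not in coll.metadata.columns]
    if missing:
        raise ValueError(f"grouping factors not in metadata: {missing}")
    groups = coll.metadata.groupby(by, sort=False, dropna=False).indices
    rows, meta_rows = [], []
    for key, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty group {key}")
        rows.append(coll.matrix[idx].mean(axis=0))
        key_t = key if isinstance(key, tuple) else (key,)
        meta_rows.append({**dict(zip(by, key_t)), "n_averaged": len(idx)})
    return SpectrumCollection(coll.axis, np.vstack(rows), pd.DataFrame(meta_rows))
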