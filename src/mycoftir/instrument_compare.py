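"""Cross-instrument comparison of transmission (HTS) and ATR spectra.

ATR sampling probes the sample through an evanescent wave whose penetration
depth grows with wavelength, so relative band intensities and (through
refractive-index dispersion) band positions differ systematically from
transmission spectra of the same material. This module aligns the two
instruments onto a common grid, picks band positions from the Savitzky-Golay
second derivative (band maxima appear as second-derivative minima), matches
closest counterpart peaks, reports the ATR - HTS position shifts, and builds
absorbance-ratio tables for the standard lipid/protein marker pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocess import SGParams, SpectralRegion, savitzky_golay, select_region
from .spectral_core import Spectrum, SpectrumCollection, WavenumberAxis

__all__ = [
    "PeakList",
    "PeakMatchTable",
    "RatioTable",
    "DEFAULT_RATIO_PAIRS",
    "align_axes",
    "pick_peaks",
    "match_peaks",
    "band_ratios",
]

#: Marker-band ratio pairs (numerator, denominator) in cm^-1:
#: lipid-to-protein, unsaturation-to-lipid, unsaturation-to-protein.
DEFAULT_RATIO_PAIRS: tuple[tuple[float, float], ...] = (
    (1742.0, 1650.0),
    (3010.0, 1742.0),
    (3010.0, 1650.0),
)


@dataclass
class PeakList:
    region: str
    instrument: str
    table: pd.DataFrame  # columns: position, absorbance, d2_depth; sorted ascending

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()


@dataclass
class PeakMatchTable:
    table: pd.DataFrame  # columns: hts_position, atr_position, shift, matched


@dataclass
class RatioTable:
    table: pd.DataFrame  # per spectrum: instrument, sample, one column per pair, flags


def align_axes(
    a: SpectrumCollection, b: SpectrumCollection
) -> tuple[SpectrumCollection, SpectrumCollection]:
    """Interpolate both collections onto a shared grid over their overlap.

    The common grid uses the coarser of the two nominal resolutions so neither
    dataset is upsampled beyond its information content.
    """
    lo = max(a.axis.values[0], b.axis.values[0])
    hi = min(a.axis.values[-1], b.axis.values[-1])
    if hi <= lo:
        raise ValueError(f"axes do not overlap: {a.axis.span} vs {b.axis.span}")
    step = max(a.axis.resolution, b.axis.resolution)
    grid = np.arange(lo, hi + 0.5 * step, step)
    grid = grid[grid <= hi]
    axis = WavenumberAxis(grid)

    def _resample(coll: SpectrumCollection) -> SpectrumCollection:
        if coll.axis == axis:
            return coll
        mat = np.vstack([np.interp(grid, coll.axis.values, row) for row in coll.matrix])
        return SpectrumCollection(axis, mat, coll.metadata.copy())

    return _resample(a), _resample(b)


def pick_peaks(
    mean_spectrum: Spectrum,
    region: SpectralRegion,
    sg: SGParams = SGParams(15, 2, 2),
    prominence_frac: float = 0.05,
    instrument: str = "",
    region_label: str = "",
) -> PeakList:
    """Band positions as local minima of the SG second derivative.

    Minima must exceed ``prominence_frac`` of the region's deepest
    second-derivative excursion, which drops baseline wiggle while keeping
    every real band — the "most prominent" peaks of the region.
    """
    if sg.deriv_order != 2:
        raise ValueError("peak picking runs on the second derivative")
    d2 = savitzky_golay(mean_spectrum, sg)
    mask = region.mask(mean_spectrum.axis)
    if np.count_nonzero(mask) < sg.window:
        raise ValueError("SG window exceeds region length")
    wn = mean_spectrum.axis.values[mask]
    depth = -d2.intensities[mask]  # band maxima -> positive peaks of -d2
    scale = depth.max()
    if scale <= 0:
        rows = pd.DataFrame(columns=["position", "absorbance", "d2_depth"])
        return PeakList(region_label, instrument, rows)
    idx, _ = find_peaks(depth, prominence=prominence_frac * scale)
    rows = pd.DataFrame(
        {
            "position": wn[idx],
            "absorbance": mean_spectrum.intensities[mask][idx],
            "d2_depth": depth[idx],
        }
    ).sort_values("position", ignore_index=True)
    return PeakList(region_label, instrument, rows)


def match_peaks(hts: PeakList, atr: PeakList, window: float = 20.0) -> PeakMatchTable:
    """Greedy one-to-one nearest matching of ATR peaks to HTS peaks.

    Candidate pairs within ``window`` cm^-1 are taken in order of ascending
    distance (ties broken toward lower wavenumber), each peak used at most
    once. Shift = ATR - HTS; unmatched peaks from either list are kept with
    ``matched=False``.
    """
    h, t = hts.positions, atr.positions
    pairs = [
        (abs(t[j] - h[i]), h[i], t[j], i, j)
        for i in range(len(h))
        for j in range(len(t))
        if abs(t[j] - h[i]) <= window
    ]
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_h: set[int] = set()
    used_t: set[int] = set()
    rows = []
    for dist, hp, tp, i, j in pairs:
        if i in used_h or j in used_t:
            continue
        used_h.add(i)
        used_t.add(j)
        rows.append({"hts_position": hp, "atr_position": tp, "shift": tp - hp, "matched": True})
    for i in range(len(h)):
        if i not in used_h:
            rows.append(
                {"hts_position": h[i], "atr_position": np.nan, "shift": np.nan, "matched": False}
            )
    for j in range(len(t)):
        if j not in used_t:
            rows.append(
                {"hts_position": np.nan, "atr_position": t[j], "shift": np.nan, "matched": False}
            )
    table = pd.DataFrame(rows, columns=["hts_position", "atr_position", "shift", "matched"])
    table = table.sort_values(
        ["matched", "hts_position", "atr_position"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return PeakMatchTable(table)


def band_ratios(
    coll: SpectrumCollection,
    pairs: tuple[tuple[float, float], ...] = DEFAULT_RATIO_PAIRS,
    window: float = 20.0,
    sg: SGParams = SGParams(15, 2, 2),
    instrument: str = "",
) -> RatioTable:
    """Absorbance ratios at detected marker-band positions, per spectrum.

    Peak positions are located once on the collection mean (within ``window``
    of each nominal position) and the ratio of raw absorbances at those
    positions is reported for every spectrum. Pairs whose numerator or
    denominator band is not detected are flagged, not dropped.
    """
    mean = coll.mean_spectrum()
    full = SpectralRegion([coll.axis.span])
    peaks = pick_peaks(mean, full, sg)

    located: dict[float, float | None] = {}
    for nominal in {w for pair in pairs for w in pair}:
        cand = peaks.positions
        if cand.size:
            k = int(np.argmin(np.abs(cand - nominal)))
            located[nominal] = float(cand[k]) if abs(cand[k] - nominal) <= window else None
        else:
            located[nominal] = None

    rows = []
    for i in range(len(coll)):
        row: dict = dict(coll.metadata.iloc[i])
        row["instrument"] = instrument or row.get("technique", "")
        for num, den in pairs:
            name = f"ratio_{num:g}_{den:g}"
            pn, pd_ = located[num], located[den]
            if pn is None or pd_ is None:
                row[name] = np.nan
                row[name + "_flag"] = "peak_missing"
            else:
                a_num = coll.matrix[i, coll.axis.index_of(pn)]
                a_den = coll.matrix[i, coll.axis.index_of(pd_)]
                if a_den <= 0:
                    row[name] = np.nan
                    row[name + "_flag"] = "nonpositive_denominator"
                else:
                    row[name] = a_num / a_den
                    row[name + "_flag"] = ""
        rows.append(row)
    return RatioTable(pd.DataFrame(rows))
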