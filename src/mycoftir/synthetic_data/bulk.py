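"""Forward model for the bulk HTS / ATR measurement campaigns.

The emulated experiment: the fungus is grown under six phosphate regimes
(Pi4 down to Pi0, g/L of KH2PO4 / Na2HPO4 in the medium) in three biological
replicates. HTS (transmission) spectra are measured once; ATR spectra are
re-measured on seven consecutive storage days. Phosphate availability drives
the stored polyphosphate (1265 cm^-1) up and — through the lipogenesis
response to nutrient limitation — the acyl lipid bands down, monotonically
across the Pi series; storage mainly dries the film (water bands) with a
small lipid drift. Replicate scatter is i.i.d. Gaussian channel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..spectral_core import Spectrum, SpectrumCollection, WavenumberAxis
from .bands import CompositionProfile, mixture_spectrum
from .optics import ATROpticsModel

__all__ = [
    "PI_CONDITIONS",
    "CampaignDesign",
    "hts_axis",
    "atr_axis",
    "base_profile",
    "synth_bulk_spectrum",
    "synth_campaign",
]

#: Phosphate design: condition label -> (KH2PO4 g/L, Na2HPO4 g/L, relative Pi level).
PI_CONDITIONS: dict[str, tuple[float, float, float]] = {
    "Pi4": (28.0, 8.0, 4.0),
    "Pi2": (14.0, 4.0, 2.0),
    "Pi1": (7.0, 2.0, 1.0),
    "Pi0.5": (3.5, 1.0, 0.5),
    "Pi0.25": (1.75, 0.5, 0.25),
    "Pi0": (0.0, 0.0, 0.0),
}


def hts_axis() -> WavenumberAxis:
    """Transmission range 4000-500 cm^-1; 6 cm^-1 resolution, 3 cm^-1 spacing.

    FTIR spectra are delivered on a grid about twice as fine as the optical
    resolution (interferogram zero-filling), so the point spacing is half the
    nominal resolution.
    """
    return WavenumberAxis(np.arange(500.0, 4000.0 + 1e-9, 3.0))


def atr_axis() -> WavenumberAxis:
    """ATR range 4000-400 cm^-1; 4 cm^-1 resolution, 2 cm^-1 spacing."""
    return WavenumberAxis(np.arange(400.0, 4000.0 + 1e-9, 2.0))


def base_profile() -> CompositionProfile:
    """Typical oleaginous-fungus biomass composition under N limitation."""
    return CompositionProfile(
        TAG=0.18,
        FFA=0.03,
        FFA_ionized=0.02,
        protein=0.22,
        polysaccharide=0.28,
        polyphosphate=0.07,
        water=0.20,
    )


@dataclass
class CampaignDesign:
    """Study conditions for a synthetic bulk campaign.

    Amplitudes are dimensionless multipliers on the affected component
    weights: ``condition_amplitude`` sets the span of the lipid/polyphosphate
    response across the Pi series, ``day_amplitude`` the span of the storage
    drift. The defaults put the condition effect about five times above the
    day effect in the lipid region.
    """

    technique: str = "ATR"
    conditions: tuple[str, ...] = tuple(PI_CONDITIONS)
    replicates: int = 3
    days: int = 7
    condition_amplitude: float = 0.6
    day_amplitude: float = 0.12
    noise_sd: float = 0.002
    baseline_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in ("HTS", "ATR"):
            raise ValueError("technique must be HTS or ATR")
        if self.technique == "HTS":
            self.days = 1

    @property
    def n_spectra(self) -> int:
        return len(self.conditions) * self.replicates * self.days


def _condition_multipliers(design: CampaignDesign, idx: int, n: int) -> dict[str, float]:
    # monotone across the Pi series: idx 0 = highest Pi. Lower phosphate
    # pushes lipogenesis (more TAG, higher unsaturation) and depletes stored
    # polyphosphate; FFA stays constant, so the lipid-region band pattern
    # changes shape, not just scale.
    x = idx / max(n - 1, 1) - 0.5  # -0.5 .. +0.5, low Pi at +0.5
    ca = design.condition_amplitude
    return {
        "TAG": 1.0 + ca * x,
        "unsaturation": 1.0 + 0.8 * ca * x,
        "polyphosphate": 1.0 - ca * x,
    }


def _day_multipliers(design: CampaignDesign, day: int) -> dict[str, float]:
    if design.days == 1:
        return {}
    u = (day - (design.days + 1) / 2) / ((design.days - 1) / 2)  # -1 .. +1
    da = design.day_amplitude
    return {
        "water": 1.0 - 0.5 * da * (day - 1) / max(design.days - 1, 1),
        "TAG": 1.0 + 0.2 * da * u,
        "unsaturation": 1.0 + 0.4 * da * u,
    }


def _apply_multipliers(
    profile: CompositionProfile | dict[str, float], mult: dict[str, float]
) -> dict[str, float]:
    w = profile.as_dict() if isinstance(profile, CompositionProfile) else dict(profile)
    for k, m in mult.items():
        if k in ("unsaturation", "CH_chain"):
            key = k + "_mult"
            w[key] = w.get(key, 1.0) * m
        else:
            w[k] = w[k] * m
    return w


def synth_bulk_spectrum(
    profile: CompositionProfile,
    technique: str,
    axis: WavenumberAxis,
    optics: ATROpticsModel | None = None,
    noise_sd: float = 0.0,
    baseline: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
    meta: dict | None = None,
) -> Spectrum:
    """One synthetic absorbance spectrum.

    For ATR the band intensities are weighted by the relative penetration
    depth d_p(v)/d_p(1742) and band centres displaced toward lower
    wavenumbers by the dispersive shift model. ``baseline`` is (offset,
    slope-per-normalised-axis); noise is i.i.d. Gaussian.
    """
    if technique not in ("HTS", "ATR"):
        raise ValueError("technique must be HTS or ATR")
    depth = shift = None
    if technique == "ATR":
        optics = optics or ATROpticsModel()
        depth, shift = optics.depth_weight, optics.center_shift
    y = mixture_spectrum(profile, axis, depth, shift)
    t = np.linspace(0.0, 1.0, len(axis))
    y = y + baseline[0] + baseline[1] * t
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sd, len(axis))
    m = {"technique": technique, **(meta or {})}
    return Spectrum(axis, y, m)


def _weights_spectrum(weights: dict[str, float], axis, depth, shift) -> np.ndarray:
    from .bands import component_spectrum, CHAIN_WEIGHT, UNSATURATION_WEIGHT

    w = dict(weights)
    acyl = w.get("TAG", 0.0) + w.get("FFA", 0.0)
    # multipliers for the derived acyl bands may ride in on the weights dict
    w["CH_chain"] = CHAIN_WEIGHT * acyl * w.pop("CH_chain_mult", 1.0)
    w["unsaturation"] = UNSATURATION_WEIGHT * acyl * w.pop("unsaturation_mult", 1.0)
    out = np.zeros(len(axis))
    for comp, wt in w.items():
        if wt > 0:
            out += wt * component_spectrum(comp, axis, depth, shift)
    return out


def synth_campaign(
    design: CampaignDesign, optics: ATROpticsModel | None = None
) -> tuple[SpectrumCollection, dict]:
    """Generate the full campaign plus ground truth.

    Returns the collection (one spectrum per condition x replicate x day) and
    a truth dict with the noiseless matrix and per-spectrum labels, from
    which exact effect matrices can be formed without touching the pipeline.
    """
    axis = atr_axis() if design.technique == "ATR" else hts_axis()
    depth = shift = None
    if design.technique == "ATR":
        optics = optics or ATROpticsModel()
        depth, shift = optics.depth_weight, optics.center_shift
    rng = np.random.default_rng(design.seed)
    prof = base_profile()

    rows, clean_rows, meta_rows = [], [], []
    t = np.linspace(0.0, 1.0, len(axis))
    for ci, cond in enumerate(design.conditions):
        cmult = _condition_multipliers(design, ci, len(design.conditions))
        for day in range(1, design.days + 1):
            dmult = _day_multipliers(design, day)
            weights = _apply_multipliers(_apply_multipliers(prof, cmult), dmult)
            clean = _weights_spectrum(weights, axis, depth, shift)
            for rep in range(1, design.replicates + 1):
                baseline = rng.normal(0.0, design.baseline_sd) + rng.normal(
                    0.0, design.baseline_sd
                ) * t
                noise = rng.normal(0.0, design.noise_sd, len(axis))
                rows.append(clean + baseline + noise)
                clean_rows.append(clean)
                meta_rows.append(
                    {
                        "spectrum_id": f"{design.technique}_{cond}_d{day}_r{rep}",
                        "technique": design.technique,
                        "sample": cond,
                        "pi_level": PI_CONDITIONS[cond][2],
                        "replicate": rep,
                        "day": day,
                    }
                )
    coll = SpectrumCollection(axis, np.vstack(rows), pd.DataFrame(meta_rows))
    truth = {
        "clean_matrix": np.vstack(clean_rows),
        "condition": [m["sample"] for m in meta_rows],
        "day": [m["day"] for m in meta_rows],
        "replicate": [m["replicate"] for m in meta_rows],
    }
    return coll, truth
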