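"""Gaussian band library and biomass composition profiles.

Band centres follow the standard mid-IR assignments for fungal biomass
(ester carbonyl of triacylglycerides at 1742 cm^-1, carboxylic-dimer C=O of
free fatty acids at 1708 cm^-1, amide I at 1650 cm^-1, the CH stretching
manifold at 2855-3010 cm^-1, polyphosphate P=O near 1265 cm^-1,
polysaccharide C-O-C near 1030-1150 cm^-1). Amplitudes are relative within a
component; absolute scaling comes from the composition profile, since
absolute molar absorptivities for intact biomass are not available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..spectral_core import BandDefinition, WavenumberAxis

__all__ = ["BAND_LIBRARY", "CompositionProfile", "component_spectrum", "mixture_spectrum"]

_HWHM_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))


def _b(center, hw, amp, comp, note=""):
    return BandDefinition(center, hw, amp, comp, note)


#: Bands per chemical component; half_width is the Gaussian HWHM in cm^-1.
BAND_LIBRARY: dict[str, tuple[BandDefinition, ...]] = {
    "TAG": (
        _b(1742, 12, 1.00, "TAG", "C=O stretching, ester bond; total lipid content"),
        _b(1160, 18, 0.35, "TAG", "C-O-C antisymmetric stretching in esters"),
    ),
    "FFA": (
        _b(1708, 12, 1.00, "FFA", "C=O stretching, carboxylic acid dimers"),
    ),
    "FFA_ionized": (
        _b(1600, 16, 1.00, "FFA_ionized", "antisymmetric COO- stretching"),
    ),
    "protein": (
        _b(1650, 20, 1.00, "protein", "amide I, C=O stretching"),
        _b(1545, 18, 0.65, "protein", "amide II, N-H bending / C-N stretching"),
    ),
    "polysaccharide": (
        _b(1030, 22, 1.00, "polysaccharide", "C-O-C stretching, alkyl aryl ethers"),
        _b(1080, 20, 0.60, "polysaccharide", "C-O stretching"),
        _b(1150, 16, 0.35, "polysaccharide", "C-O-C stretching"),
    ),
    "polyphosphate": (
        _b(1265, 18, 1.00, "polyphosphate", "P=O asymmetric stretching, phosphodiester"),
    ),
    "CH_chain": (
        _b(2925, 16, 1.00, "CH_chain", "CH2 asymmetric stretching"),
        _b(2855, 14, 0.70, "CH_chain", "CH2 symmetric stretching"),
        _b(2955, 12, 0.50, "CH_chain", "CH3 asymmetric stretching"),
        _b(1465, 12, 0.25, "CH_chain", "CH2 bending"),
        _b(1375, 10, 0.18, "CH_chain", "CH3 symmetric bending"),
        _b(730, 10, 0.08, "CH_chain", "CH2 rocking"),
    ),
    "unsaturation": (
        _b(3010, 10, 1.00, "unsaturation", "=C-H stretching; unsaturation index"),
    ),
    "water": (
        _b(3400, 150, 1.00, "water", "O-H stretching, broad"),
        _b(1640, 40, 0.30, "water", "O-H bending"),
    ),
}

#: Acyl-chain CH bands and the =C-H band scale with the total acyl lipid
#: fraction; factors are the package's order-of-magnitude defaults.
CHAIN_WEIGHT = 0.8
UNSATURATION_WEIGHT = 0.25


@dataclass(frozen=True)
class CompositionProfile:
    """Mass fractions of the main biomass components; must sum to 1."""

    TAG: float = 0.0
    FFA: float = 0.0
    FFA_ionized: float = 0.0
    protein: float = 0.0
    polysaccharide: float = 0.0
    polyphosphate: float = 0.0
    water: float = 0.0

    def __post_init__(self) -> None:
        fracs = self.as_dict()
        if any(v < 0 or v > 1 for v in fracs.values()):
            raise ValueError("fractions must lie in [0, 1]")
        total = sum(fracs.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"fractions must sum to 1, got {total}")

    def as_dict(self) -> dict[str, float]:
        return {
            "TAG": self.TAG,
            "FFA": self.FFA,
            "FFA_ionized": self.FFA_ionized,
            "protein": self.protein,
            "polysaccharide": self.polysaccharide,
            "polyphosphate": self.polyphosphate,
            "water": self.water,
        }

    def component_weights(self) -> dict[str, float]:
        """Band-library weights, with acyl-chain bands derived from TAG+FFA."""
        w = self.as_dict()
        acyl = self.TAG + self.FFA
        w["CH_chain"] = CHAIN_WEIGHT * acyl
        w["unsaturation"] = UNSATURATION_WEIGHT * acyl
        return w


def component_spectrum(
    component: str,
    axis: WavenumberAxis,
    depth_weight=None,
    center_shift=None,
) -> np.ndarray:
    """Sum-of-Gaussians spectrum of one component on the given axis.

    ``depth_weight(center)`` multiplies each band (ATR penetration-depth
    weighting); ``center_shift(center)`` displaces each band centre in cm^-1
    (dispersive peak shifts; negative = toward lower wavenumber).
    """
    bands = BAND_LIBRARY[component]
    v = axis.values
    out = np.zeros(len(axis))
    for band in bands:
        c = band.center + (center_shift(band.center) if center_shift else 0.0)
        amp = band.relative_amplitude * (depth_weight(band.center) if depth_weight else 1.0)
        sigma = band.half_width * _HWHM_TO_SIGMA
        out += amp * np.exp(-0.5 * ((v - c) / sigma) ** 2)
    return out


def mixture_spectrum(
    profile: CompositionProfile,
    axis: WavenumberAxis,
    depth_weight=None,
    center_shift=None,
) -> np.ndarray:
    """Linear (Beer-Lambert) mixture of component spectra."""
    weights = profile.component_weights()
    if all(v == 0 for v in weights.values()):
        raise ValueError("empty composition profile")
    out = np.zeros(len(axis))
    for comp, w in weights.items():
        if w > 0:
            out += w * component_spectrum(comp, axis, depth_weight, center_shift)
    return out
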