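"""ATR evanescent-wave optics: penetration depth and dispersive peak shifts.

In attenuated total reflectance the IR beam totally reflects inside a
high-index crystal (diamond, n1 = 2.40) pressed against the sample
(n2 ~ 1.50 for dried biomass) at incidence angle theta (45 deg). An
evanescent field leaks into the sample and decays to 1/e at the penetration
depth

    d_p = lambda / (2 pi n1 sqrt(sin^2 theta - (n2/n1)^2)),  lambda = 1e4 / v um,

so the effective pathlength — and hence band intensity relative to a
transmission measurement — grows toward lower wavenumbers. Refractive-index
dispersion across an absorption band additionally displaces apparent ATR band
positions toward lower wavenumbers, more strongly at the low-frequency end of
the spectrum; this is modelled phenomenologically here rather than through
full Kramers-Kronig optics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ATROpticsModel", "penetration_depth"]


@dataclass(frozen=True)
class ATROpticsModel:
    """Single-reflection ATR geometry plus the dispersive shift parameters.

    ``shift_amplitude`` is the downward band displacement (cm^-1) at the
    ``shift_reference`` wavenumber; displacements scale as
    (shift_reference / v)^2, growing toward low wavenumbers.
    """

    n1: float = 2.40  # diamond crystal
    n2: float = 1.50  # dried biomass
    theta_deg: float = 45.0
    shift_amplitude: float = 7.0
    shift_reference: float = 1375.0
    reference_wavenumber: float = 1742.0  # d_p normalisation point

    def __post_init__(self) -> None:
        if np.sin(np.deg2rad(self.theta_deg)) <= self.n2 / self.n1:
            raise ValueError(
                f"total internal reflection requires sin(theta) > n2/n1 = "
                f"{self.n2 / self.n1:.3f}; theta = {self.theta_deg} deg is below the "
                "critical angle"
            )

    def depth_weight(self, wavenumber: float) -> float:
        """d_p(v) / d_p(reference): ATR band-intensity weighting."""
        return penetration_depth(self, wavenumber) / penetration_depth(
            self, self.reference_wavenumber
        )

    def center_shift(self, wavenumber: float) -> float:
        """Dispersive band-centre displacement, negative (toward lower v)."""
        return -self.shift_amplitude * (self.shift_reference / wavenumber) ** 2


def penetration_depth(model: ATROpticsModel, wavenumber) -> float | np.ndarray:
    """Evanescent-wave 1/e penetration depth in µm at the given wavenumber."""
    wavenumber = np.asarray(wavenumber, dtype=float)
    if np.any(wavenumber <= 0):
        raise ValueError("wavenumber must be positive")
    lam_um = 1.0e4 / wavenumber
    s = np.sin(np.deg2rad(model.theta_deg)) ** 2 - (model.n2 / model.n1) ** 2
    d = lam_um / (2.0 * np.pi * model.n1 * np.sqrt(s))
    return float(d) if d.ndim == 0 else d
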