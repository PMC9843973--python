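"""Forward model for AFM-IR scenes.

A scene is one scanned area of a fungal hypha lying on a flat substrate,
imaged at three QCL wavenumbers (1600, 1708, 1742 cm^-1). For each
wavenumber the instrument records topography (µm), a deflection error signal
and a photothermal absorption map. The generator plants, in acquisition
order, the artifacts the correction chain removes: a background tilt plane,
per-scan-line height offsets, inter-map rigid drift, contact-loss dropout
pixels, and the wavenumber-dependent laser power folded into the raw
absorption signal. Lipid droplets are Gaussian swellings enriched in TAG and
FFA; in flat hyphae they sit near the body edges, in swollen hyphae at the
centre. Ground truth (clean maps, transforms, droplet masks and planted
TAG:FFA ratios) is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..afmir_pipeline import RigidTransform, apply_rigid
from ..spectral_core import AFMIRMapSet, LaserPowerSpectrum, WavenumberAxis

__all__ = ["Droplet", "AFMIRSceneParams", "default_laser_power", "synth_afmir_scene", "synth_afmir_campaign"]

MAP_WAVENUMBERS = (1600.0, 1708.0, 1742.0)

#: Idealised relative absorptivities per species at the acquired wavenumbers.
#: The carbonyl bands of TAG (1742) and FFA (1708) are treated as fully
#: resolved at the QCL linewidth; the cell-wall matrix (beta-glucan COO-)
#: absorbs only at 1600.
DEFAULT_ABSORPTIVITY: dict[str, dict[float, float]] = {
    "TAG": {1742.0: 1.0, 1708.0: 0.0, 1600.0: 0.0},
    "FFA": {1742.0: 0.0, 1708.0: 1.0, 1600.0: 0.0},
    "matrix": {1742.0: 0.0, 1708.0: 0.0, 1600.0: 0.6},
}


@dataclass
class Droplet:
    row: float
    col: float
    radius: float  # px (Gaussian sigma)
    bump_height: float = 0.05  # µm of swelling added to the topography
    amplitude: float = 1.0  # total carbonyl absorption strength
    tag_ffa_ratio: float = 2.0


def random_drift(
    seed: int, max_shift: float = 4.0, max_rot: float = 4.0
) -> dict[float, tuple[float, float, float]]:
    """Random per-wavenumber rigid drift for the two moving maps."""
    rng = np.random.default_rng(seed)
    return {
        w: tuple(np.round(rng.uniform([-max_shift, -max_shift, -max_rot],
                                      [max_shift, max_shift, max_rot]), 2))
        for w in (1708.0, 1742.0)
    }


def default_laser_power() -> LaserPowerSpectrum:
    """Smooth QCL power curve over the 1500-1825 cm^-1 tuning range."""
    wn = np.arange(1500.0, 1826.0, 5.0)
    power = 0.5 + 0.5 * np.exp(-(((wn - 1650.0) / 180.0) ** 2))
    return LaserPowerSpectrum(WavenumberAxis(wn), power)


@dataclass
class AFMIRSceneParams:
    """Study conditions for one synthetic AFM-IR scene."""

    form: str = "flat_hypha"  # or "swollen_hypha"
    shape: tuple[int, int] = (96, 96)
    scan_size: float = 5.0  # µm
    body_height: float | None = None  # µm; default per form
    body_width_frac: float = 0.30  # body width as fraction of rows
    body_angle_deg: float = 45.0  # hypha axis orientation in the scan frame
    droplets: tuple[Droplet, ...] | None = None  # default per form
    tilt: tuple[float, float] = (0.3, -0.2)  # µm across the full image (x, y)
    line_offset_sd: float = 0.01  # µm
    drift: dict[float, tuple[float, float, float]] = field(
        default_factory=lambda: {1708.0: (2.0, -1.5, 1.5), 1742.0: (-1.8, 2.2, -2.0)}
    )
    contact_loss_rate: float = 0.005
    noise_sd_topo: float = 0.002  # µm
    noise_sd_abs: float = 0.01
    matrix_level: float = 1.0
    thick_sample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.form not in ("flat_hypha", "swollen_hypha"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.body_height is None:
            # cell-wall dominated thickness: ~150 nm flat, ~200 nm swollen
            self.body_height = 0.15 if self.form == "flat_hypha" else 0.20
        for w, (dx, dy, th) in self.drift.items():
            if abs(dx) > 10 or abs(dy) > 10 or abs(th) > 10:
                raise ValueError(f"drift at {w} exceeds +-10 px / +-10 deg")
        if not (0 <= self.contact_loss_rate < 1):
            raise ValueError("contact_loss_rate must be in [0, 1)")

    def zero_artifacts(self) -> "AFMIRSceneParams":
        """Copy with every planted artifact switched off (noise included)."""
        import dataclasses

        return dataclasses.replace(
            self,
            tilt=(0.0, 0.0),
            line_offset_sd=0.0,
            drift={},
            contact_loss_rate=0.0,
            noise_sd_topo=0.0,
            noise_sd_abs=0.0,
        )


def _default_droplets(params: AFMIRSceneParams) -> tuple[Droplet, ...]:
    rows, cols = params.shape
    cy, cx = rows / 2, cols / 2
    half_w = params.body_width_frac * rows / 2
    r = max(3.0, half_w * 0.45)
    a = np.deg2rad(params.body_angle_deg)
    ux, uy = np.cos(a), np.sin(a)  # along the body axis
    nx, ny = -uy, ux  # across the body
    along = min(rows, cols) * 0.28

    def at(t_along: float, t_across: float) -> tuple[float, float]:
        return (
            cy + t_along * uy * along / 28.0 + t_across * ny * half_w,
            cx + t_along * ux * along / 28.0 + t_across * nx * half_w,
        )

    if params.form == "flat_hypha":
        # droplet swellings near the body edges, with contrasting TAG:FFA
        p1, p2 = at(-10.0, -0.6), at(10.0, 0.6)
        return (
            Droplet(p1[0], p1[1], r, tag_ffa_ratio=2.0),
            Droplet(p2[0], p2[1], r, tag_ffa_ratio=0.5),
        )
    p1, p2 = at(-7.0, 0.0), at(8.0, 0.0)
    return (
        Droplet(p1[0], p1[1], r * 1.3, bump_height=0.08, tag_ffa_ratio=2.0),
        Droplet(p2[0], p2[1], r * 1.1, bump_height=0.06, tag_ffa_ratio=2.0),
    )


def synth_afmir_scene(
    params: AFMIRSceneParams,
    laser_power: LaserPowerSpectrum | None = None,
) -> tuple[AFMIRMapSet, dict]:
    """Generate one scene (9 maps: 3 roles x 3 wavenumbers) plus ground truth."""
    rows, cols = params.shape
    rng = np.random.default_rng(params.seed)
    power = laser_power or default_laser_power()
    droplets = params.droplets if params.droplets is not None else _default_droplets(params)

    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = rows / 2, cols / 2
    half_w = params.body_width_frac * rows / 2
    # oblique band-shaped body with a smooth parabolic cross-section; the
    # oblique orientation keeps substrate pixels on every scan line, as a
    # practitioner would frame the scan
    a = np.deg2rad(params.body_angle_deg)
    dist = np.abs(-(x - cx) * np.sin(a) + (y - cy) * np.cos(a))
    body_profile = np.clip(1.0 - (dist / half_w) ** 2, 0.0, 1.0)
    body = body_profile > 0
    clean_topo = params.body_height * body_profile

    droplet_mask = np.zeros((rows, cols), dtype=bool)
    droplet_fields = []
    for d in droplets:
        g = np.exp(-0.5 * (((y - d.row) / d.radius) ** 2 + ((x - d.col) / d.radius) ** 2))
        clean_topo += d.bump_height * g * body
        droplet_mask |= (g > 0.5) & body
        droplet_fields.append(g * body)

    thickness = np.clip(clean_topo / params.body_height, 0.0, None)
    clean_abs: dict[float, np.ndarray] = {}
    for w in MAP_WAVENUMBERS:
        ideal = params.matrix_level * DEFAULT_ABSORPTIVITY["matrix"][w] * thickness * body
        for d, g in zip(droplets, droplet_fields):
            tag = d.amplitude * d.tag_ffa_ratio / (1.0 + d.tag_ffa_ratio)
            ffa = d.amplitude / (1.0 + d.tag_ffa_ratio)
            ideal = ideal + (
                tag * DEFAULT_ABSORPTIVITY["TAG"][w] + ffa * DEFAULT_ABSORPTIVITY["FFA"][w]
            ) * g
        clean_abs[w] = ideal

    grad_y, grad_x = np.gradient(clean_topo)
    clean_defl = np.hypot(grad_x, grad_y)

    tilt_plane = params.tilt[0] * (x / max(cols - 1, 1)) + params.tilt[1] * (y / max(rows - 1, 1))

    maps: dict[float, dict[str, np.ndarray]] = {}
    transforms: dict[float, RigidTransform] = {}
    loss_masks: dict[float, np.ndarray] = {}
    for w in MAP_WAVENUMBERS:
        t = RigidTransform(*params.drift.get(w, (0.0, 0.0, 0.0)))
        transforms[w] = t
        topo = apply_rigid(clean_topo, t, cval=0.0)
        absm = apply_rigid(clean_abs[w], t, cval=0.0)
        defl = apply_rigid(clean_defl, t, cval=0.0)

        topo = topo + tilt_plane
        if params.line_offset_sd > 0:
            topo = topo + rng.normal(0.0, params.line_offset_sd, (rows, 1))
        if params.noise_sd_topo > 0:
            topo = topo + rng.normal(0.0, params.noise_sd_topo, (rows, cols))
            defl = defl + rng.normal(0.0, params.noise_sd_topo, (rows, cols))

        raw = power.at(w) * absm
        if params.noise_sd_abs > 0:
            raw = raw + rng.normal(0.0, params.noise_sd_abs, (rows, cols))
        loss = np.zeros((rows, cols), dtype=bool)
        if params.contact_loss_rate > 0:
            # the tip loses contact for a few consecutive pixels of a scan
            # line; dropouts are only observable where the sample produces
            # signal, so segments are planted on high-signal stretches
            seg_len = 5
            floor = max(10 * params.noise_sd_abs, 0.25 * np.percentile(raw, 99))
            ok = raw > floor
            runs_ok = np.all(
                [ok[:, j : cols - seg_len + 1 + j] for j in range(seg_len)], axis=0
            )
            starts = np.argwhere(runs_ok)
            n_seg = int(round(params.contact_loss_rate * ok.sum() / seg_len))
            if n_seg and len(starts):
                pick = rng.choice(len(starts), size=min(n_seg, len(starts)), replace=False)
                for r, c0 in starts[pick]:
                    loss[r, c0 : c0 + seg_len] = True
                raw[loss] = 0.0
        loss_masks[w] = loss
        maps[w] = {"topography": topo, "deflection": defl, "absorption": raw}

    meta = {"form": params.form, "thick_sample": params.thick_sample, "height_units": "um"}
    mapset = AFMIRMapSet(maps, params.scan_size, power, meta=meta)
    truth = {
        "clean_topography": clean_topo,
        "clean_deflection": clean_defl,
        "clean_absorption": clean_abs,  # laser-power-normalised scale
        "body": body,
        "droplet_mask": droplet_mask,
        "droplets": droplets,
        "transforms": transforms,
        "contact_loss": loss_masks,
    }
    return mapset, truth


def synth_afmir_campaign(
    seed: int = 0, n_samples: int = 2, areas_per_sample: int = 5
) -> list[tuple[AFMIRMapSet, dict]]:
    """The default imaging campaign: 2 samples x 5 areas x 3 wavenumbers.

    Sample 1 emulates the phosphate control (flat hyphae predominant),
    sample 2 the phosphate-starved culture (swollen hyphae predominant).
    """
    scenes = []
    for s in range(n_samples):
        form = "flat_hypha" if s == 0 else "swollen_hypha"
        for a in range(areas_per_sample):
            params = AFMIRSceneParams(form=form, seed=seed + 100 * s + a)
            mapset, truth = synth_afmir_scene(params)
            mapset.meta["sample"] = f"S{s + 1}"
            mapset.meta["area"] = a + 1
            scenes.append((mapset, truth))
    return scenes
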