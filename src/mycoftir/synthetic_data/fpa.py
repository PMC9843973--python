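"""Forward model for FPA-FTIR hyperspectral scenes.

A scene is a transmission-mode absorbance cube of fungal cells on a bare
slide. The fungus is dimorphic: the same culture contains flat hyphae,
swollen hyphae and yeast-like cells, whose stored-lipid content increases in
that order. Cell bodies are capsules (hyphae) or disks (yeast) of biomass
with TAG-enriched lipid droplets inside; each pixel's spectrum is a
Beer-Lambert mixture from the band library plus a smooth per-pixel scatter
baseline, channel noise, and planted dead/hot detector pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..spectral_core import HyperspectralCube, WavenumberAxis
from .bands import CHAIN_WEIGHT, UNSATURATION_WEIGHT, component_spectrum

__all__ = ["CellGeometry", "fpa_axis", "synth_fpa_scene", "default_scene_geometries"]

MAD_SCALE = 1.4826


def fpa_axis() -> WavenumberAxis:
    """Default FPA axis: 902-3892 cm^-1 at 10 cm^-1, 300 bands.

    The grid is offset so that every marker band used for segmentation and
    ratio maps falls within the ±4 cm^-1 band-selection tolerance.
    """
    return WavenumberAxis(np.arange(902.0, 3902.0, 10.0))


@dataclass
class CellGeometry:
    """One cell body placed in the image.

    ``form`` selects the shape: hyphae are capsules (segment of given length
    and width around ``center``, ``angle_deg`` orientation), yeast cells are
    disks of ``radius``. ``lipid_to_protein`` scales the TAG weight relative
    to protein; defaults per form enforce the flat < swollen < yeast lipid
    ordering observed across cell forms. ``droplets`` is a list of
    (row, col, radius_px) TAG-enriched inclusions.
    """

    form: str
    center: tuple[float, float]
    length: float = 60.0
    width: float = 12.0
    radius: float = 16.0
    angle_deg: float = 0.0
    lipid_to_protein: float | None = None
    droplets: tuple[tuple[float, float, float], ...] = ()

    _DEFAULT_LTP = {"flat_hypha": 0.5, "swollen_hypha": 1.1, "yeast": 2.2}

    def __post_init__(self) -> None:
        if self.form not in self._DEFAULT_LTP:
            raise ValueError(f"unknown form {self.form!r}")
        if self.lipid_to_protein is None:
            self.lipid_to_protein = self._DEFAULT_LTP[self.form]

    def mask(self, rows: int, cols: int) -> np.ndarray:
        y, x = np.mgrid[0:rows, 0:cols].astype(float)
        cy, cx = self.center
        if self.form == "yeast":
            m = (y - cy) ** 2 + (x - cx) ** 2 <= self.radius**2
        else:
            a = np.deg2rad(self.angle_deg)
            ux, uy = np.cos(a), np.sin(a)
            px, py = x - cx, y - cy
            t = np.clip(px * ux + py * uy, -self.length / 2, self.length / 2)
            d2 = (px - t * ux) ** 2 + (py - t * uy) ** 2
            m = d2 <= (self.width / 2) ** 2
        if not m.any():
            raise ValueError(f"{self.form} at {self.center} lies outside the image")
        return m


def default_scene_geometries(form: str, rows: int, cols: int) -> list[CellGeometry]:
    """A frame densely covered by one predominant cell form.

    Areas of interest are chosen on the microscope because they are full of
    cells, so the defaults cover roughly half the frame: a bundle of
    crossing hyphae, or a cluster of yeast cells.
    """
    cy, cx = rows / 2, cols / 2
    if form == "yeast":
        r = min(rows, cols) * 0.14
        cells = []
        for i, (fy, fx) in enumerate(
            [(0.25, 0.25), (0.25, 0.62), (0.30, 0.93), (0.55, 0.45), (0.62, 0.80),
             (0.80, 0.22), (0.85, 0.60)]
        ):
            rr = r * (0.8 + 0.06 * i)
            c = (rows * fy, cols * fx)
            cells.append(
                CellGeometry("yeast", c, radius=rr, droplets=((c[0], c[1], rr * 0.45),))
            )
        return cells
    width = min(rows, cols) * (0.16 if form == "flat_hypha" else 0.20)
    cells = []
    for frac, ang in [(0.25, 12.0), (0.53, 12.0), (0.81, 12.0)]:
        c = (rows * frac, cx)
        g = CellGeometry(form, c, length=cols * 1.4, width=width, angle_deg=ang)
        a = np.deg2rad(ang)
        g.droplets = tuple(
            (c[0] + t * np.sin(a) * cols * 0.6, c[1] + t * np.cos(a) * cols * 0.6, width * 0.28)
            for t in (-0.5, 0.0, 0.5)
        )
        cells.append(g)
    return cells


def _pixel_weights(
    geometries: list[CellGeometry],
    rows: int,
    cols: int,
    allow_overlap: bool,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Per-pixel component weight fields, foreground mask, droplet mask."""
    comps = ["TAG", "FFA", "FFA_ionized", "protein", "polysaccharide", "polyphosphate", "water"]
    W = {c: np.zeros((rows, cols)) for c in comps}
    fg = np.zeros((rows, cols), dtype=bool)
    droplet_mask = np.zeros((rows, cols), dtype=bool)
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    for g in geometries:
        m = g.mask(rows, cols)
        if fg[m].any() and not allow_overlap:
            raise ValueError("overlapping cell geometries (set allow_overlap=True to permit)")
        m = m & ~fg  # overlaps keep the first body's composition
        fg |= m
        protein = 0.22
        W["protein"][m] += protein
        W["TAG"][m] += protein * g.lipid_to_protein
        W["FFA"][m] += 0.03
        W["FFA_ionized"][m] += 0.02
        W["polysaccharide"][m] += 0.25
        W["polyphosphate"][m] += 0.04
        W["water"][m] += 0.10
        for dy, dx, dr in g.droplets:
            d = (y - dy) ** 2 + (x - dx) ** 2 <= dr**2
            d &= m
            droplet_mask |= d
            W["TAG"][d] += protein * g.lipid_to_protein * 1.5
            W["FFA"][d] += 0.05
    return W, fg, droplet_mask


def synth_fpa_scene(
    geometries: list[CellGeometry],
    rows: int = 128,
    cols: int = 128,
    axis: WavenumberAxis | None = None,
    noise_sd: float = 0.02,
    scatter_sd: float = 0.005,
    outlier_rate: float = 0.0,
    outlier_amplitude_mads: float = 10.0,
    global_dead_pixels: int = 0,
    allow_overlap: bool = False,
    seed: int = 0,
    pixel_size: float = 0.7,
) -> tuple[HyperspectralCube, dict]:
    """Generate a hyperspectral cube plus ground truth.

    Planted outliers are isolated (pixel, band) values displaced upward by
    ``outlier_amplitude_mads`` scaled MADs of their band image;
    ``global_dead_pixels`` pixels are additionally hot across all bands.
    Truth holds the clean cube, foreground/droplet masks, the per-component
    weight fields and the planted outlier coordinates.
    """
    axis = axis or fpa_axis()
    rng = np.random.default_rng(seed)
    W, fg, droplets = _pixel_weights(geometries, rows, cols, allow_overlap)

    comp_spectra = {}
    for comp in list(W) + ["CH_chain", "unsaturation"]:
        comp_spectra[comp] = component_spectrum(comp, axis)
    acyl = W["TAG"] + W["FFA"]
    weights = dict(W)
    weights["CH_chain"] = CHAIN_WEIGHT * acyl
    weights["unsaturation"] = UNSATURATION_WEIGHT * acyl

    n_px, n_b = rows * cols, len(axis)
    Wmat = np.column_stack([weights[c].reshape(-1) for c in weights])
    Cmat = np.vstack([comp_spectra[c] for c in weights])
    clean = (Wmat @ Cmat).reshape(rows, cols, n_b)

    # smooth per-pixel scatter baseline (quadratic in the axis); every pixel
    # scatters a little (slide texture), cells twice as much
    t = np.linspace(-1.0, 1.0, n_b)
    scale = scatter_sd * (1.0 + fg)
    b0 = rng.normal(0.0, 1.0, n_px).reshape(rows, cols) * scale
    b1 = rng.normal(0.0, 1.0, n_px).reshape(rows, cols) * scale
    b2 = rng.normal(0.0, 1.0, n_px).reshape(rows, cols) * scale
    baseline = (
        b0[:, :, None] + b1[:, :, None] * t[None, None, :] + b2[:, :, None] * t[None, None, :] ** 2
    )

    values = clean + baseline + rng.normal(0.0, noise_sd, clean.shape)

    outliers = np.zeros(values.shape, dtype=bool)
    if outlier_rate > 0:
        n_out = int(round(outlier_rate * values.size))
        flat = rng.choice(values.size, size=n_out, replace=False)
        outliers.reshape(-1)[flat] = True
        flat_vals = values.reshape(-1, n_b)
        med = np.median(flat_vals, axis=0)
        mad = MAD_SCALE * np.median(np.abs(flat_vals - med), axis=0)
        idx = np.argwhere(outliers)
        # hot-pixel artifact: displacement added on top of the true signal
        values[idx[:, 0], idx[:, 1], idx[:, 2]] += outlier_amplitude_mads * mad[idx[:, 2]]
    global_pixels = np.zeros((rows, cols), dtype=bool)
    if global_dead_pixels > 0:
        flat = rng.choice(n_px, size=global_dead_pixels, replace=False)
        global_pixels.reshape(-1)[flat] = True
        flat_vals = values.reshape(-1, n_b)
        med = np.median(flat_vals, axis=0)
        mad = MAD_SCALE * np.median(np.abs(flat_vals - med), axis=0)
        for p in flat:
            values.reshape(-1, n_b)[p] += outlier_amplitude_mads * mad

    cube = HyperspectralCube(values, axis, pixel_size)
    truth = {
        "clean": HyperspectralCube(clean + baseline, axis, pixel_size),
        "foreground": fg,
        "droplets": droplets,
        "weights": weights,
        "outliers": outliers,
        "global_pixels": global_pixels,
    }
    return cube, truth
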