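"""Domain types and on-disk formats for multiscale IR data.

Conventions used throughout the package:

* wavenumber axes are stored ascending in cm^-1 (instrument files may be
  descending; readers normalise),
* absorbance is unitless,
* images are 0-based, row-major, origin top-left; AFM scan lines are rows,
* disk storage is float32, in-memory arrays are float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "SpectrumCollection",
    "BandDefinition",
    "HyperspectralCube",
    "LaserPowerSpectrum",
    "AFMIRMapSet",
    "read_spectra",
    "write_spectra",
    "read_cube",
    "write_cube",
    "read_afmir_set",
    "write_afmir_set",
]

SIDECAR_COLUMNS = ("spectrum_id", "technique", "sample", "pi_level", "replicate", "day")


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(np.asarray(arr)))
        raise ValueError(f"{what} contains non-finite values, first at index {tuple(bad[0])}")


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis must be a 1-D array of length >= 2")
        _check_finite(values, "wavenumber axis")
        if np.any(values <= 0):
            raise ValueError("wavenumbers must be positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing (duplicates?)")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def resolution(self) -> float:
        """Nominal grid spacing (median step), cm^-1."""
        return float(np.median(np.diff(self.values)))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def index_of(self, wavenumber: float, tol: float | None = None) -> int:
        """Index of the grid point nearest to `wavenumber`.

        With `tol` set, raise if the nearest point is farther than `tol` cm^-1.
        """
        i = int(np.argmin(np.abs(self.values - wavenumber)))
        if tol is not None and abs(self.values[i] - wavenumber) > tol:
            raise ValueError(
                f"no grid point within {tol} cm^-1 of {wavenumber} "
                f"(nearest: {self.values[i]:.1f})"
            )
        return i

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.shape, float(self.values[0]), float(self.values[-1])))


@dataclass
class Spectrum:
    """A single absorbance spectrum with design metadata.

    `meta` keys follow the sidecar columns: technique (HTS / ATR /
    AFMIR_POINT), sample, pi_level, replicate, day.
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.axis),):
            raise ValueError(
                f"intensity length {self.intensities.shape} does not match axis length {len(self.axis)}"
            )
        _check_finite(self.intensities, "spectrum intensities")

    def at(self, wavenumber: float) -> float:
        """Absorbance at the nearest grid point."""
        return float(self.intensities[self.axis.index_of(wavenumber)])


class SpectrumCollection:
    """An ordered set of spectra on one shared axis.

    Stored internally as a (n_spectra, n_channels) float64 matrix plus a
    metadata DataFrame with one row per spectrum.
    """

    def __init__(self, axis: WavenumberAxis, matrix: np.ndarray, metadata: pd.DataFrame):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != len(axis):
            raise ValueError("matrix must be (n_spectra, n_channels) matching the axis")
        if len(metadata) != matrix.shape[0]:
            raise ValueError("metadata rows must match spectrum count")
        _check_finite(matrix, "spectral matrix")
        self.axis = axis
        self.matrix = matrix
        self.metadata = metadata.reset_index(drop=True)

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumCollection":
        if not spectra:
            raise ValueError("empty spectrum list")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if s.axis != axis:
                raise ValueError("all spectra must share one axis")
        matrix = np.vstack([s.intensities for s in spectra])
        metadata = pd.DataFrame([s.meta for s in spectra])
        return cls(axis, matrix, metadata)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.matrix[i], dict(self.metadata.iloc[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.axis, self.matrix.mean(axis=0), {"technique": "mean"})

    def with_matrix(self, matrix: np.ndarray) -> "SpectrumCollection":
        """Same axis/metadata, new intensity matrix."""
        return SpectrumCollection(self.axis, matrix, self.metadata.copy())

    def subset(self, mask: np.ndarray) -> "SpectrumCollection":
        mask = np.asarray(mask)
        return SpectrumCollection(self.axis, self.matrix[mask], self.metadata.loc[mask])


@dataclass(frozen=True)
class BandDefinition:
    """One absorption band: Gaussian centre/width plus its chemical assignment."""

    center: float
    half_width: float
    relative_amplitude: float
    component: str
    assignment: str = ""

    def __post_init__(self) -> None:
        if not (400.0 <= self.center <= 4000.0):
            raise ValueError(f"band centre {self.center} outside 4000-400 cm^-1")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.relative_amplitude < 0:
            raise ValueError("relative_amplitude must be >= 0")


class HyperspectralCube:
    """(rows, cols, n_wavenumbers) absorbance image from an FPA detector."""

    def __init__(
        self,
        values: np.ndarray,
        axis: WavenumberAxis,
        pixel_size: float = 0.7,
    ):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValueError("cube values must be 3-D (rows, cols, bands)")
        if values.shape[2] != len(axis):
            raise ValueError("band count does not match axis length")
        self.values = values
        self.axis = axis
        self.pixel_size = float(pixel_size)

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    def band_image(self, wavenumber: float, tol: float | None = None) -> np.ndarray:
        """The 2-D image at the nearest acquired band."""
        return self.values[:, :, self.axis.index_of(wavenumber, tol=tol)]

    def as_pixel_matrix(self) -> np.ndarray:
        """(n_pixels, n_bands) view, row-major pixel order."""
        return self.values.reshape(-1, self.values.shape[2])


@dataclass
class LaserPowerSpectrum:
    """Relative QCL output power over the tunable range."""

    axis: WavenumberAxis
    power: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.axis),):
            raise ValueError("power length must match axis")
        if np.any(self.power <= 0) or not np.all(np.isfinite(self.power)):
            raise ValueError("laser power must be strictly positive and finite")

    def at(self, wavenumber: float) -> float:
        lo, hi = self.axis.span
        if not (lo <= wavenumber <= hi):
            raise ValueError(f"wavenumber {wavenumber} outside laser power range {lo}-{hi}")
        return float(np.interp(wavenumber, self.axis.values, self.power))


ROLES = ("topography", "deflection", "absorption")


class AFMIRMapSet:
    """Co-registered AFM-IR maps: per acquired wavenumber a topography,
    deflection and absorption image, plus the laser-power background spectrum.

    Topography is in µm, deflection and absorption in instrument units.
    """

    def __init__(
        self,
        maps: Mapping[float, Mapping[str, np.ndarray]],
        scan_size: float,
        laser_power: LaserPowerSpectrum,
        meta: dict | None = None,
    ):
        wavenumbers = sorted(float(w) for w in maps)
        if len(wavenumbers) != len(set(wavenumbers)):
            raise ValueError("wavenumbers must be distinct")
        shape = None
        store: dict[float, dict[str, np.ndarray]] = {}
        for w in wavenumbers:
            entry = {}
            for role in ROLES:
                if role not in maps[w]:
                    raise ValueError(f"missing {role} map at {w} cm^-1")
                m = np.asarray(maps[w][role], dtype=float)
                if m.ndim != 2:
                    raise ValueError("maps must be 2-D")
                if shape is None:
                    shape = m.shape
                elif m.shape != shape:
                    raise ValueError(f"{role} map at {w} has shape {m.shape}, expected {shape}")
                entry[role] = m
            store[w] = entry
        lo, hi = laser_power.axis.span
        for w in wavenumbers:
            if not (lo <= w <= hi):
                raise ValueError(f"map wavenumber {w} outside laser-power range {lo}-{hi}")
        self.maps = store
        self.wavenumbers = wavenumbers
        self.shape = shape
        self.scan_size = float(scan_size)
        self.laser_power = laser_power
        self.meta = dict(meta or {})

    @property
    def pixel_pitch(self) -> float:
        """µm per pixel along a scan line."""
        return self.scan_size / self.shape[1]

    def get(self, wavenumber: float, role: str) -> np.ndarray:
        return self.maps[float(wavenumber)][role]

    def replace(self, wavenumber: float, role: str, data: np.ndarray) -> None:
        data = np.asarray(data, dtype=float)
        if data.shape != self.shape:
            raise ValueError("replacement map shape mismatch")
        self.maps[float(wavenumber)][role] = data


# ---------------------------------------------------------------------------
# Readers / writers


def _normalise_axis(values: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort a (possibly descending) axis ascending, carrying the data along."""
    order = np.argsort(values)
    return values[order], matrix[order]


def read_spectra(path: str | Path, meta_path: str | Path) -> SpectrumCollection:
    """Read a delimited-text spectral matrix plus its metadata sidecar.

    The data file is CSV with a header row: first column wavenumbers, one
    column per spectrum. The sidecar is CSV keyed on ``spectrum_id`` matching
    the data column names.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("spectral file needs a wavenumber column plus >= 1 spectrum column")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    _check_finite(wn, "wavenumber column")
    _check_finite(data, f"spectral data in {path}")
    wn, data = _normalise_axis(wn, data)
    axis = WavenumberAxis(wn)

    sidecar = pd.read_csv(meta_path, dtype={"spectrum_id": str})
    sidecar = sidecar.set_index("spectrum_id")
    columns = [str(c) for c in df.columns[1:]]
    missing = [c for c in columns if c not in sidecar.index]
    if missing:
        raise ValueError(f"sidecar missing spectrum ids: {missing}")
    meta = sidecar.loc[columns].reset_index()
    return SpectrumCollection(axis, data.T, meta)


def write_spectra(
    coll: SpectrumCollection,
    path: str | Path,
    meta_path: str | Path | None = None,
    descending: bool = False,
) -> None:
    """Write a collection as CSV matrix + sidecar (float32 precision on disk).

    ``descending=True`` emits the axis high-to-low, instrument style;
    ``read_spectra`` normalises either orientation back.
    """
    if len(coll) == 0:
        raise ValueError("cannot write an empty collection")
    ids = [
        str(coll.metadata["spectrum_id"].iloc[i])
        if "spectrum_id" in coll.metadata.columns
        else f"s{i:04d}"
        for i in range(len(coll))
    ]
    wn = coll.axis.values
    mat = coll.matrix.T.astype(np.float32)
    if descending:
        wn, mat = wn[::-1], mat[::-1]
    out = pd.DataFrame(mat, columns=ids)
    out.insert(0, "wavenumber", wn.astype(np.float32))
    out.to_csv(path, index=False)
    if meta_path is not None:
        meta = coll.metadata.copy()
        meta["spectrum_id"] = ids
        cols = ["spectrum_id"] + [c for c in meta.columns if c != "spectrum_id"]
        meta[cols].to_csv(meta_path, index=False)


def read_cube(header_path: str | Path) -> HyperspectralCube:
    """Read a cube stored as JSON header + raw little-endian float32 payload.

    The payload is band-sequential: band 0 image first, row-major within a
    band. The header declares rows, cols, pixel_size_um, wavenumbers and the
    raw file name (relative to the header).
    """
    header_path = Path(header_path)
    header = json.loads(header_path.read_text())
    rows, cols = int(header["rows"]), int(header["cols"])
    wn = np.asarray(header["wavenumbers"], dtype=float)
    raw_path = header_path.parent / header["raw_file"]
    payload = np.fromfile(raw_path, dtype="<f4")
    expected = rows * cols * wn.size
    if payload.size != expected:
        raise ValueError(
            f"raw payload has {payload.size} values, expected {expected} "
            f"({rows}x{cols}x{wn.size})"
        )
    cube = payload.reshape(wn.size, rows, cols).transpose(1, 2, 0).astype(float)
    _check_finite(cube, f"cube payload {raw_path}")
    wn_sorted, planes = _normalise_axis(wn, cube.transpose(2, 0, 1))
    return HyperspectralCube(
        planes.transpose(1, 2, 0), WavenumberAxis(wn_sorted), float(header.get("pixel_size_um", 0.7))
    )


def write_cube(cube: HyperspectralCube, header_path: str | Path) -> None:
    header_path = Path(header_path)
    raw_name = header_path.with_suffix(".raw").name
    header = {
        "rows": cube.rows,
        "cols": cube.cols,
        "n_wavenumbers": len(cube.axis),
        "pixel_size_um": cube.pixel_size,
        "byte_order": "little",
        "dtype": "float32",
        "layout": "band-sequential, row-major within band",
        "wavenumbers": cube.axis.values.tolist(),
        "raw_file": raw_name,
    }
    header_path.write_text(json.dumps(header, indent=1))
    payload = cube.values.transpose(2, 0, 1).astype("<f4")
    payload.tofile(header_path.parent / raw_name)


def read_afmir_set(dir_path: str | Path) -> AFMIRMapSet:
    """Read an AFM-IR scene directory.

    Layout: ``meta.json`` (scan_size_um, wavenumbers, free-form metadata),
    ``<role>_<wavenumber>.tsv`` matrices for each role in
    topography/deflection/absorption, and ``laser_power.csv`` (wavenumber,
    power).
    """
    dir_path = Path(dir_path)
    meta = json.loads((dir_path / "meta.json").read_text())
    wavenumbers = [float(w) for w in meta["wavenumbers"]]
    power_df = pd.read_csv(dir_path / "laser_power.csv")
    wn = power_df.iloc[:, 0].to_numpy(dtype=float)
    pw = power_df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(wn)
    laser = LaserPowerSpectrum(WavenumberAxis(wn[order]), pw[order])
    maps: dict[float, dict[str, np.ndarray]] = {}
    for w in wavenumbers:
        entry = {}
        for role in ROLES:
            f = dir_path / f"{role}_{w:g}.tsv"
            if not f.exists():
                raise FileNotFoundError(f"missing {role} map for {w:g} cm^-1: {f}")
            m = np.loadtxt(f, delimiter="\t", ndmin=2)
            _check_finite(m, f"{f.name}")
            entry[role] = m
        maps[w] = entry
    extra = {k: v for k, v in meta.items() if k not in ("wavenumbers", "scan_size_um")}
    return AFMIRMapSet(maps, float(meta["scan_size_um"]), laser, meta=extra)


def write_afmir_set(mapset: AFMIRMapSet, dir_path: str | Path) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    meta = {"scan_size_um": mapset.scan_size, "wavenumbers": mapset.wavenumbers, **mapset.meta}
    (dir_path / "meta.json").write_text(json.dumps(meta, indent=1))
    pd.DataFrame(
        {
            "wavenumber": mapset.laser_power.axis.values,
            "power": mapset.laser_power.power,
        }
    ).to_csv(dir_path / "laser_power.csv", index=False)
    for w in mapset.wavenumbers:
        for role in ROLES:
            np.savetxt(
                dir_path / f"{role}_{w:g}.tsv",
                mapset.get(w, role).astype(np.float32),
                delimiter="\t",
                fmt="%.7g",
            )
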