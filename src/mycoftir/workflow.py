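"""Reproducible end-to-end runs for the three measurement scales.

Each run consumes a config (YAML file or dict), executes the corresponding
pipeline, writes machine-readable outputs (CSV/TSV/JSON) into the output
directory together with a resolved copy of the config and a manifest
(input hashes, parameters, package version, seed), so that identical
config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .afmir_pipeline import correct_mapset, log_ratio_maps, segment_afmir
from .anova_pca import build_design, contributions, decompose, effect_pca
from .fpa_pipeline import (
    SEGMENTATION_BANDS,
    band_and_ratio_maps,
    descatter,
    flag_outliers,
    repair_outliers,
    segment_cube,
    trim_cube,
)
from .instrument_compare import align_axes, band_ratios, match_peaks, pick_peaks
from .preprocess import (
    REGION_PRESETS,
    SGParams,
    emsc_fit_correct,
    savitzky_golay_collection,
    select_region,
)
from .spectral_core import read_afmir_set, read_cube, read_spectra, write_spectra

__all__ = ["load_config", "run_bulk", "run_fpa", "run_afmir"]


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, config: dict, inputs: list[Path], extra: dict) -> None:
    manifest = {
        "version": __version__,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (outdir / "config.resolved.yaml").write_text(yaml.safe_dump(config))


def _sg_from(cfg: dict, default=(15, 2, 2)) -> SGParams:
    return SGParams(
        cfg.get("sg", {}).get("window", default[0]),
        cfg.get("sg", {}).get("polyorder", default[1]),
        cfg.get("sg", {}).get("deriv", default[2]),
    )


def run_bulk(config: dict) -> dict:
    """Bulk workflow: preprocess -> ANOVA-PCA per region -> HTS/ATR comparison.

    Config keys: ``atr`` / ``atr_meta`` and optionally ``hts`` / ``hts_meta``
    (CSV paths), ``outdir``, ``regions`` (preset names), ``factors``
    (metadata columns, default condition=sample and day), ``emsc.poly_order``,
    ``sg.*``, ``seed``.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = [Path(config[k]) for k in ("atr", "atr_meta", "hts", "hts_meta") if k in config]
    for p in inputs:
        if not p.exists():
            raise FileNotFoundError(f"input missing before compute: {p}")

    atr = read_spectra(config["atr"], config["atr_meta"])
    factors = config.get("factors", ["sample", "day"])
    regions = config.get("regions", ["lipid_combined", "protein", "mixed", "polysaccharide"])
    poly_order = config.get("emsc", {}).get("poly_order", 2)

    report: dict = {"n_atr": len(atr)}
    contrib_rows = []
    for region in regions:
        sub = select_region(atr, REGION_PRESETS[region])
        if config.get("second_derivative", False):
            sub = savitzky_golay_collection(sub, _sg_from(config))
        corr, _ = emsc_fit_correct(sub, poly_order=poly_order)
        dA = build_design(list(sub.metadata[factors[0]]), factors[0])
        dB = build_design(list(sub.metadata[factors[1]]), factors[1])
        dec = decompose(corr.matrix, dA, dB)
        con = contributions(dec)
        t = con.table.copy()
        t["region"] = region
        contrib_rows.append(t.reset_index(names="partition"))
        for factor in factors:
            pca = effect_pca(dec, factor, n_components=2)
            pca.scores.to_csv(outdir / f"scores_{region}_{factor}.csv", index=False)
            pd.DataFrame(pca.loadings).to_csv(
                outdir / f"loadings_{region}_{factor}.csv", index=False
            )
    pd.concat(contrib_rows).to_csv(outdir / "contributions.csv", index=False)

    if "hts" in config:
        hts = read_spectra(config["hts"], config["hts_meta"])
        report["n_hts"] = len(hts)
        day1 = atr.subset((atr.metadata["day"] == 1).to_numpy())
        h, a = align_axes(hts, day1)
        hc, _ = emsc_fit_correct(h, poly_order=2)
        ac, _ = emsc_fit_correct(a, poly_order=2)
        peak_rows, match_rows = [], []
        for region in regions:
            ph = pick_peaks(hc.mean_spectrum(), REGION_PRESETS[region], instrument="HTS",
                            region_label=region)
            pa = pick_peaks(ac.mean_spectrum(), REGION_PRESETS[region], instrument="ATR",
                            region_label=region)
            for pl in (ph, pa):
                t = pl.table.copy()
                t["region"], t["instrument"] = region, pl.instrument
                peak_rows.append(t)
            mt = match_peaks(ph, pa).table
            mt["region"] = region
            match_rows.append(mt)
        pd.concat(peak_rows).to_csv(outdir / "peaks.csv", index=False)
        pd.concat(match_rows).to_csv(outdir / "matches.csv", index=False)
        pd.concat(
            [band_ratios(h, instrument="HTS").table, band_ratios(a, instrument="ATR").table]
        ).to_csv(outdir / "ratios.csv", index=False)

    _write_manifest(outdir, config, inputs, {"report": report})
    return report


def run_fpa(config: dict) -> dict:
    """FPA workflow: trim -> outlier repair -> segmentation -> descatter ->
    band/ratio maps with a QC report.

    Config keys: ``cube`` (JSON header path), ``outdir``, ``bands``,
    ``ratio_pairs`` (list of [num, den]), ``seed``.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    cube_path = Path(config["cube"])
    if not cube_path.exists():
        raise FileNotFoundError(f"input missing before compute: {cube_path}")

    cube = trim_cube(read_cube(cube_path))
    mask = flag_outliers(cube)
    repaired = repair_outliers(cube, mask)
    seed = int(config.get("seed", 0))
    bands = tuple(config.get("bands", SEGMENTATION_BANDS))
    seg = segment_cube(repaired, bands=bands, seed=seed)
    corrected = descatter(repaired, seg)
    pairs = tuple(tuple(p) for p in config.get("ratio_pairs", [(1742.0, 1650.0)]))
    band_images, ratio_maps_ = band_and_ratio_maps(corrected, seg, bands=bands, ratio_pairs=pairs)

    for w, img in band_images.items():
        np.savetxt(outdir / f"band_{w:g}.tsv", img.astype(np.float32), delimiter="\t", fmt="%.6g")
    np.savetxt(outdir / "mask.tsv", seg.foreground.astype(int), delimiter="\t", fmt="%d")
    for rm in ratio_maps_:
        np.savetxt(
            outdir / f"ratio_{rm.numerator:g}_{rm.denominator:g}.tsv",
            rm.values.astype(np.float32),
            delimiter="\t",
            fmt="%.6g",
        )
    report = {
        "n_pixels": cube.n_pixels,
        "n_bands": len(cube.axis),
        "outlier_values_flagged": int(mask.n_flagged),
        "global_outlier_pixels": int(mask.global_pixels.sum()),
        "foreground_pixels": int(seg.n_foreground),
        "foreground_fraction": float(seg.foreground.mean()),
        "ratio_flagged_pixels": {f"{r.numerator:g}/{r.denominator:g}": r.n_flagged for r in ratio_maps_},
    }
    (outdir / "qc_report.json").write_text(json.dumps(report, indent=1))
    _write_manifest(outdir, config, [cube_path], {"report": report})
    return report


def run_afmir(config: dict) -> dict:
    """AFM-IR workflow: correction chain -> segmentation -> log-ratio maps.

    Config keys: ``scene`` (directory), ``outdir``, ``fixed`` (wavenumber,
    default 1600), ``ratio_pairs``, ``seed``.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    scene = Path(config["scene"])
    if not scene.exists():
        raise FileNotFoundError(f"input missing before compute: {scene}")

    mapset = read_afmir_set(scene)
    fixed = float(config.get("fixed", 1600.0))
    corrected, transforms = correct_mapset(mapset, fixed_wavenumber=fixed)
    seg = segment_afmir(corrected, seed=int(config.get("seed", 0)))
    pairs = tuple(tuple(p) for p in config.get("ratio_pairs", [(1742.0, 1600.0), (1708.0, 1600.0)]))
    ratios = log_ratio_maps(corrected, seg, pairs=pairs)

    (outdir / "transforms.json").write_text(
        json.dumps({f"{w:g}": t.as_dict() for w, t in transforms.items()}, indent=1)
    )
    for w in corrected.wavenumbers:
        for role in ("topography", "deflection", "absorption"):
            np.savetxt(
                outdir / f"corrected_{role}_{w:g}.tsv",
                corrected.get(w, role).astype(np.float32),
                delimiter="\t",
                fmt="%.6g",
            )
    np.savetxt(outdir / "mask.tsv", seg.foreground.astype(int), delimiter="\t", fmt="%d")
    masked_report = {}
    for r in ratios:
        tag = (
            f"logratio_{r.numerator:g}_{r.denominator:g}"
            if r.denominator is not None
            else f"log_abs_over_topo_{r.numerator:g}"
        )
        np.savetxt(outdir / f"{tag}.tsv", r.values.astype(np.float32), delimiter="\t", fmt="%.6g")
        masked_report[tag] = r.n_masked
    report = {
        "foreground_pixels": int(seg.n_foreground),
        "transforms": {f"{w:g}": t.as_dict() for w, t in transforms.items()},
        "masked_pixels": masked_report,
    }
    (outdir / "qc_report.json").write_text(json.dumps(report, indent=1))
    _write_manifest(outdir, config, [scene / "meta.json"], {"report": report})
    return report
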