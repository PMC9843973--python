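"""ANOVA-PCA: partition a spectral matrix by experimental design, then PCA.

The data matrix X (n_spectra x n_channels) is decomposed into

    X = 1 * grand_mean + E_A + E_B + E_AB + R

where E_A rows hold (level-of-A mean - grand mean) for each spectrum's level,
E_B analogously, E_AB holds the cell interaction (cell mean - A mean - B mean
+ grand mean), and R is the remainder. For a balanced two-factor design these
partitions are mutually orthogonal, so the total (centred) sum of squares
splits additively and each factor's share of variation can be reported.
Each factor's partition plus the residual is then projected by PCA so that
scores can be inspected for grouping by that factor's levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix",
    "EffectDecomposition",
    "EffectContribution",
    "PCAResult",
    "build_design",
    "decompose",
    "contributions",
    "effect_pca",
]


@dataclass
class DesignMatrix:
    """One-hot indicator matrix (n_spectra x n_levels) for a single factor."""

    factor: str
    indicator: np.ndarray
    levels: list

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator, dtype=float)
        if ind.ndim != 2 or not np.allclose(ind.sum(axis=1), 1.0):
            raise ValueError("each spectrum must belong to exactly one level")
        if np.any(ind.sum(axis=0) < 1):
            raise ValueError("every level needs at least one spectrum")
        self.indicator = ind

    @property
    def n_levels(self) -> int:
        return self.indicator.shape[1]

    @property
    def assignments(self) -> np.ndarray:
        return self.indicator.argmax(axis=1)


@dataclass
class EffectDecomposition:
    grand_mean: np.ndarray
    effects: dict[str, np.ndarray]  # factor name -> (n_spectra, n_channels)
    interaction: np.ndarray
    residual: np.ndarray
    X: np.ndarray
    designs: dict[str, DesignMatrix]

    def reconstruct(self) -> np.ndarray:
        out = np.broadcast_to(self.grand_mean, self.X.shape).copy()
        for eff in self.effects.values():
            out += eff
        return out + self.interaction + self.residual


@dataclass
class EffectContribution:
    """Sum of squares and fractional contribution per partition."""

    table: pd.DataFrame  # index: partition name; columns: ss, fraction


@dataclass
class PCAResult:
    scores: pd.DataFrame  # columns PC1.. + factor level labels
    loadings: np.ndarray  # (n_components, n_channels)
    explained_variance_ratio: np.ndarray


def build_design(labels: Sequence, factor: str = "factor") -> DesignMatrix:
    """Indicator matrix with levels in first-appearance order."""
    labels = list(labels)
    levels: list = []
    for lab in labels:
        if lab not in levels:
            levels.append(lab)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels, got {levels}")
    index = {lev: j for j, lev in enumerate(levels)}
    ind = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        ind[i, index[lab]] = 1.0
    return DesignMatrix(factor, ind, levels)


def _level_means(X: np.ndarray, d: DesignMatrix) -> np.ndarray:
    counts = d.indicator.sum(axis=0)
    return (d.indicator.T @ X) / counts[:, None]


def decompose(X: np.ndarray, dA: DesignMatrix, dB: DesignMatrix) -> EffectDecomposition:
    """Two-factor cell-means effect partitioning of X.

    Raises on empty design cells (the interaction estimate is undefined there).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if dA.indicator.shape[0] != n or dB.indicator.shape[0] != n:
        raise ValueError("design row counts must match X")
    a, b = dA.assignments, dB.assignments
    cell_counts = np.zeros((dA.n_levels, dB.n_levels), dtype=int)
    np.add.at(cell_counts, (a, b), 1)
    if np.any(cell_counts == 0):
        empty = [
            (dA.levels[i], dB.levels[j])
            for i, j in zip(*np.nonzero(cell_counts == 0))
        ]
        raise ValueError(f"empty design cells (A-level, B-level): {empty}")

    grand = X.mean(axis=0)
    mA = _level_means(X, dA) - grand  # (nA, channels)
    mB = _level_means(X, dB) - grand
    # cell means via flat one-hot on (a, b)
    cell_sum = np.zeros((dA.n_levels * dB.n_levels, X.shape[1]))
    flat = a * dB.n_levels + b
    np.add.at(cell_sum, flat, X)
    cell_mean = cell_sum / cell_counts.reshape(-1)[:, None]

    eff_a = mA[a]
    eff_b = mB[b]
    inter = cell_mean[flat] - eff_a - eff_b - grand
    resid = X - grand - eff_a - eff_b - inter
    return EffectDecomposition(
        grand, {dA.factor: eff_a, dB.factor: eff_b}, inter, resid, X, {dA.factor: dA, dB.factor: dB}
    )


def contributions(dec: EffectDecomposition) -> EffectContribution:
    """Per-partition sums of squares and their fractions of the centred total."""
    parts = {**dec.effects, "interaction": dec.interaction, "residual": dec.residual}
    ss = {name: float(np.sum(mat**2)) for name, mat in parts.items()}
    total = sum(ss.values())
    if total == 0:
        raise ValueError("all partitions are zero (constant X); contributions undefined")
    table = pd.DataFrame(
        {"ss": pd.Series(ss), "fraction": pd.Series({k: v / total for k, v in ss.items()})}
    )
    return EffectContribution(table)


def effect_pca(dec: EffectDecomposition, factor: str, n_components: int = 2) -> PCAResult:
    """PCA (SVD of the column-centred matrix) of effect(factor) + residual."""
    if factor not in dec.effects:
        raise KeyError(f"factor {factor!r} not in decomposition {list(dec.effects)}")
    M = dec.effects[factor] + dec.residual
    M = M - M.mean(axis=0)
    rank = np.linalg.matrix_rank(M)
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds matrix rank {rank}")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    var = S**2
    evr = var[:n_components] / var.sum()
    d = dec.designs[factor]
    df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(n_components)])
    df["level"] = [d.levels[k] for k in d.assignments]
    return PCAResult(df, Vt[:n_components], evr)
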