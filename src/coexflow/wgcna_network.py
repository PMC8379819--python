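"""Weighted network construction: correlations, soft threshold, TOM.

The adjacency is the elementwise power of the absolute Pearson correlation,
A_ij = |cor(x_i, x_j)|^beta (unsigned network).  The soft threshold beta is
chosen by scanning a power grid for approximate scale-free topology: the
log-log regression of binned degree frequency on degree must reach a signed
fit index R^2 of at least ``r2_cut``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SoftThresholdScan",
    "correlation_matrix",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom_similarity",
]


@dataclass
class SoftThresholdScan:
    """Power-scan table plus the chosen soft-threshold power."""

    table: pd.DataFrame  # power, r2_signed, slope, mean_k, median_k, max_k
    chosen_power: int
    r2_cut: float


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation matrix from a genes-x-samples table."""
    if expr.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    vals = expr.to_numpy(float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0][0]
        raise ValueError(f"gene '{bad}' has zero variance; remove constant genes first")
    cor = np.corrcoef(vals)
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def adjacency(cor: pd.DataFrame | np.ndarray, beta: float) -> pd.DataFrame | np.ndarray:
    """Unsigned weighted adjacency |cor|^beta with unit diagonal."""
    if beta <= 0:
        raise ValueError("soft-threshold power beta must be > 0")
    if isinstance(cor, pd.DataFrame):
        adj = np.abs(cor.to_numpy(float)) ** beta
        np.fill_diagonal(adj, 1.0)
        return pd.DataFrame(adj, index=cor.index, columns=cor.columns)
    adj = np.abs(np.asarray(cor, float)) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def connectivity(adj: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} A_ij."""
    a = adj.to_numpy(float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    return a.sum(axis=1) - np.diag(a)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index of a connectivity vector.

    Bins k into ``n_bins`` equal-width bins, regresses log10 frequency on
    log10 mean connectivity over non-empty bins, and returns
    (R2_signed, slope) where R2_signed = -sign(slope) * R^2.  Returns
    (nan, nan) when fewer than 3 non-empty bins with positive mean k exist.
    """
    k = np.asarray(k, float)
    if len(np.unique(k)) < n_bins:
        return np.nan, np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.full(n_bins, np.nan)
    freq = np.zeros(n_bins)
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            mean_k[b] = k[mask].mean()
            freq[b] = mask.sum() / len(k)
    ok = (freq > 0) & (mean_k > 0)
    if ok.sum() < 3:
        return np.nan, np.nan
    x = np.log10(mean_k[ok])
    y = np.log10(freq[ok])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.nan, np.nan
    r2 = 1.0 - ss_res / ss_tot
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_cut: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan soft-threshold powers for approximate scale-free topology.

    Chooses the smallest power whose signed fit index reaches ``r2_cut``;
    if none does, the power maximising the index is chosen with a warning.
    """
    powers = list(powers)
    if not powers or any(
        b <= a for a, b in zip(powers, powers[1:])
    ):
        raise ValueError("powers must be non-empty and strictly ascending")
    cor = correlation_matrix(expr)
    abs_cor = np.abs(cor.to_numpy(float))
    rows = []
    for beta in powers:
        adj = abs_cor**beta
        np.fill_diagonal(adj, 1.0)
        k = adj.sum(axis=1) - 1.0
        r2_signed, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "power": beta,
                "r2_signed": r2_signed,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    reaching = table[table["r2_signed"] >= r2_cut]
    if len(reaching):
        chosen = int(reaching["power"].iloc[0])
    else:
        warnings.warn(
            f"no power reached signed R^2 >= {r2_cut}; "
            "using the power with the best fit",
            stacklevel=2,
        )
        best = table["r2_signed"].astype(float)
        chosen = int(table["power"].iloc[int(np.nanargmax(best.to_numpy()))])
    return SoftThresholdScan(table=table, chosen_power=chosen, r2_cut=r2_cut)


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (L_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij) for i != j, with
    L_ij = sum_{u != i,j} A_iu A_uj and k_i = sum_{u != i} A_iu; TOM_ii = 1.
    """
    is_df = isinstance(adj, pd.DataFrame)
    a = adj.to_numpy(float) if is_df else np.asarray(adj, float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be a symmetric square matrix")
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    # (A @ A)_ij includes u = i and u = j terms A_ii A_ij + A_ij A_jj = 2 A_ij
    L = a @ a - 2.0 * a
    min_k = np.minimum.outer(k, k)
    tom = (L + a) / (min_k + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if is_df:
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom
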