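"""Module-trait association, gene statistics, hub selection, network export.

Traits are one-hot indicator columns built from the sample metadata.  The
module-trait table correlates eigengenes with indicators; per-gene gene
significance (GS), module membership (MM), module significance (MS) and
intramodular connectivity (kWithin) feed hub-gene ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .wgcna_modules import EigengeneMatrix, ModuleAssignment

__all__ = [
    "ModuleTraitTable",
    "trait_design_matrix",
    "module_trait_correlation",
    "gene_significance",
    "module_significance",
    "module_membership",
    "intramodular_connectivity",
    "select_hub_genes",
    "export_hub_network",
]


@dataclass
class ModuleTraitTable:
    """Signed correlations and p-values between eigengenes and traits."""

    r: pd.DataFrame  # module x trait
    p: pd.DataFrame  # module x trait


def trait_design_matrix(metadata: pd.DataFrame) -> pd.DataFrame:
    """One-hot indicator matrix (samples x factor levels).

    Column order is deterministic: breed levels, then group levels, then
    tissue levels, alphabetical within each factor.  Constant (single-level)
    columns are kept but flagged with a warning; correlations against them
    are undefined.
    """
    for col in ("sample_id", "breed", "group", "tissue"):
        if col not in metadata.columns:
            raise ValueError(f"metadata is missing column '{col}'")
    cols = {}
    for factor in ("breed", "group", "tissue"):
        for level in sorted(metadata[factor].unique()):
            cols[f"{factor}_{level}"] = (metadata[factor] == level).astype(int).to_numpy()
    design = pd.DataFrame(cols, index=metadata["sample_id"].to_numpy())
    design.index.name = "sample_id"
    constant = [c for c in design.columns if design[c].nunique() == 1]
    if constant:
        warnings.warn(
            f"constant indicator columns (single-level factor): {constant}",
            stacklevel=2,
        )
    return design


def _cor_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the t transform with n-2 df."""
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def module_trait_correlation(
    eigengenes: EigengeneMatrix | pd.DataFrame,
    trait_design: pd.DataFrame,
) -> ModuleTraitTable:
    """Correlate each module eigengene with each trait indicator column."""
    eig = (
        eigengenes.eigengenes
        if isinstance(eigengenes, EigengeneMatrix)
        else eigengenes
    )
    if eig.shape[1] < 4:
        raise ValueError("module-trait correlation needs at least 4 samples")
    trait_design = trait_design.loc[eig.columns]
    r = pd.DataFrame(index=eig.index, columns=trait_design.columns, dtype=float)
    p = pd.DataFrame(index=eig.index, columns=trait_design.columns, dtype=float)
    for trait in trait_design.columns:
        t_vals = trait_design[trait].to_numpy(float)
        if np.std(t_vals) == 0:
            warnings.warn(f"trait '{trait}' is constant; skipping", stacklevel=2)
            continue
        for m in eig.index:
            r.loc[m, trait], p.loc[m, trait] = _cor_with_p(
                eig.loc[m].to_numpy(float), t_vals
            )
    return ModuleTraitTable(r=r, p=p)


def gene_significance(
    expr: pd.DataFrame,
    trait_column: pd.Series | np.ndarray,
    signed: bool = False,
) -> pd.Series:
    """GS_i = |cor(x_i, T)| per gene (or signed when requested)."""
    t = (
        trait_column.loc[expr.columns].to_numpy(float)
        if isinstance(trait_column, pd.Series)
        else np.asarray(trait_column, float)
    )
    if np.std(t) == 0:
        raise ValueError("trait column is constant")
    vals = expr.to_numpy(float)
    tc = t - t.mean()
    vc = vals - vals.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = (vc @ tc) / denom
    cor[denom == 0] = np.nan
    gs = cor if signed else np.abs(cor)
    return pd.Series(gs, index=expr.index, name="GS")


def module_significance(
    gs: pd.Series, assignment: ModuleAssignment
) -> pd.Series:
    """MS_m = mean gene significance over the genes of module m (incl. grey)."""
    out = {}
    for m in sorted(int(x) for x in assignment.labels.unique()):
        genes = assignment.genes_in(m)
        vals = gs.loc[genes].dropna()
        out[m] = float(vals.mean()) if len(vals) else np.nan
    return pd.Series(out, name="MS").rename_axis("module")


def module_membership(
    expr: pd.DataFrame,
    eigengenes: EigengeneMatrix | pd.DataFrame,
) -> pd.DataFrame:
    """MM_{i,m} = cor(x_i, ME_m) for every gene x module pair."""
    eig = (
        eigengenes.eigengenes
        if isinstance(eigengenes, EigengeneMatrix)
        else eigengenes
    )
    vals = expr.to_numpy(float)
    vc = vals - vals.mean(axis=1, keepdims=True)
    vn = np.sqrt((vc**2).sum(axis=1))
    out = {}
    for m in eig.index:
        e = eig.loc[m].to_numpy(float)
        ec = e - e.mean()
        en = np.sqrt((ec**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            cor = (vc @ ec) / (vn * en)
        cor[vn == 0] = np.nan
        out[m] = cor
    mm = pd.DataFrame(out, index=expr.index)
    mm.columns.name = "module"
    return mm


def intramodular_connectivity(
    adj: pd.DataFrame,
    assignment: ModuleAssignment,
) -> pd.DataFrame:
    """kTotal and kWithin per gene from the weighted adjacency."""
    if not adj.index.equals(assignment.labels.index):
        raise ValueError("adjacency and assignment cover different genes")
    a = adj.to_numpy(float)
    labels = assignment.labels.to_numpy()
    k_total = a.sum(axis=1) - np.diag(a)
    same = labels[:, None] == labels[None, :]
    within = np.where(same, a, 0.0)
    k_within = within.sum(axis=1) - np.diag(a)
    return pd.DataFrame(
        {"module": labels, "kTotal": k_total, "kWithin": k_within}, index=adj.index
    )


def select_hub_genes(
    stats_table: pd.DataFrame,
    assignment: ModuleAssignment,
    n: int = 30,
) -> dict[int, pd.DataFrame]:
    """Top-n genes per module by kWithin (ties broken by gene ID).

    Grey (module 0) is excluded.  ``stats_table`` must carry a ``kWithin``
    column (extra columns such as MM/GS are carried through).
    """
    hubs: dict[int, pd.DataFrame] = {}
    for m in assignment.module_ids:
        genes = assignment.genes_in(m)
        sub = stats_table.loc[genes].copy()
        sub["_gene"] = sub.index
        sub = sub.sort_values(["kWithin", "_gene"], ascending=[False, True])
        sub = sub.drop(columns="_gene").head(n)
        hubs[m] = sub
    return hubs


def export_hub_network(
    adj: pd.DataFrame,
    hub_genes: list[str],
) -> pd.DataFrame:
    """All pairwise edges among hub genes, weight = adjacency.

    Each unordered pair appears once with source < target lexicographically.
    """
    if not hub_genes:
        raise ValueError("hub gene list is empty")
    rows = []
    ordered = sorted(hub_genes)
    for i, g1 in enumerate(ordered):
        for g2 in ordered[i + 1 :]:
            rows.append(
                {"source": g1, "target": g2, "weight": float(adj.loc[g1, g2])}
            )
    return pd.DataFrame(rows, columns=["source", "target", "weight"])
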