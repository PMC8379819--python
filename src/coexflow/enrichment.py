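"""Hypergeometric over-representation analysis against GMT gene sets.

Reads standard GMT files (term, description, tab-separated members), tests a
query list for over-representation term by term with the hypergeometric
upper tail, adjusts within category by Benjamini-Hochberg, and reports the
top terms below the FDR cut.  The description field of the GMT line is used
as the category tag (e.g. BP / MF / CC); lines without a recognisable tag
fall into category "default".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeometric_test",
    "bh_adjust",
    "enrich_gene_list",
]


@dataclass
class GeneSetCollection:
    """Term id -> (name, category, member set), plus the gene universe."""

    terms: dict[str, tuple[str, str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Drop genes outside ``universe`` and terms left empty."""
        new_terms = {}
        for tid, (name, cat, members) in self.terms.items():
            kept = frozenset(members & universe)
            if kept:
                new_terms[tid] = (name, cat, kept)
        return GeneSetCollection(terms=new_terms, universe=frozenset(universe))

    def categories(self) -> list[str]:
        return sorted({cat for _, cat, _ in self.terms.values()})


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; the description field doubles as the category tag."""
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    universe: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected >= 3 tab-separated fields"
                )
            tid, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            category = desc.strip() or "default"
            terms[tid] = (tid, category, members)
            universe |= members
    if not terms:
        warnings.warn("GMT file contained no gene sets", stacklevel=2)
    return GeneSetCollection(terms=terms, universe=frozenset(universe))


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) with X ~ Hypergeometric(N, K, n).

    k = overlap, K = term size, n = query size, N = universe size.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR in input order; NaNs pass through."""
    p = np.asarray(p_values, float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.clip(ranked, 0.0, 1.0)
    adj = np.empty(m)
    adj[order] = ranked
    out[ok] = adj
    return out


def enrich_gene_list(
    genes,
    collection: GeneSetCollection,
    universe=None,
    fdr_cut: float = 0.05,
    top_n: int = 10,
) -> pd.DataFrame:
    """Over-representation of ``genes`` against the collection.

    The universe defaults to the collection's own gene universe.  Query
    genes outside the universe are dropped (count reported via warning).
    BH adjustment is performed within each category; results are filtered
    at ``fdr < fdr_cut``, ranked by (fdr, p, term_id) and truncated to
    ``top_n`` per category.
    """
    uni = frozenset(universe) if universe is not None else collection.universe
    coll = collection.restrict(set(uni))
    query = set(genes)
    dropped = len(query - uni)
    if dropped:
        warnings.warn(
            f"{dropped} query genes outside the universe were dropped", stacklevel=2
        )
    query &= uni
    if not query:
        warnings.warn("empty query after universe restriction", stacklevel=2)
        return pd.DataFrame(
            columns=["term_id", "category", "k", "K", "n", "N", "p", "fdr", "rank"]
        )
    N = len(uni)
    n = len(query)
    rows = []
    for tid in sorted(coll.terms):
        _, cat, members = coll.terms[tid]
        K = len(members)
        k = len(members & query)
        rows.append(
            {
                "term_id": tid,
                "category": cat,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeometric_test(k, K, n, N),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table["fdr"] = []
        table["rank"] = []
        return table
    table["fdr"] = np.nan
    for cat, idx in table.groupby("category").groups.items():
        table.loc[idx, "fdr"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    out = []
    for cat, sub in table.groupby("category"):
        sig = sub[sub["fdr"] < fdr_cut].sort_values(["fdr", "p", "term_id"])
        sig = sig.head(top_n).copy()
        sig["rank"] = np.arange(1, len(sig) + 1)
        out.append(sig)
    result = (
        pd.concat(out, ignore_index=True)
        if out
        else table.iloc[0:0].assign(rank=[])
    )
    return result
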