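"""Module detection: UPGMA dendrogram, static tree cut, eigengenes, merging.

Average-linkage agglomeration runs on the TOM dissimilarity; the tree is cut
at a fixed height, clusters below the minimum size fall into the unassigned
"grey" label 0, and modules whose eigengenes are closer than the merge cut
(1 - correlation < 0.25 by default) are merged iteratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dendrogram",
    "ModuleAssignment",
    "EigengeneMatrix",
    "build_dendrogram",
    "cut_dendrogram",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_color",
]

# size-rank colour aliases mirroring the usual reporting convention
_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


def module_color(label: int) -> str:
    """Colour alias for a module label; 0 is always grey."""
    if label == 0:
        return "grey"
    if label <= len(_COLORS):
        return _COLORS[label - 1]
    return f"module{label}"


@dataclass
class Dendrogram:
    """Agglomeration record in scipy linkage layout.

    ``merges[i] = (a, b)`` joins clusters a and b (original leaves are
    0..n-1, the cluster formed at step i gets id n+i) at ``heights[i]``.
    """

    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,)
    sizes: np.ndarray  # (n-1,) size of the newly formed cluster
    n_leaves: int

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible (n-1, 4) linkage matrix."""
        return np.column_stack(
            [self.merges.astype(float), self.heights, self.sizes.astype(float)]
        )

    @property
    def max_height(self) -> float:
        return float(self.heights[-1]) if len(self.heights) else 0.0


@dataclass
class ModuleAssignment:
    """Gene -> integer module label; 0 is the unassigned grey pool."""

    labels: pd.Series

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    def genes_in(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def colors(self) -> pd.Series:
        return self.labels.map(module_color)


@dataclass
class EigengeneMatrix:
    """Module eigengenes (unit-norm first right singular vectors)."""

    eigengenes: pd.DataFrame  # module x sample
    variance_explained: pd.Series = field(default_factory=pd.Series)


def build_dendrogram(dissimilarity: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a dissimilarity matrix.

    Ties are broken deterministically by the smallest pair of cluster
    indices in row-major order.
    """
    d = (
        dissimilarity.to_numpy(float)
        if isinstance(dissimilarity, pd.DataFrame)
        else np.asarray(dissimilarity, float)
    )
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric square")
    n = d.shape[0]
    work = d.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    cluster_id = np.arange(n)  # current scipy-style id of each slot
    sizes = np.ones(n, dtype=int)
    merges = np.empty((n - 1, 2), dtype=int)
    heights = np.empty(n - 1)
    out_sizes = np.empty(n - 1, dtype=int)
    for step in range(n - 1):
        flat = np.argmin(work)  # row-major => smallest indices win ties
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = work[i, j]
        a, b = cluster_id[i], cluster_id[j]
        if a > b:
            a, b = b, a
        merges[step] = (a, b)
        heights[step] = h
        new_size = sizes[i] + sizes[j]
        out_sizes[step] = new_size
        # average-linkage update into slot i
        di = work[i].copy()
        dj = work[j].copy()
        new_d = (sizes[i] * di + sizes[j] * dj) / new_size
        work[i, :] = new_d
        work[:, i] = new_d
        work[i, i] = np.inf
        work[j, :] = np.inf
        work[:, j] = np.inf
        active[j] = False
        sizes[i] = new_size
        cluster_id[i] = n + step
    return Dendrogram(merges=merges, heights=heights, sizes=out_sizes, n_leaves=n)


def cut_dendrogram(dend: Dendrogram, cut_height: float) -> np.ndarray:
    """Leaf cluster ids after removing all merges above ``cut_height``."""
    n = dend.n_leaves
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - 1):
        if dend.heights[step] <= cut_height:
            a, b = dend.merges[step]
            new = n + step
            parent[find(a)] = new
            parent[find(b)] = new
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def detect_modules(
    dend: Dendrogram,
    gene_ids: pd.Index,
    min_size: int = 30,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Static tree cut followed by a minimum-size filter.

    Clusters at ``cut_height`` (default 0.99 x max merge height) with fewer
    than ``min_size`` genes become grey (label 0); the rest are labelled
    1..M by decreasing size, ties broken by first gene position.
    """
    if cut_height is None:
        cut_height = 0.99 * dend.max_height
    if not (0 < cut_height <= dend.max_height) and dend.max_height > 0:
        raise ValueError(
            f"cut_height {cut_height} outside (0, {dend.max_height}]"
        )
    raw = cut_dendrogram(dend, cut_height)
    labels = np.zeros(len(raw), dtype=int)
    clusters = pd.Series(raw).value_counts()
    kept = clusters[clusters >= min_size]
    # order by decreasing size, then by first appearance for determinism
    first_pos = {c: int(np.argmax(raw == c)) for c in kept.index}
    ordered = sorted(kept.index, key=lambda c: (-kept[c], first_pos[c]))
    for new_label, c in enumerate(ordered, start=1):
        labels[raw == c] = new_label
    return ModuleAssignment(labels=pd.Series(labels, index=gene_ids, name="module"))


def _standardize(vals: np.ndarray) -> np.ndarray:
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (vals - mean) / sd


def module_eigengenes(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
) -> EigengeneMatrix:
    """First principal component of each module's standardised expression.

    The eigengene is the unit-norm first right singular vector of the
    genes-x-samples block; its sign is fixed so it correlates positively
    with the module's mean standardised expression.  Variance explained is
    s1^2 / sum(s^2).
    """
    mes = {}
    var_exp = {}
    for m in assignment.module_ids:
        genes = assignment.genes_in(m)
        block = _standardize(expr.loc[genes].to_numpy(float))
        if block.shape[0] == 1:
            warnings.warn(f"module {m} has a single gene", stacklevel=2)
            v = block[0] / np.linalg.norm(block[0])
            mes[m] = v
            var_exp[m] = 1.0
            continue
        _, s, vt = np.linalg.svd(block, full_matrices=False)
        me = vt[0]
        mean_profile = block.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        mes[m] = me
        var_exp[m] = float(s[0] ** 2 / np.sum(s**2))
    eig = pd.DataFrame(mes, index=expr.columns).T
    eig.index.name = "module"
    return EigengeneMatrix(
        eigengenes=eig, variance_explained=pd.Series(var_exp, name="var_explained")
    )


def merge_modules(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    merge_cut: float = 0.25,
    max_iter: int = 10,
) -> tuple[ModuleAssignment, list[dict]]:
    """Merge modules whose eigengenes are closer than ``merge_cut``.

    Iterates: compute eigengenes, cluster them by average linkage on
    1 - correlation, merge every group joined below the cut, relabel by
    size, repeat until a fixed point or ``max_iter``.  Grey never merges.
    """
    history: list[dict] = []
    current = assignment
    for it in range(max_iter):
        ids = current.module_ids
        if len(ids) < 2 or merge_cut <= 0:
            break
        eig = module_eigengenes(expr, current).eigengenes
        me = eig.loc[ids].to_numpy(float)
        diss = 1.0 - np.corrcoef(me)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip(diss, 0.0, 2.0)
        dend = build_dendrogram(diss)
        groups = cut_dendrogram(dend, merge_cut)
        if len(np.unique(groups)) == len(ids):
            break
        # map each group to a fresh label; record merge events
        labels = current.labels.copy()
        new_map: dict[int, list[int]] = {}
        for mod, grp in zip(ids, groups):
            new_map.setdefault(int(grp), []).append(mod)
        for grp, mods in sorted(new_map.items()):
            if len(mods) > 1:
                history.append({"iteration": it, "merged": sorted(mods)})
        relabel = {}
        for grp, mods in new_map.items():
            for mod in mods:
                relabel[mod] = min(mods)
        labels = labels.map(lambda m: relabel.get(int(m), 0) if m != 0 else 0)
        current = _relabel_by_size(pd.Series(labels, index=current.labels.index))
    return current, history


def _relabel_by_size(labels: pd.Series) -> ModuleAssignment:
    counts = labels[labels != 0].value_counts()
    first_pos = {m: int(np.argmax((labels == m).to_numpy())) for m in counts.index}
    ordered = sorted(counts.index, key=lambda m: (-counts[m], first_pos[m]))
    mapping = {int(old): new for new, old in enumerate(ordered, start=1)}
    mapping[0] = 0
    out = labels.map(lambda m: mapping[int(m)])
    out.name = "module"
    return ModuleAssignment(labels=out)
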