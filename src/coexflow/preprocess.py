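"""Count-matrix preprocessing: filtering, size factors, VST, sample QC.

The normalisation follows the median-of-ratios scheme: per-gene geometric
means over samples, per-sample medians of count/geomean ratios.  Dispersion
is estimated by method of moments and summarised by the parametric trend
``alpha(mu) = a0 + a1/mu``, which also drives the closed-form variance
stabilising transformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "DispersionTrend",
    "read_counts",
    "read_metadata",
    "validate_counts",
    "filter_low_expression",
    "size_factors",
    "fit_dispersion_trend",
    "vst_transform",
    "detect_outlier_samples",
]


class SizeFactorError(ValueError):
    """No gene is expressed in every sample, so median-of-ratios is undefined."""


@dataclass(frozen=True)
class DispersionTrend:
    """Parametric mean-dispersion trend alpha(mu) = a0 + a1/mu."""

    a0: float
    a1: float
    gene_means: pd.Series | None = None
    gene_dispersions: pd.Series | None = None

    def alpha(self, mu):
        return self.a0 + self.a1 / np.maximum(np.asarray(mu, float), 1e-12)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample integer count TSV (first column ``gene_id``)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    validate_counts(counts)
    return counts


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "breed", "group", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return meta


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene IDs in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample IDs in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")


def filter_low_expression(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop genes whose total count across samples is below ``min_total``."""
    keep = counts.sum(axis=1) >= min_total
    if not keep.any():
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    For each gene with all-positive counts, compute its geometric mean over
    samples; the size factor of a sample is the median over those genes of
    count / geometric mean.
    """
    mat = counts.to_numpy(float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise SizeFactorError(
            "no gene has positive counts in every sample; "
            "filter genes or provide deeper data before normalising"
        )
    sub = mat[positive]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_geo)[:, None]
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def fit_dispersion_trend(
    counts: pd.DataFrame,
    sf: pd.Series,
    trim_fraction: float = 0.05,
) -> DispersionTrend:
    """Fit alpha(mu) = a0 + a1/mu to per-gene method-of-moments dispersions.

    Per gene, on size-factor-normalised counts q: ``alpha_hat = max(0,
    (var - mean) / mean^2)``.  The trend is least squares of alpha_hat on
    1/mean over genes with alpha_hat > 0, with one trimming pass removing
    the ``trim_fraction`` largest absolute residuals.  Coefficients are
    clamped at 1e-8.  Falls back to (0.01, 1.0) when fewer than 10 usable
    genes exist.
    """
    if counts.shape[1] < 2:
        raise ValueError("dispersion estimation needs at least 2 samples")
    q = counts.to_numpy(float) / sf.to_numpy(float)[None, :]
    mean = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(mean > 0, (var - mean) / np.maximum(mean, 1e-12) ** 2, 0.0)
    alpha_hat = np.maximum(alpha_hat, 0.0)

    usable = alpha_hat > 0
    means_s = pd.Series(mean, index=counts.index, name="mean")
    disps_s = pd.Series(alpha_hat, index=counts.index, name="dispersion")
    if usable.sum() < 10:
        warnings.warn(
            "fewer than 10 genes with positive dispersion; "
            "falling back to default trend a0=0.01, a1=1",
            stacklevel=2,
        )
        return DispersionTrend(0.01, 1.0, means_s, disps_s)

    x = 1.0 / mean[usable]
    y = alpha_hat[usable]
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = np.abs(y - X @ coef)
    if len(y) >= 20 and trim_fraction > 0:
        cutoff = np.quantile(resid, 1.0 - trim_fraction)
        keep = resid <= cutoff
        coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
    a0 = float(max(coef[0], 1e-8))
    a1 = float(max(coef[1], 1e-8))
    return DispersionTrend(a0, a1, means_s, disps_s)


def vst_transform(
    counts: pd.DataFrame,
    sf: pd.Series,
    trend: DispersionTrend,
) -> pd.DataFrame:
    """Closed-form variance stabilising transform for the a0 + a1/mu trend.

    With q = count / size factor,

        vst(q) = log2( (1 + a1 + 2 a0 q + 2 sqrt(a0 q (1 + a1 + a0 q)))
                       / (4 a0) )

    which is strictly increasing in q and asymptotically log2(q) + const.
    When a0 is zero the fallback log2(q + 1) is used.
    """
    q = counts.to_numpy(float) / sf.to_numpy(float)[None, :]
    a0, a1 = trend.a0, trend.a1
    if a0 <= 0:
        warnings.warn("a0 = 0; falling back to log2(q + 1)", stacklevel=2)
        vals = np.log2(q + 1.0)
    else:
        vals = np.log2(
            (1.0 + a1 + 2.0 * a0 * q + 2.0 * np.sqrt(a0 * q * (1.0 + a1 + a0 * q)))
            / (4.0 * a0)
        )
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def detect_outlier_samples(
    expr: pd.DataFrame,
    method: str = "average",
    cut_fraction: float = 0.85,
    max_cluster_fraction: float = 0.10,
) -> tuple[list[str], np.ndarray]:
    """Flag samples that split off high in a hierarchical clustering tree.

    Samples are clustered on Euclidean distance between expression columns
    with the given linkage.  Cutting the tree at ``cut_fraction`` times the
    maximum merge height, any cluster containing fewer than
    ``max_cluster_fraction`` of the samples is flagged — but only when a
    dominant core cluster (>= 1 - 2 x max_cluster_fraction of samples)
    exists at that cut; a flat tree with no dominant cluster yields no
    flags.  Nothing is removed automatically; callers decide what to do
    with the flags.
    """
    n = expr.shape[1]
    if n < 3:
        warnings.warn("fewer than 3 samples; outlier detection skipped", stacklevel=2)
        return [], np.empty((0, 4))
    d = pdist(expr.to_numpy(float).T, metric="euclidean")
    Z = linkage(d, method=method)
    max_h = Z[:, 2].max()
    if max_h <= 0:
        return [], Z
    labels = fcluster(Z, t=cut_fraction * max_h, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    if sizes.max() < (1.0 - 2.0 * max_cluster_fraction) * n:
        return [], Z  # no dominant core: flat tree, nothing to flag
    small = sizes[sizes < max_cluster_fraction * n].index
    flagged = [s for s, lab in zip(expr.columns, labels) if lab in set(small)]
    return flagged, Z
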