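"""Per-contrast negative-binomial Wald tests and candidate-gene set algebra.

Each contrast is a two-group (high vs low) comparison within one breed and
tissue.  Genes are fitted with a log-link NB GLM (intercept + group) with
log size factors as offsets and a plug-in dispersion from the mean-trend;
significance comes from the Wald statistic on the group coefficient.  Count
outliers are flagged by Cook's distance and get a missing p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import DispersionTrend, fit_dispersion_trend, size_factors

__all__ = [
    "NBFit",
    "CandidateSets",
    "nb_wald_fit",
    "cooks_outlier_flag",
    "run_de_contrast",
    "combine_candidate_sets",
    "ddct_relative_abundance",
]

_LN2 = np.log(2.0)


class ContrastError(ValueError):
    """Raised when a requested contrast cannot be formed from the metadata."""


@dataclass
class NBFit:
    """One gene's NB GLM fit: intercept + group coefficient on log2 scale."""

    gene_id: str
    beta0: float
    lfc: float
    se_lfc: float
    mu_hat: np.ndarray
    alpha: float
    converged: bool
    pseudo: bool = False  # separation handled with a pseudo-count refit

    @property
    def wald_z(self) -> float:
        if not self.converged or self.se_lfc <= 0:
            return np.nan
        return self.lfc / self.se_lfc


@dataclass
class CandidateSets:
    """Union-within-breed / intersect-across-breeds candidate algebra."""

    per_contrast: dict[tuple[str, str], set[str]]
    breed_unions: dict[str, set[str]]
    intersection: set[str] = field(default_factory=set)


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS for NB regression with log link and known dispersion.

    Returns (beta on natural-log scale, covariance of beta, converged).
    Weights use the expected information w = mu / (1 + alpha mu).
    """
    beta = np.zeros(X.shape[1])
    # initialise from the overall mean
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        XtWX = X.T @ WX
        try:
            beta_new = np.linalg.solve(XtWX, WX.T @ z)
        except np.linalg.LinAlgError:
            return beta, np.full((X.shape[1], X.shape[1]), np.nan), False
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        converged = False
    return beta, cov, converged


def nb_wald_fit(
    count_row: np.ndarray,
    group_indicator: np.ndarray,
    sf: np.ndarray,
    trend: DispersionTrend,
) -> NBFit:
    """Fit one gene: NB GLM with offset log(sf), Wald SE on the group term.

    The dispersion is the trend evaluated at the gene's normalised mean.
    The group coefficient is reported as a log2 fold change (high vs low).
    All-zero genes are returned unconverged; complete separation (one group
    all zeros) triggers a pseudo-count (+0.5) refit with the flag set.
    """
    y = np.asarray(count_row, float)
    g = np.asarray(group_indicator, float)
    gene_id = getattr(count_row, "name", "")
    sf = np.asarray(sf, float)
    mu_bar = np.mean(y / sf)
    if mu_bar <= 0:
        return NBFit(gene_id, np.nan, np.nan, np.nan, np.zeros_like(y), np.nan, False)
    alpha = float(trend.alpha(mu_bar))
    X = np.column_stack([np.ones_like(y), g])
    offset = np.log(sf)
    pseudo = False
    if y[g == 1].sum() == 0 or y[g == 0].sum() == 0:
        y = y + 0.5
        pseudo = True
    beta, cov, converged = _irls_nb(y, X, offset, alpha)
    se_nat = np.sqrt(cov[1, 1]) if np.isfinite(cov[1, 1]) else np.nan
    mu_hat = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
    return NBFit(
        gene_id=str(gene_id),
        beta0=float(beta[0] / _LN2),
        lfc=float(beta[1] / _LN2),
        se_lfc=float(se_nat / _LN2) if np.isfinite(se_nat) else np.nan,
        mu_hat=mu_hat,
        alpha=alpha,
        converged=bool(converged and np.isfinite(se_nat) and se_nat > 0),
        pseudo=pseudo,
    )


def cooks_outlier_flag(
    fit: NBFit,
    count_row: np.ndarray,
    group_indicator: np.ndarray,
    threshold_quantile: float = 0.99,
) -> bool:
    """Flag a gene whose worst Cook's distance exceeds an F quantile.

    D_j = (pearson_j^2 / (p * phi)) * h_jj / (1 - h_jj)^2 with phi = 1 and
    hat values from the IRLS weights; the gene is flagged when
    max_j D_j > F^{-1}(threshold_quantile; p, m - p).
    """
    y = np.asarray(count_row, float)
    m = len(y)
    p = 2
    if m <= p:
        warnings.warn("too few samples for Cook's distance", stacklevel=2)
        return False
    if not fit.converged:
        return False
    if threshold_quantile >= 1.0:
        return False
    mu = fit.mu_hat
    alpha = fit.alpha
    var = mu + alpha * mu**2
    r = (y - mu) / np.sqrt(np.maximum(var, 1e-12))
    w = mu / (1.0 + alpha * mu)
    X = np.column_stack([np.ones(m), np.asarray(group_indicator, float)])
    WX = X * w[:, None]
    try:
        XtWX_inv = np.linalg.inv(X.T @ WX)
    except np.linalg.LinAlgError:
        return False
    h = np.einsum("ij,jk,ik->i", X, XtWX_inv, WX)
    h = np.clip(h, 0.0, 1.0 - 1e-8)
    d = (r**2 / p) * h / (1.0 - h) ** 2
    return bool(d.max() > stats.f.ppf(threshold_quantile, p, m - p))


def run_de_contrast(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    breed: str,
    tissue: str,
    alpha: float = 0.05,
    high_label: str = "High",
    low_label: str = "Low",
    cooks_quantile: float = 0.99,
) -> pd.DataFrame:
    """Two-group NB Wald test for one breed x tissue contrast.

    Size factors and the dispersion trend are estimated within the contrast
    subset.  Returns one row per gene with lfc, se, z, p, a ``significant``
    flag at raw p < alpha (no multiplicity adjustment) and the Cook's flag.
    Cook's-flagged genes have missing p and are never significant.
    """
    sel = metadata[(metadata["breed"] == breed) & (metadata["tissue"] == tissue)]
    for lab in (high_label, low_label):
        if (sel["group"] == lab).sum() < 2:
            raise ContrastError(
                f"contrast {breed}/{tissue}: group '{lab}' has fewer than 2 samples"
            )
    sample_ids = sel["sample_id"].tolist()
    sub = counts[sample_ids]
    g = (sel["group"] == high_label).to_numpy(float)
    sf = size_factors(sub)
    trend = fit_dispersion_trend(sub, sf)
    sf_arr = sf.to_numpy(float)

    rows = []
    for gene_id, y in sub.iterrows():
        fit = nb_wald_fit(y, g, sf_arr, trend)
        flagged = cooks_outlier_flag(fit, y.to_numpy(float), g, cooks_quantile)
        z = fit.wald_z
        if flagged or not np.isfinite(z):
            pval = np.nan
        else:
            pval = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "gene_id": gene_id,
                "lfc": fit.lfc,
                "se": fit.se_lfc,
                "z": z,
                "p": pval,
                "significant": bool(np.isfinite(pval) and pval < alpha),
                "cooks_flagged": flagged,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    out.attrs["contrast"] = (breed, tissue)
    return out


def combine_candidate_sets(
    de_tables: Mapping[tuple[str, str], pd.DataFrame],
) -> CandidateSets:
    """Union significant genes within each breed, intersect across breeds."""
    per_contrast: dict[tuple[str, str], set[str]] = {}
    breed_unions: dict[str, set[str]] = {}
    for (breed, tissue), table in de_tables.items():
        sig = set(table.index[table["significant"].astype(bool)])
        per_contrast[(breed, tissue)] = sig
        breed_unions.setdefault(breed, set()).update(sig)
    if not breed_unions:
        return CandidateSets({}, {}, set())
    if len(breed_unions) == 1:
        warnings.warn(
            "single breed supplied; intersection equals that breed's union",
            stacklevel=2,
        )
    inter: set[str] | None = None
    for u in breed_unions.values():
        inter = set(u) if inter is None else inter & u
    return CandidateSets(per_contrast, breed_unions, inter or set())


def ddct_relative_abundance(
    ct_table: pd.DataFrame,
    control_condition: str,
) -> pd.DataFrame:
    """Relative mRNA abundance by the 2^-ddCt method.

    ``ct_table`` has columns ``sample, condition, target_ct, reference_ct``
    (Ct values already averaged over technical replicates).  Per sample
    dCt = target - reference; per condition ddCt = mean dCt(condition) -
    mean dCt(control); RQ = 2^-ddCt.
    """
    required = {"sample", "condition", "target_ct", "reference_ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")
    if control_condition not in set(ct_table["condition"]):
        raise ValueError(f"control condition '{control_condition}' not present")
    if ct_table["reference_ct"].isna().any():
        raise ValueError("missing reference-gene Ct values")
    tab = ct_table.copy()
    tab["dct"] = tab["target_ct"].astype(float) - tab["reference_ct"].astype(float)
    mean_dct = tab.groupby("condition")["dct"].mean()
    ddct = mean_dct - mean_dct[control_condition]
    out = pd.DataFrame({"mean_dct": mean_dct, "ddct": ddct, "rq": 2.0 ** (-ddct)})
    out.index.name = "condition"
    return out
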