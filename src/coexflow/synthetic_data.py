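"""Synthetic multi-tissue count data with planted co-expression modules.

Generates gene-by-sample negative-binomial count matrices in which blocks of
genes share a latent per-sample profile (built from tissue effects, a
high/low group effect, and profile noise), so that every downstream stage of
the pipeline — filtering, normalisation, differential expression, network
construction, module detection and trait association — can be validated
against known ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "ModuleSpecTruth",
    "GroundTruth",
    "make_design",
    "simulate_dataset",
    "write_fixture",
    "default_module_specs",
    "benchmark_dataset",
]


class InvalidDesignError(ValueError):
    """Raised when a study design is structurally impossible."""


class InvalidParameterError(ValueError):
    """Raised for non-positive dispersion or other bad simulation parameters."""


@dataclass(frozen=True)
class StudyDesign:
    """Fully crossed factorial design: breeds x groups x tissues x reps."""

    breeds: tuple[str, ...]
    groups: tuple[str, ...]
    tissues: tuple[str, ...]
    reps_per_cell: int
    n_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, levels in (
            ("breeds", self.breeds),
            ("groups", self.groups),
            ("tissues", self.tissues),
        ):
            if len(levels) == 0:
                raise InvalidDesignError(f"factor '{name}' has no levels")
            if len(set(levels)) != len(levels):
                raise InvalidDesignError(f"factor '{name}' has duplicate levels")
        if self.reps_per_cell < 1:
            raise InvalidDesignError("reps_per_cell must be >= 1")

    @property
    def n_samples(self) -> int:
        return (
            len(self.breeds)
            * len(self.groups)
            * len(self.tissues)
            * self.reps_per_cell
        )


@dataclass(frozen=True)
class ModuleSpecTruth:
    """Parameters of one planted module.

    ``tissue_effect`` maps tissue label -> additive log2 shift of the module
    profile in that tissue; ``group_effect`` is added to the profile for
    samples in the high group.  Gene loadings are drawn uniformly from
    ``loading_range`` and gene-level noise has sd ``noise_sd``.
    ``profile_noise_sd`` is the sd of the per-sample noise baked into the
    latent profile itself (default 0.2).
    """

    module_id: int
    size: int
    tissue_effect: Mapping[str, float] = field(default_factory=dict)
    group_effect: float = 0.0
    loading_range: tuple[float, float] = (0.8, 1.0)
    noise_sd: float = 0.3
    profile_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.module_id < 1:
            raise InvalidParameterError("module_id must be >= 1")
        if self.size < 1:
            raise InvalidParameterError("module size must be >= 1")
        if self.noise_sd <= 0:
            raise InvalidParameterError("noise_sd must be > 0")
        lo, hi = self.loading_range
        if lo > hi:
            raise InvalidParameterError("loading_range low must be <= high")


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline against the simulation."""

    module_of_gene: pd.Series  # gene_id -> module_id (0 = background)
    de_status: pd.DataFrame  # gene_id x tissue, 0/1 planted-DE flags
    profiles: pd.DataFrame  # module_id x sample_id latent profiles
    baseline_log2: pd.Series  # gene_id -> mu_g
    loadings: pd.Series  # gene_id -> lambda_g (0 for background)
    size_factors: pd.Series  # sample_id -> true s_s
    dispersion: tuple[float, float]  # (a0, a1)
    de_log2fc: float = 0.0


def make_design(
    breeds: Sequence[str],
    groups: Sequence[str],
    tissues: Sequence[str],
    reps_per_cell: int,
    seed: int = 0,
    n_genes: int = 0,
) -> tuple[StudyDesign, pd.DataFrame]:
    """Build a fully crossed design and its per-sample metadata table.

    Sample IDs encode ``breed_group_rep_tissue``.  Returns the design object
    and a DataFrame with columns ``sample_id, breed, group, tissue``.
    """
    design = StudyDesign(
        breeds=tuple(breeds),
        groups=tuple(groups),
        tissues=tuple(tissues),
        reps_per_cell=int(reps_per_cell),
        n_genes=n_genes,
        seed=seed,
    )
    rows = []
    for breed, group, tissue, rep in itertools.product(
        design.breeds, design.groups, design.tissues, range(1, reps_per_cell + 1)
    ):
        rows.append(
            {
                "sample_id": f"{breed}_{group}_{rep}_{tissue}",
                "breed": breed,
                "group": group,
                "tissue": tissue,
            }
        )
    metadata = pd.DataFrame(rows, columns=["sample_id", "breed", "group", "tissue"])
    if metadata["sample_id"].duplicated().any():
        raise InvalidDesignError("sample IDs are not unique")
    return design, metadata


def default_module_specs() -> list[ModuleSpecTruth]:
    """Six-module benchmark layout used by the bundled fixture.

    Module 3 carries the high/low group signal; modules 1-2 are tissue
    contrasts; modules 4-6 are trait-neutral with independent latent
    profiles (large profile noise), keeping pairwise profile correlations
    low so the planted partition is recoverable.
    """
    return [
        ModuleSpecTruth(
            module_id=1,
            size=200,
            tissue_effect={"Fat": 1.2, "Liver": -0.6, "Muscle": -0.6},
            loading_range=(0.6, 1.0),
            noise_sd=0.25,
        ),
        ModuleSpecTruth(
            module_id=2,
            size=150,
            tissue_effect={"Fat": 0.0, "Liver": 1.0, "Muscle": -1.0},
            loading_range=(0.6, 1.0),
            noise_sd=0.25,
        ),
        ModuleSpecTruth(
            module_id=3,
            size=120,
            group_effect=1.6,
            loading_range=(0.6, 1.0),
            noise_sd=0.25,
        ),
        ModuleSpecTruth(
            module_id=4,
            size=100,
            loading_range=(0.6, 1.0),
            noise_sd=0.25,
            profile_noise_sd=1.0,
        ),
        ModuleSpecTruth(
            module_id=5,
            size=80,
            loading_range=(0.6, 1.0),
            noise_sd=0.25,
            profile_noise_sd=1.0,
        ),
        ModuleSpecTruth(
            module_id=6,
            size=50,
            loading_range=(0.6, 1.0),
            noise_sd=0.25,
            profile_noise_sd=1.0,
        ),
    ]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean m, dispersion a) with Var = m + a m^2, via gamma-Poisson."""
    alpha = np.maximum(alpha, 1e-12)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def simulate_dataset(
    design: StudyDesign,
    metadata: pd.DataFrame,
    module_specs: Sequence[ModuleSpecTruth],
    n_background_genes: int,
    seed: int,
    a0: float = 0.01,
    a1: float = 1.0,
    background_noise_sd: float = 0.5,
    de_genes_per_tissue: int = 0,
    de_log2fc: float = 2.0,
    baseline_log2_range: tuple[float, float] = (3.0, 12.0),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an NB count matrix with planted modules and DE genes.

    Per gene g in sample s the log2 signal is
    ``x_gs = mu_g + lambda_g * e_{m(g),s} + de_gs + eps`` with
    ``eps ~ N(0, noise_sd)``; counts are NB with mean ``s_s * 2**x_gs`` and
    dispersion ``alpha(m) = a0 + a1/m``.  Sample size factors are drawn
    log-uniform in [0.5, 2].  Planted per-tissue DE genes are taken from the
    background pool; in their designated tissue the high group is shifted by
    ``+/- de_log2fc`` (alternating sign).  Deterministic given ``seed``.
    """
    if a0 <= 0 or a1 < 0:
        raise InvalidParameterError("dispersion parameters must satisfy a0 > 0, a1 >= 0")
    rng = np.random.default_rng(seed)

    n_module_genes = sum(m.size for m in module_specs)
    n_genes = n_module_genes + n_background_genes
    if de_genes_per_tissue * len(design.tissues) > n_background_genes:
        raise InvalidDesignError("not enough background genes for requested DE genes")
    n_samples = len(metadata)
    sample_ids = metadata["sample_id"].tolist()
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    # latent per-module profiles on the samples
    high_label = "High" if "High" in design.groups else design.groups[0]
    is_high = (metadata["group"] == high_label).to_numpy(float)
    profiles = np.zeros((len(module_specs), n_samples))
    for i, spec in enumerate(module_specs):
        base = np.array(
            [spec.tissue_effect.get(t, 0.0) for t in metadata["tissue"]], float
        )
        base += spec.group_effect * is_high
        base += rng.normal(0.0, spec.profile_noise_sd, n_samples)
        profiles[i] = base

    module_map = np.zeros(n_genes, dtype=int)
    loadings = np.zeros(n_genes)
    noise_sd = np.full(n_genes, background_noise_sd)
    pos = 0
    for i, spec in enumerate(module_specs):
        sl = slice(pos, pos + spec.size)
        module_map[sl] = spec.module_id
        lo, hi = spec.loading_range
        lam = rng.uniform(lo, hi, spec.size)
        lam *= rng.choice([-1.0, 1.0], spec.size)  # mixed-sign loadings
        loadings[sl] = lam
        noise_sd[sl] = spec.noise_sd
        pos += spec.size

    mu = rng.uniform(*baseline_log2_range, n_genes)  # baseline log2 means
    size_factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), n_samples))

    # planted DE genes drawn from the background block, one tissue each
    de_status = np.zeros((n_genes, len(design.tissues)), dtype=int)
    de_shift = np.zeros((n_genes, n_samples))
    bg_idx = np.arange(n_module_genes, n_genes)
    next_bg = 0
    for t_i, tissue in enumerate(design.tissues):
        in_tissue = (metadata["tissue"] == tissue).to_numpy(float)
        for j in range(de_genes_per_tissue):
            g = bg_idx[next_bg]
            next_bg += 1
            sign = 1.0 if j % 2 == 0 else -1.0
            de_status[g, t_i] = 1
            de_shift[g] = sign * de_log2fc * in_tissue * is_high

    eps = rng.normal(0.0, 1.0, (n_genes, n_samples)) * noise_sd[:, None]
    if len(module_specs):
        signal = (
            loadings[:, None]
            * profiles[module_map - 1]
            * (module_map > 0)[:, None]
        )
    else:
        signal = 0.0
    x = mu[:, None] + signal + de_shift + eps

    mean = size_factors[None, :] * np.exp2(x)
    alpha = a0 + a1 / np.maximum(mean, 1e-8)
    counts = _nb_draw(rng, mean, alpha)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sample_ids)
    tissue_cols = [f"de_{t.lower()}" for t in design.tissues]
    truth = GroundTruth(
        module_of_gene=pd.Series(module_map, index=counts_df.index, name="module_id"),
        de_status=pd.DataFrame(de_status, index=counts_df.index, columns=tissue_cols),
        profiles=pd.DataFrame(
            profiles,
            index=pd.Index([m.module_id for m in module_specs], name="module_id"),
            columns=sample_ids,
        ),
        baseline_log2=pd.Series(mu, index=counts_df.index, name="baseline_log2"),
        loadings=pd.Series(loadings, index=counts_df.index, name="loading"),
        size_factors=pd.Series(size_factors, index=sample_ids, name="size_factor"),
        dispersion=(a0, a1),
        de_log2fc=de_log2fc,
    )
    return counts_df, truth


def benchmark_dataset(
    seed: int,
    n_background_genes: int = 300,
    de_genes_per_tissue: int = 20,
) -> tuple[StudyDesign, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """The standard validation fixture: 36-sample design, six planted modules.

    2 breeds x 2 high/low groups x 3 tissues x 3 reps with the
    ``default_module_specs`` layout, a brighter baseline (log2 means in
    [6, 12], keeping shot noise from drowning module signal at this sample
    size) and planted per-tissue DE genes.  Returns
    (design, metadata, counts, truth).
    """
    design, metadata = make_design(
        ["Breed1", "Breed2"], ["High", "Low"], ["Fat", "Liver", "Muscle"],
        reps_per_cell=3, seed=seed,
    )
    counts, truth = simulate_dataset(
        design,
        metadata,
        default_module_specs(),
        n_background_genes=n_background_genes,
        seed=seed,
        de_genes_per_tissue=de_genes_per_tissue,
        baseline_log2_range=(6.0, 12.0),
    )
    return design, metadata, counts, truth


def write_fixture(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write counts/metadata/truth TSVs; returns the emitted paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
    }
    counts.to_csv(paths["counts"], sep="\t")
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    truth_df = pd.concat([truth.module_of_gene, truth.de_status], axis=1)
    truth_df.to_csv(paths["truth"], sep="\t")
    return paths
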