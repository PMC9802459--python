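"""Synthetic data generators for the sex-differential variability analyses.

Bulk RNA-seq counts are drawn gene-by-gene from negative binomial
distributions whose log-mean depends on sex, covariates (age, RIN, ischemic
time, five genotype PCs) and library size, and whose log-overdispersion
depends on sex for a planted fraction of "SDV" genes. Ground truth for every
planted effect is carried alongside the counts so that recall and
false-discovery behaviour of the detection pipeline can be measured exactly.

Additional generators produce gene-set collections with planted
overrepresentation, per-tissue eGene labels with planted depletion, and a
small labeled single-cell count matrix with exclusive marker genes for the
cell-type-specificity statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "ExpressionStudy",
    "generate_study",
    "generate_gene_sets",
    "generate_egene_labels",
    "generate_sc_counts",
]

COVARIATES = ["age", "ischemic_time", "RIN", "PC1", "PC2", "PC3", "PC4", "PC5"]


@dataclass
class SynthConfig:
    """Generative settings for one synthetic expression study.

    Defaults emulate a well-powered bulk tissue: a few hundred donors per
    sex, counts of well-expressed genes in the hundreds-to-thousands (the
    scale at which dispersion testing is typically run), baseline
    overdispersion around 0.1 (squared biological CV), and a tenth of genes
    carrying a sex effect of 1.5 on log-overdispersion.
    """

    n_genes: int = 1000
    n_male: int = 200
    n_female: int = 200
    baseline_log_mu_range: tuple[float, float] = (np.log(500.0), np.log(5000.0))
    baseline_sigma_range: tuple[float, float] = (0.05, 0.2)
    sdv_fraction: float = 0.1
    sdv_log_sigma_effect: float = 1.5
    sbe_fraction: float = 0.1
    sbe_log_mu_effect: float = 0.5
    covariate_effect_scale: float = 0.05
    library_size_range: tuple[int, int] = (5_000_000, 20_000_000)
    outlier_fraction: float = 0.02
    outlier_scale: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_male < 1 or self.n_female < 1:
            raise ValueError("both sexes need at least one sample (sex term unidentifiable otherwise)")
        for name in ("sdv_fraction", "sbe_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("baseline_log_mu_range", "baseline_sigma_range", "library_size_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is an empty interval")
        if self.baseline_sigma_range[0] <= 0:
            raise ValueError("baseline overdispersion must be positive")
        if self.library_size_range[0] <= 0:
            raise ValueError("library sizes must be positive")


@dataclass
class ExpressionStudy:
    """Counts, per-sample metadata and (for synthetic data) planted truth."""

    counts: pd.DataFrame  # genes x samples, integer
    sample_meta: pd.DataFrame  # indexed by sample id
    gene_meta: pd.DataFrame  # indexed by gene id
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.gene_meta), len(self.sample_meta)):
            raise ValueError("counts dimensions must match gene_meta x sample_meta")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.sample_meta["library_size"] <= 0).any():
            raise ValueError("library sizes must be positive")


def generate_study(config: SynthConfig) -> ExpressionStudy:
    """Draw one NB-distributed study with planted SDV/SBE genes and outliers.

    The mean model is log mu = baseline + covariate effects + sex effect +
    outlier shift + log(library size / reference); the overdispersion model
    is log sigma = log baseline + sex effect. Sex is coded male = 1 so a
    positive planted dispersion effect means higher variability in males.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    n = config.n_male + config.n_female

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(G)]

    male = np.zeros(n, dtype=bool)
    male[rng.choice(n, size=config.n_male, replace=False)] = True

    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample"))
    meta["sex"] = np.where(male, "male", "female")
    meta["age"] = rng.uniform(20.0, 70.0, size=n)
    meta["ischemic_time"] = rng.normal(size=n)
    meta["RIN"] = rng.normal(size=n)
    for k in range(1, 6):
        meta[f"PC{k}"] = rng.normal(size=n)
    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    meta["library_size"] = np.round(lib).astype(np.int64)
    ref_lib = float(np.sqrt(lo * hi))

    n_out = int(round(config.outlier_fraction * n))
    outlier = np.zeros(n, dtype=bool)
    if n_out:
        outlier[rng.choice(n, size=n_out, replace=False)] = True
    meta["is_outlier"] = outlier

    # per-gene baselines and planted effects
    b0 = rng.uniform(*config.baseline_log_mu_range, size=G)
    sigma0 = rng.uniform(*config.baseline_sigma_range, size=G)
    n_sdv = int(round(config.sdv_fraction * G))
    is_sdv = np.zeros(G, dtype=bool)
    beta_sigma_sex = np.zeros(G)
    if n_sdv:
        idx = rng.choice(G, size=n_sdv, replace=False)
        is_sdv[idx] = True
        sign = rng.choice([-1.0, 1.0], size=n_sdv)
        beta_sigma_sex[idx] = sign * config.sdv_log_sigma_effect
    beta_mu_sex = np.zeros(G)
    n_sbe = int(round(config.sbe_fraction * G))
    if n_sbe:
        idx = rng.choice(G, size=n_sbe, replace=False)
        beta_mu_sex[idx] = rng.choice([-1.0, 1.0], size=n_sbe) * config.sbe_log_mu_effect

    # covariates enter the mean on a standardized scale
    zcov = np.column_stack(
        [(meta["age"].to_numpy() - 45.0) / 15.0]
        + [meta[c].to_numpy() for c in COVARIATES[1:]]
    )
    beta_cov = rng.normal(scale=config.covariate_effect_scale, size=(G, zcov.shape[1]))

    # outliers get an aberrant expression profile: gene-specific log-mean
    # perturbations (a uniform shift would be a pure library-size change and
    # vanish under CPM normalization)
    outlier_shift = np.zeros((G, n))
    if n_out:
        outlier_shift[:, outlier] = config.outlier_scale * rng.standard_normal((G, n_out))
    log_mu = (
        b0[:, None]
        + beta_cov @ zcov.T
        + beta_mu_sex[:, None] * male[None, :]
        + outlier_shift
        + np.log(meta["library_size"].to_numpy() / ref_lib)[None, :]
    )
    mu = np.exp(log_mu)
    sigma = sigma0[:, None] * np.exp(beta_sigma_sex[:, None] * male[None, :])
    r = 1.0 / sigma
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    direction = np.where(
        ~is_sdv, "none", np.where(beta_sigma_sex > 0, "male_higher", "female_higher")
    )
    truth = pd.DataFrame(
        {
            "is_sdv": is_sdv,
            "sdv_direction": direction,
            "true_beta_sigma_sex": beta_sigma_sex,
            "true_beta_mu_sex": beta_mu_sex,
            "baseline_log_mu": b0,
            "baseline_sigma": sigma0,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    gene_meta = pd.DataFrame(
        {"chromosome": ["autosome"] * G}, index=pd.Index(gene_ids, name="gene")
    )
    counts_df = pd.DataFrame(counts, index=gene_meta.index, columns=meta.index)
    return ExpressionStudy(counts=counts_df, sample_meta=meta, gene_meta=gene_meta, truth=truth)


def generate_gene_sets(
    n_sets: int,
    universe: list[str],
    labels: pd.Series | None = None,
    target_label: str | None = None,
    planted_overlap: float = 0.0,
    n_planted: int = 0,
    set_size_range: tuple[int, int] = (15, 100),
    seed: int = 0,
) -> tuple[dict[str, list[str]], list[str]]:
    """Random gene sets, optionally with planted overrepresentation.

    Planted sets draw a ``planted_overlap`` fraction of their members from
    genes carrying ``target_label``; all other members (and all members of
    null sets) are sampled uniformly from the universe.

    Returns the collection (name -> member list) and the planted set names.
    """
    if len(universe) == 0:
        raise ValueError("universe must be nonempty")
    if not 0.0 <= planted_overlap <= 1.0:
        raise ValueError("planted_overlap must lie in [0, 1]")
    if n_planted > n_sets:
        raise ValueError("n_planted cannot exceed n_sets")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    labeled: list[str] = []
    if n_planted and planted_overlap > 0:
        if labels is None or target_label is None:
            raise ValueError("planted sets need gene labels and a target label")
        labeled = [g for g in universe if labels.get(g) == target_label]
        if not labeled:
            raise ValueError("no universe gene carries the target label")
    sets: dict[str, list[str]] = {}
    planted_names: list[str] = []
    for i in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        size = min(size, len(universe))
        name = f"SET_{i:04d}"
        if i < n_planted:
            k = min(int(round(planted_overlap * size)), len(labeled))
            members = list(rng.choice(labeled, size=k, replace=False))
            pool = [g for g in universe if g not in set(members)]
            members += list(rng.choice(pool, size=size - k, replace=False))
            planted_names.append(name)
        else:
            members = list(rng.choice(universe, size=size, replace=False))
        sets[name] = sorted(members)
    return sets, planted_names


def generate_egene_labels(
    tissues: list[str],
    genes: list[str],
    sdv_calls: dict[str, pd.Series],
    depletion_factor: float,
    base_rate: float = 0.3,
    seed: int = 0,
) -> dict[str, pd.Series]:
    """Per-tissue eGene flags with planted depletion among SDV genes.

    P(eGene | SDV) = depletion_factor * P(eGene | not SDV), clipped to [0, 1].
    """
    if depletion_factor < 0:
        raise ValueError("depletion_factor must be nonnegative")
    rng = np.random.default_rng(seed)
    out: dict[str, pd.Series] = {}
    p_sdv = float(np.clip(depletion_factor * base_rate, 0.0, 1.0))
    for t in tissues:
        sdv = sdv_calls[t].reindex(genes).fillna(False).to_numpy(dtype=bool)
        p = np.where(sdv, p_sdv, base_rate)
        out[t] = pd.Series(rng.random(len(genes)) < p, index=pd.Index(genes, name="gene"))
    return out


def generate_sc_counts(
    n_cells_per_type: tuple[int, int, int] = (120, 100, 80),
    n_markers_per_type: int = 20,
    n_housekeeping: int = 60,
    marker_rate: float = 5.0,
    housekeeping_rate: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Labeled single-cell counts with exclusive markers per cell type.

    Marker genes are Poisson-expressed only in their own type (so their
    pseudo-bulk specificity is exactly 1); housekeeping genes are expressed
    at a common rate in every cell.
    """
    if any(c < 1 for c in n_cells_per_type):
        raise ValueError("need at least one cell per type")
    rng = np.random.default_rng(seed)
    types = ["L1", "L2", "basal"]
    labels = np.repeat(types, n_cells_per_type)
    n_cells = len(labels)
    gene_ids, cols = [], []
    for t_idx, t in enumerate(types):
        for m in range(n_markers_per_type):
            gene_ids.append(f"MARK_{t}_{m:03d}")
            lam = np.where(labels == t, marker_rate, 0.0)
            cols.append(rng.poisson(lam))
    for h in range(n_housekeeping):
        gene_ids.append(f"HK_{h:03d}")
        cols.append(rng.poisson(housekeeping_rate, size=n_cells))
    counts = pd.DataFrame(
        np.column_stack(cols),
        index=pd.Index([f"C{i:05d}" for i in range(n_cells)], name="cell"),
        columns=pd.Index(gene_ids, name="gene"),
    )
    return counts, pd.Series(labels, index=counts.index, name="cell_type")
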