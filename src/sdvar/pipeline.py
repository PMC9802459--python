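"""Per-tissue discovery of sex-differentially variable (SDV) genes.

The procedure, applied independently within each tissue:

1. counts-per-million (CPM) computation and removal of genes with zero CPM
   in any individual;
2. removal of global expression outliers by Tukey fences on principal
   component scores of log2(CPM + 1);
3. upper-quartile normalization factors and a log(library size x factor)
   offset;
4. per-gene NB location-scale fits of three nested models — both mean and
   overdispersion on sex + age + ischemic time + RIN + PC1..PC5 (model 1),
   sex dropped from overdispersion (model 2), sex dropped from mean
   (model 3) — with chi-square(1) likelihood-ratio tests for the two sex
   terms, Benjamini-Hochberg correction per test family;
5. a permutation empirical null for the sex-dispersion coefficient of every
   gene passing the BH screen (sex labels shuffled, covariates left in
   place), BH correction of the empirical p-values;
6. the SDV call: screened q < alpha AND permutation q < alpha, with
   direction from the sign of the sex-dispersion coefficient (male = 1
   coding, positive means more variable in males).

A stratified discovery/replication split with a random-gene-sampling null
replication rate mirrors the validation design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nb
from .synth import COVARIATES, ExpressionStudy

__all__ = [
    "NormalizedStudy",
    "compute_cpm",
    "filter_expressed",
    "uq_norm_factors",
    "pca_outlier_removal",
    "bh_adjust",
    "build_designs",
    "test_all_genes",
    "test_gene",
    "permutation_test",
    "call_sdv",
    "normalize_study",
    "run_sdv",
    "replication_analysis",
    "null_replication_rate",
]


@dataclass
class NormalizedStudy:
    counts: pd.DataFrame  # filtered genes x kept samples
    cpm: pd.DataFrame
    norm_factors: pd.Series
    offset: pd.Series  # log(library_size * norm_factor)
    kept_samples: list[str]
    kept_genes: list[str]


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """CPM with library size taken as the column sum; columns sum to 1e6."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    return counts * (1e6 / lib)


def filter_expressed(cpm: pd.DataFrame) -> list[str]:
    """Genes kept iff CPM > 0 in every individual."""
    keep = (cpm > 0).all(axis=1)
    return cpm.index[keep].tolist()


def uq_norm_factors(counts: pd.DataFrame) -> pd.Series:
    """Upper-quartile normalization factors, rescaled to geometric mean 1.

    The raw factor is the 75th percentile of a sample's counts over genes
    with any expression (nonzero row sum), divided by the library size.
    """
    expressed = counts.loc[counts.sum(axis=1) > 0]
    lib = counts.sum(axis=0)
    q75 = expressed.quantile(0.75, axis=0)
    if (q75 <= 0).any():
        bad = q75.index[q75 <= 0].tolist()
        raise ValueError(f"degenerate upper quartile (zero) in samples: {bad}")
    raw = q75 / lib
    factors = raw / np.exp(np.mean(np.log(raw)))
    factors.name = "norm_factor"
    return factors


def pca_outlier_removal(
    log2_cpm: pd.DataFrame, var_share: float = 0.05, whisker: float = 1.5
) -> list[str]:
    """Kept sample ids after Tukey-fence screening of PC scores.

    PCA is run on samples (genes as centered features); along every
    component explaining more than ``var_share`` of total variance, samples
    outside [Q1 - whisker*IQR, Q3 + whisker*IQR] of the scores are removed.
    Single pass, no iteration.
    """
    if log2_cpm.shape[1] < 3:
        raise ValueError("need at least 3 samples for outlier screening")
    X = log2_cpm.to_numpy(dtype=np.float64).T  # samples x genes
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    share = var / var.sum() if var.sum() > 0 else var
    scores = U * s
    out = np.zeros(X.shape[0], dtype=bool)
    for k in np.flatnonzero(share > var_share):
        sc = scores[:, k]
        q1, q3 = np.percentile(sc, [25, 75])
        iqr = q3 - q1
        out |= (sc > q3 + whisker * iqr) | (sc < q1 - whisker * iqr)
    return log2_cpm.columns[~out].tolist()


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, in [0, 1])."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def build_designs(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    """Model-1 design matrix (shared by mean and dispersion) and sex column.

    Columns: intercept, sex (male = 1), then z-scored continuous covariates.
    Returns (X, sex_indicator, sex_column_index).
    """
    male = (meta["sex"].to_numpy() == "male").astype(np.float64)
    if male.sum() == 0 or male.sum() == len(male):
        raise ValueError("both sexes must be present")
    cols = [np.ones(len(meta)), male]
    for c in COVARIATES:
        v = meta[c].to_numpy(dtype=np.float64)
        sd = v.std()
        cols.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
    X = np.column_stack(cols)
    return X, male, 1


def test_all_genes(
    counts: pd.DataFrame, meta: pd.DataFrame, offset: np.ndarray,
    return_coefs: bool = False,
):
    """Fit models 1-3 for every gene (batched) and run both sex LRTs.

    Returns a per-gene frame with the model-1 sex coefficients for mean and
    overdispersion, LRT p-values, log-likelihoods and convergence flags.
    """
    X, _, sex_col = build_designs(meta)
    X_red = np.delete(X, sex_col, axis=1)
    Y = counts.to_numpy(dtype=np.float64)
    pm = X.shape[1]

    b1, ll1, c1, _ = nb.fit_batch(Y, X, X, offset)
    # warm start nested models from the full fit with the sex term dropped
    s2 = np.delete(b1, pm + sex_col, axis=1)
    b2, ll2, c2, _ = nb.fit_batch(Y, X, X_red, offset, start=s2)
    s3 = np.delete(b1, sex_col, axis=1)
    b3, ll3, c3, _ = nb.fit_batch(Y, X_red, X, offset, start=s3)

    converged = c1 & c2 & c3
    # guard against a reduced fit beating the full model (failed optimum)
    tol = 1e-4 * (1.0 + np.abs(ll1))
    converged &= (ll1 >= ll2 - tol) & (ll1 >= ll3 - tol)
    from scipy import stats

    p_sigma = stats.chi2.sf(np.maximum(2.0 * (ll1 - ll2), 0.0), 1)
    p_mu = stats.chi2.sf(np.maximum(2.0 * (ll1 - ll3), 0.0), 1)
    out = pd.DataFrame(
        {
            "beta_mu_sex": b1[:, sex_col],
            "beta_sigma_sex": b1[:, pm + sex_col],
            "p_sigma_sex": p_sigma,
            "p_mu_sex": p_mu,
            "loglik_full": ll1,
            "converged": converged,
        },
        index=counts.index,
    )
    if return_coefs:
        return out, b1
    return out


def test_gene(y, meta: pd.DataFrame, offset) -> pd.Series:
    """Single-gene version of :func:`test_all_genes`."""
    df = test_all_genes(
        pd.DataFrame([np.asarray(y)], index=["gene"]), meta, np.asarray(offset)
    )
    return df.iloc[0]


def permutation_test(
    y,
    meta: pd.DataFrame,
    offset,
    beta_obs: float,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    start: np.ndarray | None = None,
    max_fail: float = 0.2,
) -> tuple[float, bool]:
    """Empirical p for the sex-dispersion coefficient under label shuffling.

    Only the sex labels are permuted; every other covariate stays attached
    to its sample. The empirical p is the fraction of permutations whose
    refitted |beta_sigma_sex| strictly exceeds |beta_obs| (denominator B,
    no smoothing). Returns (p, reliable); reliable is False when more than
    ``max_fail`` of permutation fits failed to converge.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X, male, sex_col = build_designs(meta)
    n = X.shape[0]
    perm_male = np.empty((B, n))
    for b in range(B):
        perm_male[b] = rng.permutation(male)
    X_perm = np.broadcast_to(X, (B,) + X.shape).copy()
    X_perm[:, :, sex_col] = perm_male
    Y = np.broadcast_to(np.asarray(y, dtype=np.float64), (B, n))
    bcoef, _, conv, _ = nb.fit_batch(Y, X_perm, X_perm, np.asarray(offset), start=start)
    pm = X.shape[1]
    beta_perm = bcoef[:, pm + sex_col]
    ok = conv
    fail_rate = 1.0 - ok.mean()
    p = float(np.sum(np.abs(beta_perm[ok]) > abs(beta_obs)) / B)
    return p, fail_rate <= max_fail


def call_sdv(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Final SDV calls: screened BH q and permutation BH q both below alpha."""
    res = results.copy()
    ok_q = res["q_sigma_sex"] < alpha
    ok_perm = res["perm_q"].notna() & (res["perm_q"] < alpha)
    res["is_sdv"] = ok_q & ok_perm & res["converged"]
    res["direction"] = np.where(
        ~res["is_sdv"], "none", np.where(res["beta_sigma_sex"] > 0, "male_higher", "female_higher")
    )
    return res


def normalize_study(
    counts: pd.DataFrame, remove_outliers: bool = True
) -> NormalizedStudy:
    """CPM filter, outlier removal and upper-quartile offsets for one tissue."""
    cpm_all = compute_cpm(counts)
    if remove_outliers:
        kept_samples = pca_outlier_removal(np.log2(cpm_all + 1.0))
    else:
        kept_samples = counts.columns.tolist()
    sub = counts[kept_samples]
    cpm = compute_cpm(sub)
    kept_genes = filter_expressed(cpm)
    filtered = sub.loc[kept_genes]
    factors = uq_norm_factors(filtered)
    lib = filtered.sum(axis=0)
    offset = np.log(lib * factors)
    offset.name = "offset"
    return NormalizedStudy(
        counts=filtered,
        cpm=cpm.loc[kept_genes],
        norm_factors=factors,
        offset=offset,
        kept_samples=kept_samples,
        kept_genes=kept_genes,
    )


def run_sdv(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    remove_outliers: bool = True,
    min_sex_count: int = 3,
) -> pd.DataFrame:
    """The full per-tissue SDV procedure; one result row per tested gene."""
    norm = normalize_study(counts, remove_outliers=remove_outliers)
    meta_kept = meta.loc[norm.kept_samples]
    sexes = meta_kept["sex"].value_counts()
    if sexes.get("male", 0) < min_sex_count or sexes.get("female", 0) < min_sex_count:
        raise ValueError("fewer than the minimum samples of one sex survive outlier removal")

    res, coefs = test_all_genes(
        norm.counts, meta_kept, norm.offset.to_numpy(), return_coefs=True
    )
    tested = res.copy()
    conv = tested["converged"].to_numpy()
    # BH over all tested (converged) genes, per test family
    tested["q_sigma_sex"] = np.nan
    tested["q_mu_sex"] = np.nan
    tested.loc[conv, "q_sigma_sex"] = bh_adjust(tested.loc[conv, "p_sigma_sex"].to_numpy())
    tested.loc[conv, "q_mu_sex"] = bh_adjust(tested.loc[conv, "p_mu_sex"].to_numpy())

    rng = np.random.default_rng(seed)
    screened = tested.index[tested["q_sigma_sex"] < alpha].tolist()
    perm_p = pd.Series(np.nan, index=tested.index)
    reliable = pd.Series(True, index=tested.index)
    X, male, sex_col = build_designs(meta_kept)
    pm = X.shape[1]
    offs = norm.offset.to_numpy()
    gene_pos = {g: i for i, g in enumerate(norm.counts.index)}
    # batch several genes' permutation refits into one Newton solve; the
    # permuted labels carry no sex effect, so each refit starts at the
    # observed fit with both sex coefficients zeroed
    chunk = max(1, 200 // B)
    for i0 in range(0, len(screened), chunk):
        genes = screened[i0 : i0 + chunk]
        c = len(genes)
        perm_male = rng.permuted(np.tile(male, (c * B, 1)), axis=1)
        Xp = np.broadcast_to(X, (c * B,) + X.shape).copy()
        Xp[:, :, sex_col] = perm_male
        Y = np.repeat(norm.counts.loc[genes].to_numpy(dtype=np.float64), B, axis=0)
        starts = np.repeat(coefs[[gene_pos[g] for g in genes]], B, axis=0).copy()
        starts[:, sex_col] = 0.0
        starts[:, pm + sex_col] = 0.0
        bcoef, _, conv, _ = nb.fit_batch(Y, Xp, Xp, offs, start=starts)
        beta = bcoef[:, pm + sex_col].reshape(c, B)
        convc = conv.reshape(c, B)
        for j, g in enumerate(genes):
            ok = convc[j]
            beta_obs = float(tested.loc[g, "beta_sigma_sex"])
            perm_p.loc[g] = float(np.sum(np.abs(beta[j][ok]) > abs(beta_obs)) / B)
            reliable.loc[g] = ok.mean() >= 0.8
    tested["perm_p"] = perm_p
    perm_q = pd.Series(np.nan, index=tested.index)
    if screened:
        # BH over the screened family (the genes that entered permutation)
        perm_q.loc[screened] = bh_adjust(tested.loc[screened, "perm_p"].to_numpy())
    tested["perm_q"] = perm_q
    tested.loc[~reliable, "converged"] = False

    out = call_sdv(tested, alpha=alpha)
    out.index.name = "gene"
    out.attrs["kept_samples"] = norm.kept_samples
    out.attrs["n_removed_samples"] = counts.shape[1] - len(norm.kept_samples)
    out.attrs["n_filtered_genes"] = counts.shape[0] - len(norm.kept_genes)
    out.attrs["n_nonconverged"] = int((~out["converged"]).sum())
    return out


def _stratified_split(meta: pd.DataFrame, split: float, rng) -> tuple[list[str], list[str]]:
    disc, repl = [], []
    for sex in ("male", "female"):
        ids = meta.index[meta["sex"] == sex].tolist()
        k = int(round(split * len(ids)))
        picked = set(rng.choice(ids, size=k, replace=False))
        disc += [i for i in ids if i in picked]
        repl += [i for i in ids if i not in picked]
    return disc, repl


def replication_analysis(
    study: ExpressionStudy,
    split: float = 0.7,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Discovery/replication validation of the SDV procedure.

    Samples are split by sex (``split`` into discovery); discovery runs the
    full procedure; a discovery call replicates when, in the replication
    set, both the dispersion LRT p and the permutation p are < 0.05
    (nominal) and the more-variable sex agrees.
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    meta = study.sample_meta
    disc_ids, repl_ids = _stratified_split(meta, split, rng)
    for ids, name in ((disc_ids, "discovery"), (repl_ids, "replication")):
        m = meta.loc[ids, "sex"].value_counts()
        if m.get("male", 0) < 10 or m.get("female", 0) < 10:
            raise ValueError(f"fewer than 10 samples of one sex in the {name} set")

    disc = run_sdv(
        study.counts[disc_ids], meta.loc[disc_ids], B=B, alpha=alpha,
        seed=int(rng.integers(2**31)),
    )
    hits = disc.index[disc["is_sdv"]].tolist()

    repl = _replication_eval(study, repl_ids, hits, disc, B=B, rng=rng)
    n_repl = int(repl["replicated"].sum()) if len(repl) else 0
    rate = n_repl / len(hits) if hits else float("nan")
    return {
        "discovery": disc,
        "replication": repl,
        "discovery_ids": disc_ids,
        "replication_ids": repl_ids,
        "n_discovered": len(hits),
        "n_replicated": n_repl,
        "replication_rate": rate,
    }


def _replication_eval(
    study: ExpressionStudy,
    repl_ids: list[str],
    genes: list[str],
    disc: pd.DataFrame,
    B: int,
    rng,
) -> pd.DataFrame:
    """Nominal-level LRT + permutation check of given genes in the replication set."""
    meta_r = study.sample_meta.loc[repl_ids]
    norm_r = normalize_study(study.counts[repl_ids], remove_outliers=False)
    rows = []
    genes = [g for g in genes if g in norm_r.counts.index]
    if not genes:
        return pd.DataFrame(
            columns=["beta_sigma_sex", "p_sigma_sex", "perm_p", "replicated"]
        )
    res_r = test_all_genes(norm_r.counts.loc[genes], meta_r, norm_r.offset.to_numpy())
    for g in genes:
        row = res_r.loc[g]
        perm_p, ok = permutation_test(
            norm_r.counts.loc[g].to_numpy(dtype=np.float64),
            meta_r,
            norm_r.offset.to_numpy(),
            beta_obs=float(row["beta_sigma_sex"]),
            B=B,
            seed=rng,
        )
        same_dir = np.sign(row["beta_sigma_sex"]) == np.sign(disc.loc[g, "beta_sigma_sex"])
        rows.append(
            {
                "gene": g,
                "beta_sigma_sex": row["beta_sigma_sex"],
                "p_sigma_sex": row["p_sigma_sex"],
                "perm_p": perm_p,
                "replicated": bool(
                    row["converged"] and ok and row["p_sigma_sex"] < 0.05
                    and perm_p < 0.05 and same_dir
                ),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def null_replication_rate(
    study: ExpressionStudy,
    replication: dict,
    n_draws: int = 10000,
    draw_size: int | None = None,
    B: int = 200,
    seed: int = 0,
) -> dict:
    """Replication rate of randomly sampled discovery-tested genes.

    Each draw samples ``draw_size`` genes uniformly from all genes tested in
    the discovery set and computes their replication rate against the fixed
    replication set, giving the null distribution the observed rate is
    compared to. ``draw_size`` defaults to the discovery-significant count.
    """
    rng = np.random.default_rng(seed)
    disc = replication["discovery"]
    tested = disc.index.tolist()
    if draw_size is None:
        draw_size = max(int(replication["n_discovered"]), 1)
    if draw_size > len(tested):
        raise ValueError("draw_size exceeds the number of discovery-tested genes")

    # evaluate replication status once per unique gene, then sample
    pool = sorted(set(tested))
    flags = _replication_eval(
        study, replication["replication_ids"], pool, disc, B=B, rng=rng
    )["replicated"]
    repl_flags = np.array([bool(flags.get(g, False)) for g in pool])
    rates = np.empty(n_draws)
    for d in range(n_draws):
        idx = rng.choice(len(pool), size=draw_size, replace=False)
        rates[d] = repl_flags[idx].mean()
    return {"rates": rates, "median": float(np.median(rates))}
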