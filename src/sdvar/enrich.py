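"""Overrepresentation tests and cross-tissue permutation meta-analysis.

Per-tissue enrichment of a gene set for a label of interest (e.g. "genes
more variable in females") is scored with an upper-tail hypergeometric test.
Tissue-level p-values are combined with Fisher's statistic T = -2 * sum(ln p),
but because hypergeometric p-values are discrete the chi-square reference
distribution is invalid; the null for T is instead built by permuting gene
labels independently within each tissue and recomputing every per-tissue
p-value. The same label-permutation machinery drives the eGene-depletion
test: per-tissue fold enrichment of eGenes among SDV genes, a two-sided
Fisher exact test per tissue, and a one-sided permutation test of whether
the cross-tissue median fold is lower than expected by chance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hypergeom_overrep",
    "fisher_combined_perm",
    "egene_depletion",
    "score_rank_test",
]

_P_FLOOR = np.finfo(np.float64).tiny


def hypergeom_overrep(overlap: int, set_size: int, label_count: int, universe_size: int):
    """Upper-tail hypergeometric p-value P(X >= overlap), observed value included."""
    overlap = np.asarray(overlap)
    if np.any(overlap > np.minimum(set_size, label_count)) or np.any(
        np.asarray([set_size, label_count]) > universe_size
    ):
        raise ValueError("inconsistent hypergeometric counts")
    if np.any(overlap < 0):
        raise ValueError("overlap must be nonnegative")
    p = stats.hypergeom.sf(overlap - 1, universe_size, label_count, set_size)
    return float(p) if np.ndim(overlap) == 0 else p


def _tissue_perm_pvalues(rng, z, S, set_sizes, M, B):
    """Observed and permuted per-set hypergeometric p-values for one tissue.

    z is the 0/1 target-label indicator over the tissue universe; S the
    boolean set-membership matrix (sets x genes). Permuting gene labels
    within the tissue is realized by permuting z.
    """
    K = int(z.sum())
    ov_obs = S @ z
    p_obs = stats.hypergeom.sf(ov_obs - 1, M, K, set_sizes)
    Z = rng.permuted(np.tile(z, (B, 1)), axis=1).T.astype(np.float32)
    ov_perm = (S.astype(np.float32) @ Z).round()
    p_perm = stats.hypergeom.sf(ov_perm - 1, M, K, set_sizes[:, None])
    return p_obs, p_perm


def fisher_combined_perm(
    labels_by_tissue: dict[str, pd.Series],
    sets: dict[str, list[str]],
    target_label: str,
    B: int = 10000,
    seed: int = 0,
    min_label_count: int = 20,
    exclude_sets: list[str] | None = None,
) -> pd.DataFrame:
    """Permutation-calibrated Fisher combination of per-tissue enrichments.

    Tissues with fewer than ``min_label_count`` genes carrying the target
    label are excluded. Returns one row per set: T_obs, the empirical
    permutation p (fraction of permuted T >= T_obs) and its BH adjustment,
    plus each tissue's observed hypergeometric p.
    """
    import warnings

    if B < 100:
        warnings.warn("fewer than 100 permutations gives a very coarse empirical p")
    rng = np.random.default_rng(seed)
    exclude = set(exclude_sets or [])
    set_names = [s for s in sets if s not in exclude]
    tissues = [
        t for t, lab in labels_by_tissue.items()
        if int((lab == target_label).sum()) >= min_label_count
    ]
    if not tissues:
        raise ValueError("no tissue passes the minimum label-count rule")

    T_obs = np.zeros(len(set_names))
    T_perm = np.zeros((len(set_names), B))
    tissue_p = {}
    for t in tissues:
        lab = labels_by_tissue[t]
        universe = lab.index.to_numpy()
        gene_idx = {g: i for i, g in enumerate(universe)}
        M = len(universe)
        S = np.zeros((len(set_names), M), dtype=bool)
        for si, name in enumerate(set_names):
            idx = [gene_idx[g] for g in sets[name] if g in gene_idx]
            S[si, idx] = True
        set_sizes = S.sum(axis=1)
        z = (lab.to_numpy() == target_label).astype(np.float64)
        p_obs, p_perm = _tissue_perm_pvalues(rng, z, S, set_sizes, M, B)
        tissue_p[t] = p_obs
        T_obs += -2.0 * np.log(np.maximum(p_obs, _P_FLOOR))
        T_perm += -2.0 * np.log(np.maximum(p_perm, _P_FLOOR))

    perm_p = (T_perm >= T_obs[:, None]).sum(axis=1) / B
    from .pipeline import bh_adjust

    out = pd.DataFrame(
        {"T_obs": T_obs, "perm_p": perm_p, "perm_q": bh_adjust(perm_p)},
        index=pd.Index(set_names, name="set"),
    )
    for t in tissues:
        out[f"p_{t}"] = tissue_p[t]
    out.attrs["tissues"] = tissues
    return out


def egene_depletion(
    sdv_by_tissue: dict[str, pd.Series],
    egene_by_tissue: dict[str, pd.Series],
    B: int = 10000,
    seed: int = 0,
    min_sdv: int = 20,
) -> dict:
    """Depletion of eGenes among SDV genes, aggregated as a median fold.

    Per tissue: the 2x2 SDV x eGene table, fold enrichment (observed over
    expected overlap) and a two-sided Fisher exact p, BH-adjusted across
    tissues. The cross-tissue median fold is tested one-sidedly against a
    null built by permuting SDV labels within each tissue: the empirical p
    is the fraction of permutation rounds whose median fold is at most the
    observed one.
    """
    rng = np.random.default_rng(seed)
    rows = []
    folds_perm = []
    tissues = []
    for t, sdv in sdv_by_tissue.items():
        eg = egene_by_tissue[t]
        genes = sdv.index.intersection(eg.index)
        s = sdv.loc[genes].to_numpy(dtype=bool)
        e = eg.loc[genes].to_numpy(dtype=bool)
        if s.sum() < min_sdv:
            continue
        if not s.any() or not e.any():
            import warnings

            warnings.warn(f"tissue {t}: empty SDV or eGene set after intersection; dropped")
            continue
        M = len(genes)
        ov = int((s & e).sum())
        table = [[ov, int(s.sum() - ov)], [int(e.sum() - ov), M - int(s.sum()) - int(e.sum()) + ov]]
        expected = s.sum() * e.sum() / M
        fold = ov / expected
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {"tissue": t, "overlap": ov, "n_sdv": int(s.sum()), "n_egene": int(e.sum()),
             "universe": M, "fold": fold, "fisher_p": p, "odds_ratio": odds}
        )
        tissues.append(t)
        # permuted SDV labels, eGene labels fixed
        Z = rng.permuted(np.tile(s.astype(np.float32), (B, 1)), axis=1)
        ov_perm = Z @ e.astype(np.float32)
        folds_perm.append(ov_perm / expected)
    if not rows:
        raise ValueError("no tissue passes the minimum SDV-count rule")
    per_tissue = pd.DataFrame(rows).set_index("tissue")
    from .pipeline import bh_adjust

    per_tissue["fisher_q"] = bh_adjust(per_tissue["fisher_p"].to_numpy())
    median_obs = float(per_tissue["fold"].median())
    median_perm = np.median(np.vstack(folds_perm), axis=0)
    perm_p = float((median_perm <= median_obs).sum() / B)
    return {
        "per_tissue": per_tissue,
        "median_fold": median_obs,
        "perm_p": perm_p,
        "null_medians": median_perm,
    }


def score_rank_test(scores_a, scores_b) -> float:
    """Two-sided Mann-Whitney U p-value with tie correction."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
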