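"""Power and false-positive-rate simulations for dispersion-difference tests.

Two groups of counts are drawn from negative binomial distributions with a
common mean and overdispersions sigma and sigma + delta_sigma; each draw is
tested with three procedures:

* Fligner-Killeen and Levene's test (mean-centered by default) applied to
  ln(counts + 1) — rank/ANOVA tests of scale on the log scale;
* the NB location-scale likelihood-ratio test applied to the raw counts,
  comparing (mu ~ group, sigma ~ group) against (mu ~ group, sigma ~ 1)
  on one degree of freedom.

Power (or FPR when delta_sigma = 0) is the fraction of replicates whose
p-value falls below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import nb

__all__ = ["PowerGridSpec", "draw_pair", "run_three_tests", "nb_lrt_batch", "power_grid"]

TESTS = ["fligner_killeen", "levene", "nb_lrt"]


@dataclass
class PowerGridSpec:
    """Simulation grid; defaults follow a GTEx-scale design.

    The mean is fixed at 1500 counts and the two groups total 400 samples;
    the unbalanced design is 320 vs 80. The baseline overdispersion grid and
    the proportional delta grid span the range typical of bulk RNA-seq.
    """

    mu: float = 1500.0
    group_sizes: tuple[tuple[int, int], ...] = ((200, 200), (320, 80))
    sigma_base: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)
    delta_factors: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0)
    reps: int = 1000
    alpha: float = 0.05
    seed: int = 0
    levene_center: str = "mean"

    def validate(self) -> None:
        if self.mu <= 0 or self.reps < 1 or not 0 < self.alpha < 1:
            raise ValueError("invalid grid specification")
        if not self.sigma_base or not self.delta_factors:
            raise ValueError("grids must be nonempty")
        if any(s <= 0 for s in self.sigma_base) or any(d < 0 for d in self.delta_factors):
            raise ValueError("sigma_base must be positive and deltas nonnegative")


def _nb_draw(rng, mu: float, sigma: float, size) -> np.ndarray:
    if sigma < nb.SIGMA_FLOOR:
        return rng.poisson(mu, size=size)
    r = 1.0 / sigma
    return rng.negative_binomial(r, r / (r + mu), size=size)


def draw_pair(n1: int, n2: int, mu: float, sigma1: float, sigma2: float, seed):
    """Two independent NB count samples with shared mean."""
    if min(n1, n2) < 1 or mu <= 0 or sigma1 < 0 or sigma2 < 0:
        raise ValueError("need positive sizes, positive mean, nonnegative sigmas")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _nb_draw(rng, mu, sigma1, n1), _nb_draw(rng, mu, sigma2, n2)


def run_three_tests(sample1, sample2, levene_center: str = "mean") -> dict[str, float]:
    """P-values from Fligner-Killeen, Levene and the NB dispersion LRT.

    The rank tests see ln(counts + 1); the LRT sees raw counts. A group that
    is constant after transformation makes the scale tests degenerate; those
    p-values are reported as 1.
    """
    y1 = np.asarray(sample1, dtype=np.float64)
    y2 = np.asarray(sample2, dtype=np.float64)
    if y1.size == 0 or y2.size == 0:
        raise ValueError("both samples must be nonempty")
    l1, l2 = np.log(y1 + 1.0), np.log(y2 + 1.0)
    degenerate = np.ptp(l1) == 0 or np.ptp(l2) == 0
    if degenerate:
        p_fk = p_lev = 1.0
    else:
        p_fk = float(stats.fligner(l1, l2).pvalue)
        p_lev = float(stats.levene(l1, l2, center=levene_center).pvalue)
    p_nb = float(nb_lrt_batch(np.concatenate([y1, y2])[None, :], y1.size, y2.size)[0])
    return {"fligner_killeen": p_fk, "levene": p_lev, "nb_lrt": p_nb, "degenerate": degenerate}


def nb_lrt_batch(Y: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Vectorized NB dispersion LRT over replicate rows of [group1, group2]."""
    n = n1 + n2
    grp = np.zeros(n)
    grp[n1:] = 1.0
    X = np.column_stack([np.ones(n), grp])
    X1 = np.ones((n, 1))
    _, ll_full, c_full, _ = nb.fit_batch(Y, X, X)
    _, ll_red, c_red, _ = nb.fit_batch(Y, X, X1)
    dev = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p = stats.chi2.sf(dev, 1)
    p[~(c_full & c_red)] = np.nan
    return p


def power_grid(spec: PowerGridSpec) -> pd.DataFrame:
    """Power/FPR table over the (group sizes) x sigma x delta grid.

    Each row gives, for one test at one grid point, the fraction of ``reps``
    p-values below alpha and its binomial Monte Carlo standard error.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for (n1, n2) in spec.group_sizes:
        for sigma in spec.sigma_base:
            for fac in spec.delta_factors:
                delta = fac * sigma
                Y1 = _nb_draw(rng, spec.mu, sigma, (spec.reps, n1))
                Y2 = _nb_draw(rng, spec.mu, sigma + delta, (spec.reps, n2))
                Y = np.concatenate([Y1, Y2], axis=1).astype(np.float64)
                L = np.log(Y + 1.0)
                p_fk = np.empty(spec.reps)
                p_lev = np.empty(spec.reps)
                for i in range(spec.reps):
                    a, b = L[i, :n1], L[i, n1:]
                    if np.ptp(a) == 0 or np.ptp(b) == 0:
                        p_fk[i] = p_lev[i] = 1.0
                        continue
                    p_fk[i] = stats.fligner(a, b).pvalue
                    p_lev[i] = stats.levene(a, b, center=spec.levene_center).pvalue
                p_nb = nb_lrt_batch(Y, n1, n2)
                for test, pv in (
                    ("fligner_killeen", p_fk),
                    ("levene", p_lev),
                    ("nb_lrt", p_nb),
                ):
                    ok = np.isfinite(pv)
                    frac = float((pv[ok] < spec.alpha).mean())
                    rows.append(
                        {
                            "test": test,
                            "n1": n1,
                            "n2": n2,
                            "sigma_base": sigma,
                            "delta_sigma": delta,
                            "power_or_fpr": frac,
                            "mc_se": float(np.sqrt(frac * (1 - frac) / ok.sum())),
                            "n_valid": int(ok.sum()),
                        }
                    )
    return pd.DataFrame(rows)
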