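"""Negative binomial location-scale regression.

The NB2 family is parametrized by a mean ``mu`` and an overdispersion
``sigma`` (the reciprocal of the classical size parameter ``theta``), so that

    Var(y) = mu + sigma * mu**2.

``sigma`` is the squared biological coefficient of variation: the excess,
non-Poisson component of variability. Both ``mu`` and ``sigma`` are modeled
on a log link as linear functions of covariates, with an optional offset on
the mean predictor to absorb library size. Nested models are compared with
chi-square likelihood-ratio tests.

The fitter is a damped Newton method on the joint coefficient vector,
batched across many responses (genes, permutations, simulation replicates)
sharing the same design, which is what makes genome-scale permutation
testing affordable in pure numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = ["NBDesign", "NBFit", "nb_loglik", "fit", "fit_batch", "lrt"]

# sigma below this is treated as (and fitted at) the Poisson limit
SIGMA_FLOOR = 1e-8
_ETA_S_MIN = np.log(SIGMA_FLOOR)
_ETA_S_MAX = 30.0
_ETA_MU_MAX = 45.0

_MAX_ITER = 200
_LL_RTOL = 1e-8
_GRAD_TOL = 1e-5


@dataclass
class NBDesign:
    """One response vector with design matrices for mean and overdispersion.

    Both design matrices must contain an intercept column and be of full
    column rank; the offset is added to the linear predictor of ``log mu``.
    """

    y: np.ndarray
    X_mu: np.ndarray
    X_sigma: np.ndarray
    offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.X_mu = np.atleast_2d(np.asarray(self.X_mu, dtype=np.float64))
        self.X_sigma = np.atleast_2d(np.asarray(self.X_sigma, dtype=np.float64))
        n = self.y.shape[0]
        if self.offset is None:
            self.offset = np.zeros(n)
        self.offset = np.asarray(self.offset, dtype=np.float64)
        if self.X_mu.shape[0] != n or self.X_sigma.shape[0] != n or self.offset.shape[0] != n:
            raise ValueError("y, X_mu, X_sigma and offset must have equal row counts")
        if np.any(self.y < 0) or np.any(self.y != np.floor(self.y)):
            raise ValueError("response must contain nonnegative integers")
        for name, X in (("X_mu", self.X_mu), ("X_sigma", self.X_sigma)):
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(f"{name} is rank deficient")


@dataclass
class NBFit:
    """Maximum-likelihood coefficients for one NB location-scale model."""

    beta_mu: np.ndarray
    beta_sigma: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float = field(default=np.nan)


def nb_loglik(y, mu, sigma) -> float:
    """Total NB2 log-likelihood sum_i log NB(y_i; mu_i, sigma_i).

    With r = 1/sigma the term for one observation is

        lgamma(y + r) - lgamma(r) - lgamma(y + 1)
        + r*log(r / (r + mu)) + y*log(mu / (r + mu)),

    which tends to the Poisson log-pmf as sigma -> 0; sigma below 1e-8
    is evaluated on that Poisson branch.
    """
    y = np.asarray(y, dtype=np.float64)
    mu = np.broadcast_to(np.asarray(mu, dtype=np.float64), y.shape)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=np.float64), y.shape)
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
        raise ValueError("mu and sigma must be finite")
    if np.any(mu <= 0) or np.any(sigma < 0):
        raise ValueError("mu must be positive and sigma nonnegative")
    out = np.empty_like(y)
    pois = sigma < SIGMA_FLOOR
    if np.any(pois):
        yp, mp = y[pois], mu[pois]
        out[pois] = yp * np.log(mp) - mp - special.gammaln(yp + 1.0)
    nb = ~pois
    if np.any(nb):
        yn, mn = y[nb], mu[nb]
        r = 1.0 / sigma[nb]
        out[nb] = (
            special.gammaln(yn + r)
            - special.gammaln(r)
            - special.gammaln(yn + 1.0)
            + r * (np.log(r) - np.log(r + mn))
            + yn * (np.log(mn) - np.log(r + mn))
        )
    return float(out.sum())


def _trigamma(x):
    """Vectorized trigamma via recurrence to x >= 6 plus asymptotic series."""
    x = np.asarray(x, dtype=np.float64)
    acc = np.zeros_like(x)
    xs = x.copy()
    for _ in range(6):
        small = xs < 6.0
        if not small.any():
            break
        inv = np.where(small, 1.0 / np.where(small, xs, 1.0) ** 2, 0.0)
        acc += inv
        xs = np.where(small, xs + 1.0, xs)
    z = 1.0 / xs
    z2 = z * z
    tail = z * (1.0 + z * (0.5 + z * (1.0 / 6.0 + z2 * (-1.0 / 30.0 + z2 * (1.0 / 42.0 - z2 / 30.0)))))
    return acc + tail


def _predictors(b, X_mu, X_sigma, offset):
    pm = X_mu.shape[-1]
    eta_mu = np.matmul(X_mu, b[..., :pm, None])[..., 0] + offset
    eta_s = np.matmul(X_sigma, b[..., pm:, None])[..., 0]
    eta_mu = np.clip(eta_mu, -_ETA_MU_MAX, _ETA_MU_MAX)
    eta_s = np.clip(eta_s, _ETA_S_MIN, _ETA_S_MAX)
    return np.exp(eta_mu), np.exp(-eta_s)  # mu, r = 1/sigma


def _batch_loglik(y, mu, r):
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * (np.log(r) - np.log(r + mu))
        + y * (np.log(mu) - np.log(r + mu))
    ).sum(axis=-1)


def _grad_hess(y, mu, r, X_mu, X_sigma):
    """Per-batch gradient and observed-information Hessian on the link scale."""
    rm = r + mu
    g_mu = r * (y - mu) / rm
    A = special.psi(y + r) - special.psi(r) + np.log(r) - np.log(rm) + (mu - y) / rm
    g_s = -r * A
    A1 = _trigamma(y + r) - _trigamma(r) + 1.0 / r - 1.0 / rm - (mu - y) / rm**2
    w_mm = -mu * r * (y + r) / rm**2
    w_ss = r * r * A1 + r * A
    w_ms = -mu * r * (y - mu) / rm**2

    Xm_t = np.swapaxes(X_mu, -1, -2)
    Xs_t = np.swapaxes(X_sigma, -1, -2)
    grad = np.concatenate(
        [
            np.matmul(Xm_t, g_mu[..., None])[..., 0],
            np.matmul(Xs_t, g_s[..., None])[..., 0],
        ],
        axis=-1,
    )
    H_mm = np.matmul(Xm_t, X_mu * w_mm[..., None])
    H_ss = np.matmul(Xs_t, X_sigma * w_ss[..., None])
    H_ms = np.matmul(Xm_t, X_sigma * w_ms[..., None])
    top = np.concatenate([H_mm, H_ms], axis=-1)
    bot = np.concatenate([np.swapaxes(H_ms, -1, -2), H_ss], axis=-1)
    return grad, np.concatenate([top, bot], axis=-2)


def _poisson_irls(y, X_mu, offset, n_iter: int = 30):
    """Batched Poisson regression warm start for the mean coefficients."""
    pm = X_mu.shape[-1]
    batch = y.shape[:-1]
    b = np.zeros(batch + (pm,))
    b[..., 0] = np.log(np.maximum(y.mean(axis=-1), 0.5)) - np.mean(offset, axis=-1)
    for _ in range(n_iter):
        eta = np.einsum("...np,...p->...n", X_mu, b) + offset
        eta = np.clip(eta, -_ETA_MU_MAX, _ETA_MU_MAX)
        mu = np.exp(eta)
        z = eta - offset + (y - mu) / mu
        XtW = np.swapaxes(X_mu, -1, -2) * mu[..., None, :]
        H = XtW @ X_mu
        H += 1e-10 * np.eye(pm)
        rhs = np.einsum("...pn,...n->...p", XtW, z)
        b_new = np.linalg.solve(H, rhs[..., None])[..., 0]
        if np.max(np.abs(b_new - b)) < 1e-10:
            b = b_new
            break
        b = b_new
    return b


def fit_batch(y, X_mu, X_sigma, offset=None, start=None):
    """Fit NB location-scale models for a batch of responses.

    Parameters
    ----------
    y : (B, n) or (n,) array of counts.
    X_mu, X_sigma : (n, p) design matrices shared across the batch, or
        (B, n, p) per-element designs.
    offset : optional (n,) or (B, n) additive offset for log-mean.
    start : optional (B, pm+ps) warm-start coefficients.

    Returns
    -------
    params : (B, pm+ps) coefficients (mean block first).
    loglik : (B,) maximized log-likelihoods.
    converged : (B,) bool flags.
    n_iter : (B,) iteration counts.
    """
    y = np.asarray(y, dtype=np.float64)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[None, :]
    B, n = y.shape
    X_mu = np.asarray(X_mu, dtype=np.float64)
    X_sigma = np.asarray(X_sigma, dtype=np.float64)
    if X_mu.ndim == 2:
        X_mu = np.broadcast_to(X_mu, (B,) + X_mu.shape)
    if X_sigma.ndim == 2:
        X_sigma = np.broadcast_to(X_sigma, (B,) + X_sigma.shape)
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=np.float64)
    if offset.ndim == 1:
        offset = np.broadcast_to(offset, (B, n))
    pm, ps = X_mu.shape[-1], X_sigma.shape[-1]
    p = pm + ps

    if start is None:
        b = np.zeros((B, p))
        b[:, :pm] = _poisson_irls(y, X_mu, offset)
        # method-of-moments overdispersion intercept from Poisson residuals
        eta = np.einsum("bnp,bp->bn", X_mu, b[:, :pm]) + offset
        mu0 = np.exp(np.clip(eta, -_ETA_MU_MAX, _ETA_MU_MAX))
        num = ((y - mu0) ** 2 - mu0).sum(axis=-1)
        den = (mu0**2).sum(axis=-1)
        sig0 = np.clip(num / np.maximum(den, 1e-300), 1e-4, 1e4)
        b[:, pm] = np.log(sig0)
    else:
        b = np.array(start, dtype=np.float64)
        if b.ndim == 1:
            b = np.broadcast_to(b, (B, p)).copy()

    mu, r = _predictors(b, X_mu, X_sigma, offset)
    ll = _batch_loglik(y, mu, r)
    converged = np.zeros(B, dtype=bool)
    n_iter = np.zeros(B, dtype=int)
    eye = np.eye(p)

    for it in range(_MAX_ITER):
        act = ~converged
        if not act.any():
            break
        ya, Xma, Xsa = y[act], X_mu[act], X_sigma[act]
        offa, ba, lla = offset[act], b[act], ll[act]
        mua, ra = _predictors(ba, Xma, Xsa, offa)
        grad, H = _grad_hess(ya, mua, ra, Xma, Xsa)
        gmax = np.abs(grad).max(axis=-1)

        # damped Newton: escalate ridge until the solve is finite, then
        # halve the step until the log-likelihood does not decrease
        scale = np.abs(np.diagonal(H, axis1=-2, axis2=-1)).max(axis=-1)
        scale = np.maximum(scale, 1.0)
        step = np.zeros_like(ba)
        todo = np.ones(ba.shape[0], dtype=bool)
        ridge = 1e-10
        while todo.any() and ridge < 1e12:
            idx = np.flatnonzero(todo)
            Hr = -(H[idx] - (ridge * scale[idx])[:, None, None] * eye)
            try:
                sol = np.linalg.solve(Hr, grad[idx][..., None])[..., 0]
            except np.linalg.LinAlgError:
                sol = np.full((idx.size, p), np.nan)
            # a usable Newton direction must be finite and uphill
            ascent = np.einsum("bp,bp->b", sol, grad[idx])
            good = np.all(np.isfinite(sol), axis=-1) & (ascent > 0)
            step[idx[good]] = sol[good]
            todo[idx[good]] = False
            ridge *= 100.0

        new_b = ba + step
        new_ll = np.full_like(lla, -np.inf)
        pending = np.ones(ba.shape[0], dtype=bool)
        for _ in range(40):
            if not pending.any():
                break
            mu_t, r_t = _predictors(new_b[pending], Xma[pending], Xsa[pending], offa[pending])
            ll_t = _batch_loglik(ya[pending], mu_t, r_t)
            ok = np.isfinite(ll_t) & (ll_t >= lla[pending] - 1e-12 * (1.0 + np.abs(lla[pending])))
            idx = np.flatnonzero(pending)
            new_ll[idx[ok]] = ll_t[ok]
            pending[idx[ok]] = False
            bad = idx[~ok]
            new_b[bad] = ba[bad] + 0.5 * (new_b[bad] - ba[bad])
        # elements whose line search never succeeded stay put this iteration
        stuck = pending
        new_b[stuck] = ba[stuck]
        new_ll[stuck] = lla[stuck]

        dll = new_ll - lla
        done = (np.abs(dll) < _LL_RTOL * (1.0 + np.abs(new_ll))) & (gmax < _GRAD_TOL)
        done |= stuck & (gmax < 10 * _GRAD_TOL)
        b[act], ll[act] = new_b, new_ll
        idx_act = np.flatnonzero(act)
        converged[idx_act[done]] = True
        n_iter[idx_act] += 1

    # rare stragglers: polish individually with a quasi-Newton fallback
    for i in np.flatnonzero(~converged):
        res = optimize.minimize(
            lambda bb: -_batch_loglik(
                y[i], *_predictors(bb, X_mu[i], X_sigma[i], offset[i])
            ),
            b[i],
            jac=lambda bb: -_grad_hess(
                y[i], *_predictors(bb, X_mu[i], X_sigma[i], offset[i]), X_mu[i], X_sigma[i]
            )[0],
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if np.isfinite(res.fun) and -res.fun >= ll[i]:
            b[i], ll[i] = res.x, -res.fun
        g, _ = _grad_hess(y[i], *_predictors(b[i], X_mu[i], X_sigma[i], offset[i]), X_mu[i], X_sigma[i])
        converged[i] = np.abs(g).max() < 1e-3

    if squeeze:
        return b[0], ll[0], converged[0], n_iter[0]
    return b, ll, converged, n_iter


def fit(design: NBDesign) -> NBFit:
    """Maximum-likelihood fit of one NB location-scale model."""
    if np.all(design.y == 0):
        raise ValueError("response is identically zero")
    b, ll, conv, it = fit_batch(design.y, design.X_mu, design.X_sigma, design.offset)
    pm = design.X_mu.shape[1]
    mu, r = _predictors(b, design.X_mu, design.X_sigma, design.offset)
    g, _ = _grad_hess(design.y, mu, r, design.X_mu, design.X_sigma)
    return NBFit(
        beta_mu=b[:pm],
        beta_sigma=b[pm:],
        loglik=float(ll),
        converged=bool(conv),
        n_iter=int(it),
        grad_norm=float(np.abs(g).max()),
    )


def lrt(full: NBFit, reduced: NBFit, df: int) -> float:
    """Chi-square likelihood-ratio p-value for nested NB fits."""
    if df < 1:
        raise ValueError("df must be a positive integer")
    dev = 2.0 * (full.loglik - reduced.loglik)
    if dev < -1e-6 * (1.0 + abs(full.loglik)):
        raise ValueError(
            f"full-model log-likelihood below reduced ({full.loglik} < {reduced.loglik}); fit failed"
        )
    return float(stats.chi2.sf(max(dev, 0.0), df))
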