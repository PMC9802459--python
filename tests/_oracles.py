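"""Brute-force oracles used by multiple test modules."""

import itertools

import numpy as np

from sdvar import nb


def lattice_oracle(y, X_mu, X_sigma, offset, center, width=1.5, steps=9):
    """Coarse grid search over coefficients; independent of the Newton path."""
    grids = [np.linspace(c - width, c + width, steps) for c in center]
    best = -np.inf
    for combo in itertools.product(*grids):
        b = np.array(combo)
        pm = X_mu.shape[1]
        mu = np.exp(np.clip(X_mu @ b[:pm] + offset, -40, 40))
        sigma = np.exp(np.clip(X_sigma @ b[pm:], -18, 25))
        best = max(best, nb.nb_loglik(y, mu, sigma))
    return best
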