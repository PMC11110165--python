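"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from first principles (plain numpy
linear algebra, nested loops) and shares no code path with rxnopt.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import norm


def matern52(XA: np.ndarray, XB: np.ndarray, length_scales, signal_var) -> np.ndarray:
    """Anisotropic Matern-5/2 kernel matrix."""
    ls = np.asarray(length_scales, dtype=float)
    d = (XA[:, None, :] - XB[None, :, :]) / ls
    r = np.sqrt((d**2).sum(-1))
    s = np.sqrt(5.0) * r
    return signal_var * (1.0 + s + s**2 / 3.0) * np.exp(-s)


def gp_posterior(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    signal_var: float,
    length_scales,
    noise: float,
    y_mean: float | None = None,
    alpha: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Textbook Gaussian conditioning: posterior mean and sd at Xte.

    The training covariance carries the fitted noise plus the solver jitter
    ``alpha``; the predictive variance carries signal + noise (a new
    measurement's variance), matching the convention of the package model.
    """
    if y_mean is None:
        y_mean = float(np.mean(ytr))
    K = matern52(Xtr, Xtr, length_scales, signal_var)
    K[np.diag_indices_from(K)] += noise + alpha
    Ks = matern52(Xte, Xtr, length_scales, signal_var)
    L = cholesky(K, lower=True)
    coef = cho_solve((L, True), ytr - y_mean)
    mean = y_mean + Ks @ coef
    v = solve_triangular(L, Ks.T, lower=True)
    var = (signal_var + noise) - (v**2).sum(axis=0)
    return mean, np.sqrt(np.clip(var, 0.0, None))


def expected_improvement_ref(mean, sd, best, xi=0.0):
    """Scalar closed-form EI, written independently of the package."""
    mean, sd = float(mean), float(sd)
    gain = mean - best - xi
    if sd == 0.0:
        return max(gain, 0.0)
    z = gain / sd
    return gain * norm.cdf(z) + sd * norm.pdf(z)


def replay_brute_force(alkynes, conversions, threshold):
    """Double-loop convergence scan over a history.

    Returns (first_pass, counts): for each substrate the 1-based index of
    its first conversion strictly above the threshold (None if never) and
    the number of its own observations strictly before that index.
    """
    labels = sorted(set(alkynes))
    first = {}
    for a in labels:
        idx = None
        for i in range(len(alkynes)):
            if alkynes[i] == a and conversions[i] > threshold:
                idx = i + 1
                break
        first[a] = idx
    counts = {}
    for a in labels:
        n = 0
        stop = first[a] if first[a] is not None else len(alkynes) + 1
        for i in range(len(alkynes)):
            if alkynes[i] == a and (i + 1) < stop:
                n += 1
        counts[a] = n
    return first, counts
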