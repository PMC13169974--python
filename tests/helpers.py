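"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: brute-force loops,
closed forms and linear-program transport, so they can validate the fast
implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def brute_force_cv(values: np.ndarray, kernel: int) -> np.ndarray:
    """Per-pixel double-loop CV over clipped kernel windows (population SD)."""
    r = kernel // 2
    out = np.full(values.shape, np.nan)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            if not np.isfinite(values[i, j]):
                continue
            win = values[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1]
            w = win[np.isfinite(win)]
            if w.size == 0:
                continue
            mu = w.mean()
            if mu == 0:
                continue
            out[i, j] = w.std() / mu
    return out


def brute_force_nan_median(values: np.ndarray, radius: int) -> np.ndarray:
    """Window-by-window NaN-aware median (clipped windows)."""
    out = np.full(values.shape, np.nan)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            win = values[
                max(0, i - radius) : i + radius + 1,
                max(0, j - radius) : j + radius + 1,
            ]
            w = win[np.isfinite(win)]
            if w.size:
                out[i, j] = np.median(w)
    return out


def wrapped_exp_bin_probs(tau: float, period: float, n_bins: int) -> np.ndarray:
    """Analytic bin probabilities of a periodically wrapped exponential decay.

    Wrapping multiplies every within-period bin integral by the same
    geometric series factor, so the normalized probabilities equal the
    truncated-exponential bin integrals renormalized over one period.
    """
    edges = np.linspace(0.0, period, n_bins + 1)
    p = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
    return p / p.sum()


def merge_small_bins(observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0):
    """Aggregate trailing bins until every expected count is >= min_expected."""
    obs_out, exp_out = [], []
    acc_o, acc_e = 0.0, 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_out.append(acc_o)
            exp_out.append(acc_e)
            acc_o, acc_e = 0.0, 0.0
    if acc_e > 0 and exp_out:
        obs_out[-1] += acc_o
        exp_out[-1] += acc_e
    return np.array(obs_out), np.array(exp_out)


def transport_w1_lp(sample_a, sample_b) -> float:
    """First-order Wasserstein distance by explicit linear-program transport.

    Solves min sum_ij |a_i - b_j| x_ij subject to uniform marginals — the
    optimal-transport definition, independent of the sorting shortcut.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    # row marginals: sum_j x_ij = 1/na; column marginals: sum_i x_ij = 1/nb
    a_eq = []
    b_eq = []
    for i in range(na):
        row = np.zeros((na, nb))
        row[i, :] = 1.0
        a_eq.append(row.ravel())
        b_eq.append(1.0 / na)
    for j in range(nb):
        col = np.zeros((na, nb))
        col[:, j] = 1.0
        a_eq.append(col.ravel())
        b_eq.append(1.0 / nb)
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.array(b_eq), bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)
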