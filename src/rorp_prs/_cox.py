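"""Efron partial-likelihood derivatives for score tests.

The Cox fits themselves go through lifelines; this module only supplies the
log partial likelihood with gradient and Hessian under Efron tie handling,
which lifelines does not expose, for the Grønnesby–Borgan score test.
"""

from __future__ import annotations

import numpy as np


def efron_loglik(
    beta: np.ndarray, time: np.ndarray, event: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """(log partial likelihood, gradient, Hessian) at ``beta``, Efron ties."""
    beta = np.asarray(beta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    order = np.argsort(-time, kind="mergesort")  # descending time
    t_s, e_s, X_s = time[order], event[order], X[order]
    eta = X_s @ beta
    eta -= eta.max()  # common shift cancels in every ratio and in ll up to constant
    w = np.exp(eta)
    wX = w[:, None] * X_s
    wXX = wX[:, :, None] * X_s[:, None, :]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # add the whole tie group to the risk set
        S0 += w[i:j].sum()
        S1 += wX[i:j].sum(axis=0)
        S2 += wXX[i:j].sum(axis=0)
        deaths = np.flatnonzero(e_s[i:j] == 1) + i
        d = len(deaths)
        if d:
            D0 = w[deaths].sum()
            D1 = wX[deaths].sum(axis=0)
            D2 = wXX[deaths].sum(axis=0)
            ll += eta[deaths].sum()
            grad += X_s[deaths].sum(axis=0)
            for el in range(d):
                f = el / d
                phi0 = S0 - f * D0
                phi1 = S1 - f * D1
                phi2 = S2 - f * D2
                ll -= np.log(phi0)
                r1 = phi1 / phi0
                grad -= r1
                hess -= phi2 / phi0 - np.outer(r1, r1)
        i = j
    return ll, grad, hess


def score_test(
    time: np.ndarray,
    event: np.ndarray,
    X_base: np.ndarray,
    beta_base: np.ndarray,
    X_add: np.ndarray,
) -> tuple[float, int]:
    """Score (Rao) test for adding ``X_add`` to a fitted Cox model.

    Evaluates the Efron score and information of the augmented model at
    (beta_base, 0) and returns (chi2 statistic, df).
    """
    X_full = np.column_stack([X_base, X_add])
    beta_full = np.concatenate([np.asarray(beta_base, float), np.zeros(X_add.shape[1])])
    _, grad, hess = efron_loglik(beta_full, time, event, X_full)
    info = -hess
    stat = float(grad @ np.linalg.solve(info, grad))
    return stat, X_add.shape[1]
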