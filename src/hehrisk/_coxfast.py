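"""Lightweight Newton-Raphson Cox partial-likelihood solver.

The subset-discovery search fits thousands of small Cox models per
cohort, so this module provides a vectorised solver (Efron tie handling,
Wald covariance from the observed information) tuned for binary design
matrices with few columns.  The user-facing model interface in
:mod:`hehrisk.survival` wraps lifelines; this solver is cross-checked
against it in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CoxConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class FastCoxFit:
    beta: np.ndarray
    loglik: float
    cov: np.ndarray  # inverse observed information
    n_events: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _prepare(X, time, event):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order]


def _loglik_grad_hess(x, t, d, beta):
    """Efron partial log-likelihood, gradient and Hessian (of -loglik)."""
    n, p = x.shape
    eta = x @ beta
    eta -= eta.max()  # guards overflow; constant shift cancels
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]
    # reverse cumulative risk-set sums; row i holds sum over {j: t_j >= t_i}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev_idx = np.flatnonzero(d)
    if ev_idx.size == 0:
        raise ValueError("no events")
    ev_t = t[ev_idx]
    # index of first row with time >= each event time (risk-set start)
    start = np.searchsorted(t, ev_t, side="left")

    untied = np.unique(ev_t).size == ev_t.size
    if untied:
        s0 = S0[start]
        s1 = S1[start]
        s2 = S2[start]
        ll = float(np.sum(eta[ev_idx] - np.log(s0)))
        g = s1 / s0[:, None]
        grad = x[ev_idx].sum(axis=0) - g.sum(axis=0)
        hess = np.einsum("kij,k->ij", s2, 1.0 / s0) - np.einsum("ki,kj->ij", g, g)
        return ll, grad, hess

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for ut in np.unique(ev_t):
        rows = ev_idx[ev_t == ut]
        dsz = rows.size
        i0 = np.searchsorted(t, ut, side="left")
        s0r, s1r, s2r = S0[i0], S1[i0], S2[i0]
        s0d = w[rows].sum()
        s1d = wx[rows].sum(axis=0)
        s2d = wxx[rows].sum(axis=0)
        ll += float(eta[rows].sum())
        grad += x[rows].sum(axis=0)
        for l in range(dsz):
            f = l / dsz
            den = s0r - f * s0d
            num1 = s1r - f * s1d
            num2 = s2r - f * s2d
            ll -= np.log(den)
            g = num1 / den
            grad -= g
            hess += num2 / den - np.outer(g, g)
    return ll, grad, hess


def null_loglik(time, event) -> float:
    """Partial log-likelihood of the model with no covariates."""
    x = np.zeros((np.asarray(time).size, 1))
    xs, ts, ds = _prepare(x, time, event)
    ll, _, _ = _loglik_grad_hess(xs, ts, ds, np.zeros(1))
    return ll


def fit(X, time, event, max_iter=50, tol=1e-9) -> FastCoxFit:
    """Maximise the Efron partial likelihood by damped Newton iteration.

    Raises :class:`CoxConvergenceError` (with the iteration trace) when
    the iteration fails to converge, and :class:`ValueError` for constant
    covariates or designs with no events.
    """
    x, t, d = _prepare(X, time, event)
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("no events in the data")
    if np.any(x.std(axis=0) == 0):
        bad = np.flatnonzero(x.std(axis=0) == 0)
        raise ValueError(f"constant covariate column(s): {list(bad)}")

    p = x.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(x, t, d, beta)
    trace = [(0, ll)]
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # damped step: halve until the likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(x, t, d, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise CoxConvergenceError(
                "step halving failed; possible complete separation -- "
                "consider exact or penalised methods",
                trace,
            )
        beta, ll_prev, ll = cand, ll, ll_new
        grad, hess = grad_new, hess_new
        trace.append((it, ll))
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)) or abs(ll - ll_prev) < tol:
            break
        if np.max(np.abs(beta)) > 50:
            raise CoxConvergenceError(
                "diverging coefficients; possible complete separation -- "
                "consider exact or penalised methods",
                trace,
            )
    else:
        raise CoxConvergenceError("Newton iteration did not converge", trace)

    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    return FastCoxFit(beta=beta, loglik=ll, cov=cov, n_events=n_events)
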