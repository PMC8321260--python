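"""Taylor and expected-gradient analysis of the two-step meta-update.

The interpolation meta-update can be understood through the short SGD
trajectory it induces: two support steps followed by one query step,

    phi_0 = theta
    phi_1 = phi_0 - a * L_s'(phi_0)
    phi_2 = phi_0 - a * L_s'(phi_0) - a * L_q'(phi_1),

where ``a`` is the inner learning rate.  The *effective gradient* of the
update is ``(phi_0 - phi_2) / a = L_s'(phi_0) + L_q'(phi_1)``; expanding
``L_q'(phi_1)`` around ``phi_0`` gives the truncated form

    g = L_s'(phi_0) + L_q'(phi_0) - a * L_q''(phi_0) L_s'(phi_0) + O(a^2).

The first two terms jointly minimise the expected loss over sampled batches;
the third, a gradient-alignment cross term, is what distinguishes this
update from plain averaged SGD.  Averaging the truncated gradient over the
batch distribution (Monte Carlo here) exposes each term's expectation.

These routines operate on scalar and low-dimensional losses with explicit
first and second derivatives; they serve as a correctness oracle for the
meta-update, not as a training path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "SmoothLoss",
    "QuadraticLoss",
    "LogCoshLoss",
    "Trajectory",
    "two_step_trajectory",
    "taylor_effective_gradient",
    "expected_gradient_mc",
]


@dataclass(frozen=True)
class SmoothLoss:
    """A loss with explicit value, gradient, and Hessian callables."""

    value: Callable[[np.ndarray], float]
    d1: Callable[[np.ndarray], np.ndarray]
    d2: Callable[[np.ndarray], np.ndarray]


def QuadraticLoss(c, a=1.0) -> SmoothLoss:
    """``L(phi) = a/2 (phi - c)^2`` (elementwise curvature ``a``)."""
    c = np.asarray(c, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    return SmoothLoss(
        value=lambda p: float(np.sum(0.5 * a * (p - c) ** 2)),
        d1=lambda p: a * (np.asarray(p, dtype=np.float64) - c),
        d2=lambda p: a * np.ones_like(np.asarray(p, dtype=np.float64)),
    )


def LogCoshLoss(c) -> SmoothLoss:
    """``L(phi) = log cosh(phi - c)``; non-zero third derivative."""
    c = np.asarray(c, dtype=np.float64)

    def d2(p):
        return 1.0 / np.cosh(np.asarray(p, dtype=np.float64) - c) ** 2

    return SmoothLoss(
        value=lambda p: float(np.sum(np.log(np.cosh(p - c)))),
        d1=lambda p: np.tanh(np.asarray(p, dtype=np.float64) - c),
        d2=d2,
    )


@dataclass(frozen=True)
class Trajectory:
    """The three parameter states of the two-step analysis."""

    phi0: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray

    def effective_gradient(self, alpha: float) -> np.ndarray:
        """``(phi0 - phi2) / alpha``, the update expressed as a gradient."""
        return (self.phi0 - self.phi2) / alpha


def _as_vec(phi) -> np.ndarray:
    return np.atleast_1d(np.asarray(phi, dtype=np.float64))


def two_step_trajectory(phi0, loss_s: SmoothLoss, loss_q: SmoothLoss, alpha: float) -> Trajectory:
    """Exact two-support-step / one-query-step SGD trajectory."""
    phi0 = _as_vec(phi0)
    g0 = np.asarray(loss_s.d1(phi0), dtype=np.float64)
    if not np.all(np.isfinite(g0)):
        raise FloatingPointError("non-finite support gradient at phi0")
    phi1 = phi0 - alpha * g0
    g1 = np.asarray(loss_q.d1(phi1), dtype=np.float64)
    if not np.all(np.isfinite(g1)):
        raise FloatingPointError("non-finite query gradient at phi1")
    phi2 = phi1 - alpha * g1
    return Trajectory(phi0=phi0, phi1=phi1, phi2=phi2)


def taylor_effective_gradient(phi0, loss_s: SmoothLoss, loss_q: SmoothLoss, alpha: float) -> np.ndarray:
    """First-order Taylor truncation of the effective gradient.

    Returns ``L_s'(phi0) + L_q'(phi0) - alpha * L_q''(phi0) L_s'(phi0)``.
    Exact (to rounding) for quadratic losses; O(alpha^2) error otherwise.
    """
    phi0 = _as_vec(phi0)
    gs = np.asarray(loss_s.d1(phi0), dtype=np.float64)
    gq = np.asarray(loss_q.d1(phi0), dtype=np.float64)
    hq = np.asarray(loss_q.d2(phi0), dtype=np.float64)
    if hq.ndim == 2:
        cross = hq @ gs
    else:
        cross = hq * gs
    return gs + gq - alpha * cross


def expected_gradient_mc(
    task_family: Callable[[np.random.Generator], SmoothLoss],
    phi,
    alpha: float,
    n_samples: int,
    rng: np.random.Generator,
) -> dict:
    """Monte-Carlo estimate of the expected truncated effective gradient.

    ``task_family(rng)`` draws one loss; each Monte-Carlo sample draws an
    independent support/query pair.  Returns the estimate of the total
    gradient and of its three components (support, query, cross term), each
    with a standard error of the mean.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 Monte-Carlo samples")
    phi = _as_vec(phi)
    dim = phi.size
    support = np.empty((n_samples, dim))
    query = np.empty((n_samples, dim))
    cross = np.empty((n_samples, dim))
    for i in range(n_samples):
        ls = task_family(rng)
        lq = task_family(rng)
        gs = np.asarray(ls.d1(phi), dtype=np.float64)
        gq = np.asarray(lq.d1(phi), dtype=np.float64)
        hq = np.asarray(lq.d2(phi), dtype=np.float64)
        support[i] = gs
        query[i] = gq
        cross[i] = (hq @ gs) if hq.ndim == 2 else hq * gs
    total = support + query - alpha * cross

    def _summ(x):
        mean = x.mean(axis=0)
        se = x.std(axis=0, ddof=1) / np.sqrt(n_samples)
        return mean, se

    est, se = _summ(total)
    s_m, s_se = _summ(support)
    q_m, q_se = _summ(query)
    c_m, c_se = _summ(cross)
    return {
        "estimate": est,
        "stderr": se,
        "support_term": (s_m, s_se),
        "query_term": (q_m, q_se),
        "cross_term": (c_m, c_se),
        "n_samples": n_samples,
    }
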