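"""Discrete-time normative belief filter for change-point environments.

A decision-maker observes a sequence of noisy samples generated by one of
two sources. At every step the active source may switch to the other with
probability ``H`` (the hazard rate). The posterior log-odds of the two
sources, ``L``, then obeys the update

    L_n = psi(L_{n-1}, H) + LLR_n

where ``LLR_n`` is the log-likelihood ratio of the new sample and ``psi``
maps the previous belief into the prior log-odds for the next sample:

    psi(L, H) = L + log[(1-H)/H + exp(-L)] - log[(1-H)/H + exp(L)]

``psi`` is the model's hazard-dependent nonlinearity: it leaks belief near
L = 0 (leak rate 2H to first order) and saturates at the non-absorbing
boundary +/- log((1-H)/H) for strong beliefs, so accumulation is suspended
without terminating the decision.

The probability-domain forward recursion (:func:`posterior_step`) is the
brute-force oracle for the log-odds filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LeakBias",
    "log_prior_odds",
    "belief_update",
    "run_filter",
    "posterior_step",
    "psi_slope",
    "leak_and_bias",
    "stabilizing_boundary",
    "leaky_prior",
    "bounded_prior",
]


@dataclass(frozen=True)
class LeakBias:
    """First-order (Taylor) approximation of ``psi`` around a reference belief.

    ``psi(L) ~= (1 - K) * L + theta``.  At L = 0, K = 2H and theta = 0; for
    |L| -> inf, K -> 1 and theta -> +/- log((1-H)/H).
    """

    K: float
    theta: float


def _check_hazard(H: float) -> float:
    H = float(H)
    if not math.isfinite(H) or H < 0.0 or H > 1.0:
        raise ValueError(f"hazard rate must lie in [0, 1], got {H!r}")
    return H


def _log_prior_ratio(H: float) -> float:
    """r = log((1-H)/H), the log prior-odds of 'no switch' vs 'switch'."""
    return math.log1p(-H) - math.log(H)


def log_prior_odds(L_prev, H):
    """Prior log-odds ``psi(L_prev, H)`` before observing the next sample.

    Evaluated as ``L + logaddexp(r, -L) - logaddexp(r, L)`` with
    ``r = log((1-H)/H)``, which is overflow-safe for |L| up to 1e4 and
    preserves the saturation value.

    ``H = 0`` and ``H = 1`` are handled as the analytic limits
    ``psi = L_prev`` (perfect integration) and ``psi = -L_prev``.

    Accepts scalar or array ``L_prev``; returns the matching shape.
    """
    H = _check_hazard(H)
    L = np.asarray(L_prev, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("L_prev must be finite")
    if H == 0.0:
        out = L.copy()
    elif H == 1.0:
        out = -L
    elif H == 0.5:
        # all three terms cancel analytically; return the exact zero
        out = np.zeros_like(L)
    else:
        r = _log_prior_ratio(H)
        out = L + np.logaddexp(r, -L) - np.logaddexp(r, L)
    return float(out) if np.isscalar(L_prev) or out.ndim == 0 else out


def belief_update(L_prev: float, llr: float, H: float) -> float:
    """One step of the normative filter: ``psi(L_prev, H) + llr``."""
    llr = float(llr)
    if not math.isfinite(llr):
        raise ValueError("llr must be finite")
    return log_prior_odds(L_prev, H) + llr


def run_filter(llr_seq: Sequence[float], H: float, L0: float = 0.0) -> np.ndarray:
    """Run the filter over a sequence of log-likelihood ratios.

    Returns the belief trajectory ``L_1..L_n`` (the initial belief ``L0`` is
    not included).  With ``H = 0`` this is ``L0 + cumsum(llr_seq)``; with
    ``H = 0.5`` the history is irrelevant and the output equals the input.
    """
    llrs = np.asarray(llr_seq, dtype=float)
    if llrs.size == 0:
        raise ValueError("llr_seq must be non-empty")
    if not np.all(np.isfinite(llrs)):
        raise ValueError("llr_seq must be finite")
    H = _check_hazard(H)
    L0 = float(L0)
    if H == 0.0:
        return L0 + np.cumsum(llrs)
    if H == 0.5:
        return llrs.copy()
    if H == 1.0:
        out = np.empty_like(llrs)
        L = L0
        for i, llr in enumerate(llrs):
            L = -L + llr
            out[i] = L
        return out
    r = _log_prior_ratio(H)
    out = np.empty_like(llrs)
    L = L0
    logaddexp = np.logaddexp
    for i, llr in enumerate(llrs):
        L = L + logaddexp(r, -L) - logaddexp(r, L) + llr
        out[i] = L
    return out


def posterior_step(q_prev, likelihood_pair, H):
    """Forward recursion in the probability domain (hidden-Markov filtering).

    ``q_i' \\propto p(x | z_i) * [(1-H) q_i + H q_j]``, normalized.  This is
    the textbook forward pass for a two-state hidden Markov model and serves
    as the independent oracle for the log-odds filter:
    ``log(q1'/q2') == belief_update(log(q1/q2), log-likelihood-ratio, H)``.
    """
    H = _check_hazard(H)
    q1, q2 = (float(v) for v in q_prev)
    l1, l2 = (float(v) for v in likelihood_pair)
    if q1 < 0 or q2 < 0 or q1 + q2 <= 0:
        raise ValueError("q_prev must be non-negative with positive sum")
    if l1 < 0 or l2 < 0:
        raise ValueError("likelihoods must be non-negative")
    if l1 == 0 and l2 == 0:
        raise ValueError("degenerate evidence: both likelihoods are zero")
    s = q1 + q2
    q1, q2 = q1 / s, q2 / s
    p1 = l1 * ((1.0 - H) * q1 + H * q2)
    p2 = l2 * (H * q1 + (1.0 - H) * q2)
    z = p1 + p2
    return (p1 / z, p2 / z)


def psi_slope(L, H):
    """Analytic derivative d psi / dL.

    ``1 - sigmoid(-(L + r)) - sigmoid(L - r)`` with ``r = log((1-H)/H)``;
    equals ``1 - 2H`` at L = 0 and tends to 0 as |L| -> inf.
    Requires ``0 < H < 1``.
    """
    H = _check_hazard(H)
    if H == 0.0 or H == 1.0:
        raise ValueError("psi_slope is degenerate at H = 0 or 1")
    r = _log_prior_ratio(H)
    L = np.asarray(L, dtype=float)
    # 1/(1 + exp(a)) evaluated stably
    def _inv1pexp(a):
        return np.where(a > 0, np.exp(-a) / (1.0 + np.exp(-a)), 1.0 / (1.0 + np.exp(np.minimum(a, 0))))
    out = 1.0 - _inv1pexp(L + r) - _inv1pexp(-L + r)
    return float(out) if out.ndim == 0 else out


def leak_and_bias(L_ref: float, H: float) -> LeakBias:
    """Leak rate ``K`` and bias ``theta`` of the first-order expansion at L_ref.

    ``K = 1 - dpsi/dL`` and ``theta = psi(L_ref) - (dpsi/dL) * L_ref``.
    Raises for H in {0, 1}, where the expansion is degenerate.
    """
    H = _check_hazard(H)
    if H == 0.0 or H == 1.0:
        raise ValueError("leak/bias expansion is degenerate at H = 0 or 1")
    slope = psi_slope(L_ref, H)
    psi = log_prior_odds(L_ref, H)
    return LeakBias(K=1.0 - slope, theta=psi - slope * float(L_ref))


def stabilizing_boundary(H: float) -> float:
    """Non-absorbing saturation level of the prior: ``log((1-H)/H)``.

    Positive for H < 0.5, zero at H = 0.5, negative for H > 0.5.  Unbounded
    (raises) at H in {0, 1}.
    """
    H = _check_hazard(H)
    if H == 0.0 or H == 1.0:
        raise ValueError("stabilizing boundary is unbounded at H = 0 or 1")
    return _log_prior_ratio(H)


def leaky_prior(L_prev, K):
    """Prior map of the leaky-accumulator approximation: ``(1 - K) * L``."""
    out = (1.0 - float(K)) * np.asarray(L_prev, dtype=float)
    return float(out) if out.ndim == 0 else out


def bounded_prior(L_prev, theta):
    """Prior map of the bounded accumulator: identity clipped at ``+/- theta``.

    Perfect integration between the stabilizing boundaries; the normative
    ``psi`` in its strong-belief regime corresponds to
    ``theta = log((1-H)/H)``.
    """
    theta = float(theta)
    if theta < 0:
        raise ValueError("theta must be non-negative")
    out = np.clip(np.asarray(L_prev, dtype=float), -theta, theta)
    return float(out) if out.ndim == 0 else out
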