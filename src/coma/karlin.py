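"""Karlin-Altschul statistics of discrete score distributions.

A score system (a finite set of score values s_k with probabilities p_k) is
*admissible* when its expected score is negative and at least one score is
positive.  For an admissible system the scale parameter lambda is the unique
positive root of

    sum_k p_k * exp(lambda * s_k) = 1,

the relative entropy is H = lambda * sum_k p_k s_k exp(lambda s_k), and K is
evaluated with the classical lattice series

    K = lambda' * exp(-2 sigma) / (H * (1 - exp(-lambda'))),

    sigma = sum_{k>=1} (1/k) * [ E(exp(lambda S_k); S_k < 0) + P(S_k >= 0) ],

where S_k is the k-step random walk of i.i.d. scores reduced to its lattice
span and lambda' is lambda per lattice step.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "InadmissibleScoreSystem",
    "collapse_distribution",
    "lattice_distribution",
    "solve_lambda",
    "solve_lambda_scaled",
    "entropy_H",
    "karlin_K",
]


class InadmissibleScoreSystem(ValueError):
    """Raised when a score distribution violates Karlin-Altschul conditions."""


def _check_admissible(values: np.ndarray, probs: np.ndarray) -> None:
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError("probabilities must sum to 1")
    if float(np.dot(probs, values)) >= 0:
        raise InadmissibleScoreSystem(
            "inadmissible score system: non-negative mean score")
    if not (values[probs > 0] > 0).any():
        raise InadmissibleScoreSystem(
            "inadmissible score system: no positive score")


def collapse_distribution(values, probs):
    """Merge duplicate score values, dropping zero-probability entries."""
    values = np.asarray(values, dtype=float).ravel()
    probs = np.asarray(probs, dtype=float).ravel()
    uniq, inv = np.unique(values, return_inverse=True)
    p = np.bincount(inv, weights=probs, minlength=uniq.size)
    keep = p > 0
    return uniq[keep], p[keep]


def lattice_distribution(scores, weights=None, c_bits: int = 5):
    """Integer lattice distribution of scores scaled by 2**c_bits and rounded.

    Returns ``(values, probs)`` with integer values on the lattice and the
    total probability mass per lattice point.  ``weights`` defaults to the
    uniform distribution over all entries of ``scores``.
    """
    s = np.asarray(scores, dtype=float).ravel()
    if weights is None:
        w = np.full(s.size, 1.0 / s.size)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        w = w / w.sum()
    lat = np.rint(s * (1 << c_bits)).astype(np.int64)
    lo, hi = int(lat.min()), int(lat.max())
    p = np.bincount(lat - lo, weights=w, minlength=hi - lo + 1)
    values = np.arange(lo, hi + 1)
    keep = p > 0
    return values[keep], p[keep]


def solve_lambda(values, probs, tol: float = 1e-10) -> float:
    """Unique positive root of sum p_k exp(lambda s_k) = 1.

    Bracketed bisection (via Brent's method) on (1e-6, 50), followed by a
    Newton polish.  Raises :class:`InadmissibleScoreSystem` if the system has
    a non-negative mean or no positive score.
    """
    values, probs = collapse_distribution(values, probs)
    _check_admissible(values, probs)

    def f(lam):
        return float(np.dot(probs, np.exp(lam * values))) - 1.0

    lo = 1e-6
    if f(lo) >= 0:  # mean barely negative; root below bracket floor
        lo = 1e-12
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 50:
            raise InadmissibleScoreSystem("no root found for lambda in (0, 50]")
    lam = brentq(f, lo, hi, xtol=tol)
    for _ in range(3):  # Newton polish
        e = np.exp(lam * values)
        g = float(np.dot(probs, e)) - 1.0
        dg = float(np.dot(probs, values * e))
        if dg == 0:
            break
        step = g / dg
        lam -= step
        if abs(step) < tol:
            break
    return float(lam)


def solve_lambda_scaled(scores, weights=None, c_bits: int = 5,
                        tol: float = 1e-8) -> float:
    """Solve lambda on scores discretized to c_bits of precision.

    The scores are multiplied by 2**c_bits, rounded to the nearest integer,
    and the root is solved on the resulting lattice; the returned lambda is
    expressed per original score unit.
    """
    values, probs = lattice_distribution(scores, weights, c_bits)
    lam_lat = solve_lambda(values, probs, tol=tol)
    return lam_lat * (1 << c_bits)


def entropy_H(values, probs, lam: float) -> float:
    """Relative entropy H = lambda * E[s * exp(lambda s)] (nats)."""
    values = np.asarray(values, dtype=float).ravel()
    probs = np.asarray(probs, dtype=float).ravel()
    return float(lam * np.dot(probs, values * np.exp(lam * values)))


def _lattice_span(values: np.ndarray) -> int:
    d = 0
    for v in values:
        d = math.gcd(d, abs(int(v)))
    return max(d, 1)


def karlin_K(values, probs, lam: float, max_iter: int = 500,
             rel_tol: float = 1e-5) -> float:
    """Karlin-Altschul K for an integer-valued admissible score distribution.

    ``lam`` is the solved lambda per score unit.  The distribution is reduced
    to its lattice span d (K is evaluated with lambda' = lambda * d); a span
    that cannot be determined raises a ValueError with a diagnostic.
    """
    values = np.asarray(values).ravel()
    probs = np.asarray(probs, dtype=float).ravel()
    if not np.issubdtype(values.dtype, np.integer):
        ints = np.rint(values).astype(np.int64)
        if np.max(np.abs(ints - values)) > 1e-9:
            raise ValueError("karlin_K requires integer (lattice) scores; "
                             "discretize with lattice_distribution first")
        values = ints
    values, probs = collapse_distribution(values, probs)
    values = values.astype(np.int64)
    _check_admissible(values, probs)

    d = _lattice_span(values)
    if d == 0:
        raise ValueError("lattice-period detection failed: all scores zero")
    values = values // d
    lam_lat = lam * d
    H = entropy_H(values, probs, lam_lat)  # invariant under span reduction

    lo, hi = int(values.min()), int(values.max())
    base = np.zeros(hi - lo + 1)
    base[values - lo] = probs

    # sigma series by repeated convolution of the step distribution; the
    # terms decay geometrically, but near-zero-drift systems converge
    # slowly, so stop only after several consecutive negligible terms
    sigma = 0.0
    P = np.ones(1)  # S_0 = 0
    offset = 0  # index 0 of P corresponds to score `offset`
    small = 0
    for k in range(1, max_iter + 1):
        P = np.convolve(P, base)
        offset += lo
        scores_k = np.arange(offset, offset + P.size)
        neg = scores_k < 0
        term = float(np.dot(P[neg], np.exp(lam_lat * scores_k[neg])))
        term += float(P[~neg].sum())
        sigma += term / k
        small = small + 1 if term / k < rel_tol * max(sigma, 1e-300) else 0
        if small >= 3 and k >= 8:
            break
    K = lam_lat * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam_lat)))
    return float(K)
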