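"""Position-dependent gap costs for a profile pair.

Gap cost limits are derived from the score system itself: conserved,
high-scoring positions should be expensive to interrupt, variable positions
cheap.  For every row (resp. column) of the score matrix the w largest
scores are kept; their autocorrelation (sum over all unordered pairs of
products, self-pairs included) divided by the number of summed products and
square-rooted gives a *characteristic value* on the scale of the maxima.  A
second autocorrelation of the characteristic values over a cyclic window of
size omega, normalized by omega*(omega+1)/2 and square-rooted, yields the
per-position gap cost limit A^(i) (B^(j) for the second profile); windows
with a non-positive product sum give a limit of 0.

A widening term z added to every multiplier inside both autocorrelations
inflates the limits when the score system is weak.  It is applied twice: in
pass 1 with z1 = zeta / sqrt(H), and after an initial alignment with
z2 = -y / (log E + x), so that a significant initial E-value narrows the
limits.

The final costs combine the limits with the thickness-adjusted indel
probabilities as a probabilistic OR, the deletion branch down-weighted by
c_del:

    G(i, j) = A^(i) * (1 - (c_del D^(i) + I'^(j) - c_del D^(i) I'^(j)))
    C(i, j) = B^(j) * (1 - (c_del D'^(j) + I^(i) - c_del D'^(j) I^(i)))

so gaps are most expensive where neither profile shows indel activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SearchConfig
from .profile import Profile, thickness_adjust

__all__ = ["GapModel", "top_max_scores", "characteristic_values",
           "gap_cost_limits", "widen_z1", "widen_z2", "final_gap_costs",
           "build_gap_model"]


@dataclass
class GapModel:
    A: np.ndarray      # (m,) gap cost limits, profile 1
    B: np.ndarray      # (n,) gap cost limits, profile 2
    G: np.ndarray      # (m, n) final deletion costs for profile 1
    C: np.ndarray      # (m, n) final costs for profile 2
    z: float = 0.0


def top_max_scores(scores: np.ndarray, axis: int, w: int = 4) -> np.ndarray:
    """Per-row (axis=0) or per-column (axis=1) top-w scores, descending.

    When fewer than w values exist the smallest kept value is repeated so
    the sequences stay length w (the periodic-sequence convention).
    """
    mat = scores if axis == 0 else scores.T
    k = min(w, mat.shape[1])
    top = -np.sort(-mat, axis=1)[:, :k]
    if k < w:
        pad = np.repeat(top[:, -1:], w - k, axis=1)
        top = np.concatenate([top, pad], axis=1)
    return top


def _pair_product_sum(vals: np.ndarray, z: float) -> np.ndarray:
    """Sum over all unordered pairs (self-pairs included) of (v_a+z)(v_b+z).

    ``vals`` is (n, w); returns (n,).  Equals ((sum v)^2 + sum v^2) / 2.
    Multipliers are floored at zero: a negative score carries no gap-cost
    signal, and the floor keeps the limits monotone in the widening term z.
    """
    shifted = np.maximum(vals + z, 0.0)
    s1 = shifted.sum(axis=1)
    s2 = (shifted ** 2).sum(axis=1)
    return 0.5 * (s1 ** 2 + s2)


def characteristic_values(maxima: np.ndarray, z: float = 0.0) -> np.ndarray:
    """Characteristic value per position from its top-w maxima.

    Square root of the autocorrelation (with +z on every multiplier) divided
    by the number of summed products w*(w+1)/2; non-positive sums give 0.
    """
    maxima = np.atleast_2d(np.asarray(maxima, dtype=float))
    w = maxima.shape[1]
    total = _pair_product_sum(maxima, z)
    n_products = w * (w + 1) / 2
    return np.sqrt(np.maximum(total, 0.0) / n_products)


def gap_cost_limits(char_values: np.ndarray, omega: int = 4,
                    z: float = 0.0) -> np.ndarray:
    """Second-level autocorrelation of characteristic values.

    For each position the window of omega consecutive characteristic values
    (cyclic continuation of the periodic sequence) is autocorrelated over
    all unordered pairs including self-pairs, normalized by
    omega*(omega+1)/2 and square-rooted; non-positive sums give 0.
    """
    a = np.asarray(char_values, dtype=float)
    m = a.size
    idx = (np.arange(m)[:, None] + np.arange(omega)[None, :]) % m
    return characteristic_values(a[idx], z)


def widen_z1(H: float, zeta: float = 1.0, z_max: float = 10.0) -> float:
    """Pass-1 widening term, inversely proportional to sqrt(H)."""
    if H <= 0:
        return z_max
    return min(zeta / np.sqrt(H), z_max)


def widen_z2(evalue: float, x: float = 0.0, y: float = 1.0,
             z_max: float = 10.0) -> float:
    """Pass-2 widening term z = -y / (log E + x).

    Small E-values (likely related pair) shrink z, narrowing the limits;
    E-values at or beyond the singularity log E + x >= 0 clamp to z_max.
    """
    if evalue <= 0:
        return 0.0
    denom = np.log(evalue) + x
    if denom >= 0:
        return z_max
    return float(np.clip(-y / denom, 0.0, z_max))


def final_gap_costs(A: np.ndarray, B: np.ndarray,
                    D1: np.ndarray, I1: np.ndarray,
                    D2: np.ndarray, I2: np.ndarray,
                    c_del: float = 0.6):
    """Two-sided final gap costs G (m, n) and C (m, n).

    ``D1``/``I1`` are the (thickness-adjusted) deletion and insertion
    probabilities of profile 1, ``D2``/``I2`` of profile 2.
    """
    dw1 = c_del * D1[:, None]
    iw2 = I2[None, :]
    G = A[:, None] * (1.0 - (dw1 + iw2 - dw1 * iw2))
    dw2 = c_del * D2[None, :]
    iw1 = I1[:, None]
    C = B[None, :] * (1.0 - (dw2 + iw1 - dw2 * iw1))
    return G, C


def build_gap_model(system_scores: np.ndarray, profile1: Profile,
                    profile2: Profile, cfg: SearchConfig = SearchConfig(),
                    z: float = 0.0) -> GapModel:
    """Gap model of a profile pair for a given widening term z."""
    max1 = top_max_scores(system_scores, axis=0, w=cfg.w)
    max2 = top_max_scores(system_scores, axis=1, w=cfg.w)
    a1 = characteristic_values(max1, z)
    a2 = characteristic_values(max2, z)
    A = gap_cost_limits(a1, cfg.omega, z)
    B = gap_cost_limits(a2, cfg.omega, z)
    D1 = thickness_adjust(profile1.del_prob, profile1.eff_seqs, cfg.u, cfg.v)
    I1 = thickness_adjust(profile1.ins_prob, profile1.eff_seqs, cfg.u, cfg.v)
    D2 = thickness_adjust(profile2.del_prob, profile2.eff_seqs, cfg.u, cfg.v)
    I2 = thickness_adjust(profile2.ins_prob, profile2.eff_seqs, cfg.u, cfg.v)
    G, C = final_gap_costs(A, B, D1, I1, D2, I2, cfg.c_del)
    return GapModel(A=A, B=B, G=G, C=C, z=z)
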