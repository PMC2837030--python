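"""Score system for a pair of profiles.

The cell score for matching position i of the first profile with position j
of the second is a symmetric cross log-odds: each profile's positional
log-odds scores are averaged over the observed weighted frequencies of the
other profile, and the result is normalized so that the uniform background
over cells sums the implied target probabilities to 1:

    L1_ij = sum_a f'_a^(j) * s_ia        (profile 1 scored on profile 2's
    L2_ij = sum_a f_a^(i)  * s'_ja        observed frequencies, and v.v.)

    s_ij  = mix(L1, L2) - ln(N) / lambda_p,
    N     = mean over cells of exp(lambda_p * mix(L1, L2)).

The *thickness correction* replaces the even mixture (L1+L2)/2 with the
weighted mixture (w1 L1 + w2 L2)/(w1 + w2), w1 = 1 - 1/t^(i),
w2 = 1 - 1/t'^(j): the contribution of a profile built from few effective
sequences (whose targets are pseudocount-dominated) is down-weighted, and a
pair of single-sequence profiles is left uncorrected.  Positions with
relative entropy below kappa/(-log E) are additionally scaled down by the
configurable factor (0.5 by default).

The scale parameter lambda of the finished system is solved on scores
discretized to ``c_bits`` bits of precision; composition-based statistics
then rescale the scores so that the solved lambda matches a reference value
(the initial table's lambda, or the lambda_u of a database's global score
system), making identical scores carry identical significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SearchConfig
from .karlin import (entropy_H, karlin_K, lattice_distribution,
                     solve_lambda, solve_lambda_scaled)
from .profile import Profile

__all__ = ["PairScoreSystem", "raw_pair_scores", "cross_logodds",
           "correct_scores", "entropy_downscale", "composition_scale",
           "build_pair_system"]


@dataclass
class PairScoreSystem:
    """Finished score system for one profile pair with solved statistics."""

    scores: np.ndarray          # (m, n)
    lambda_: float              # solved on the discretized scores, per unit
    H: float                    # relative entropy, nats
    K: float                    # Karlin-Altschul K
    N: float                    # background normalizer of the raw system
    lambda_ref: float           # reference lambda the scores are scaled to
    c_bits: int = 5

    @property
    def shape(self):
        return self.scores.shape


def cross_logodds(profile1: Profile, profile2: Profile):
    """The two cross log-odds components (L1, L2), each (m, n)."""
    if profile1.length == 0 or profile2.length == 0:
        raise ValueError("zero-length profile")
    L1 = profile1.scores @ profile2.obs_freq.T
    L2 = (profile2.scores @ profile1.obs_freq.T).T
    return L1, L2


def _normalize(mix: np.ndarray, lambda_p: float):
    odds = np.exp(lambda_p * mix)
    N = float(odds.mean())
    return mix - np.log(N) / lambda_p, N


def raw_pair_scores(profile1: Profile, profile2: Profile) -> np.ndarray:
    """Uncorrected pair score matrix (even mixture, normalized)."""
    L1, L2 = cross_logodds(profile1, profile2)
    lam_p = profile1.lambda_ref
    s, _ = _normalize(0.5 * (L1 + L2), lam_p)
    return s


def correct_scores(L1: np.ndarray, L2: np.ndarray,
                   eff1: np.ndarray, eff2: np.ndarray) -> np.ndarray:
    """Thickness-weighted mixture of the cross log-odds components.

    Weights w1 = 1 - 1/t^(i) and w2 = 1 - 1/t'^(j) vanish for
    single-sequence profiles; cells where both weights are zero fall back to
    the uncorrected even mixture (no correction for a pair of
    single-sequence profiles).
    """
    w1 = np.maximum(0.0, 1.0 - 1.0 / np.asarray(eff1, dtype=float))[:, None]
    w2 = np.maximum(0.0, 1.0 - 1.0 / np.asarray(eff2, dtype=float))[None, :]
    total = w1 + w2
    even = 0.5 * (L1 + L2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mixed = (w1 * L1 + w2 * L2) / total
    return np.where(total > 0, mixed, even)


def entropy_threshold(expected_evalue: float, kappa: float = 1.0) -> float:
    """Low-information threshold tau = kappa / (-log E); disabled for E >= 1."""
    if expected_evalue >= 1.0:
        return 0.0
    return kappa / (-np.log(expected_evalue))


def entropy_downscale(scores: np.ndarray, rel_ent1: np.ndarray,
                      rel_ent2: np.ndarray, expected_evalue: float = 1e-4,
                      kappa: float = 1.0, factor: float = 0.5) -> np.ndarray:
    """Scale down rows/columns whose positional relative entropy is low.

    Rows of profile 1 (columns of profile 2) with relative entropy below the
    threshold are multiplied by ``factor``; a threshold disabled by
    E >= 1 leaves the matrix unchanged.
    """
    tau = entropy_threshold(expected_evalue, kappa)
    out = scores.copy()
    out[np.asarray(rel_ent1) < tau, :] *= factor
    out[:, np.asarray(rel_ent2) < tau] *= factor
    return out


def composition_scale(scores: np.ndarray, lambda_star: float,
                      lambda_ref: float) -> np.ndarray:
    """Rescale scores so the solved lambda becomes the reference value.

    Uses the identity lambda(r * s) = lambda(s) / r: multiplying the scores
    by lambda_star / lambda_ref moves the solved parameter onto the
    reference.
    """
    return scores * (lambda_star / lambda_ref)


def build_pair_system(profile1: Profile, profile2: Profile,
                      cfg: SearchConfig = SearchConfig(),
                      lambda_ref: float | None = None) -> PairScoreSystem:
    """Full score-system pipeline for one pair of profiles.

    Raw symmetric cross log-odds -> thickness correction -> entropy
    down-scaling -> lambda solved on the discretized scores ->
    composition-based rescaling onto ``lambda_ref`` (the initial table's
    lambda when no database reference is supplied) -> final lambda, H and K.
    """
    lam_p = profile1.lambda_ref
    if lambda_ref is None:
        lambda_ref = lam_p
    L1, L2 = cross_logodds(profile1, profile2)
    mix = correct_scores(L1, L2, profile1.eff_seqs, profile2.eff_seqs)
    # normalizer from the uncorrected system (Eq. 2 convention)
    _, N = _normalize(0.5 * (L1 + L2), lam_p)
    s = mix - np.log(N) / lam_p
    s = entropy_downscale(s, profile1.rel_entropy, profile2.rel_entropy,
                          cfg.expected_evalue, cfg.kappa, cfg.downscale_factor)
    lam_star = solve_lambda_scaled(s, c_bits=cfg.c_bits)
    s = composition_scale(s, lam_star, lambda_ref)
    lam = solve_lambda_scaled(s, c_bits=cfg.c_bits)
    values, probs = lattice_distribution(s, c_bits=cfg.c_bits)
    H = entropy_H(values, probs, lam / (1 << cfg.c_bits))
    kv, kp = lattice_distribution(s, c_bits=cfg.c_bits_K)
    K = karlin_K(kv, kp, lam / (1 << cfg.c_bits_K))
    return PairScoreSystem(scores=s, lambda_=lam, H=H, K=K, N=N,
                           lambda_ref=lambda_ref, c_bits=cfg.c_bits)
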