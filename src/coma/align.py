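"""Local alignment of two profiles under position-dependent gap costs.

A modified Smith-Waterman recurrence: a diagonal move onto cell (i, j) adds
the pair score s_ij; a vertical move (consuming position i of profile 1
against a gap in profile 2) subtracts the two-sided cost G(i, j); a
horizontal move subtracts C(i, j).  Gap costs are charged per traversed
cell, at the current partner position.  Cells are floored at zero and the
single best local alignment is traced back from the global maximum with the
deterministic tie-breaking order diagonal > vertical > horizontal.

The full two-pass protocol aligns once with the H-derived widening term
z1 = zeta/sqrt(H), estimates an initial (ungapped-statistics) E-value,
re-derives z2 = -y/(log E + x), rebuilds the gap model and realigns; the
returned hit carries the gapped-EVD E- and P-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SearchConfig
from .gaps import build_gap_model, widen_z1, widen_z2
from .pairscore import PairScoreSystem, build_pair_system
from .profile import Profile

__all__ = ["AlignmentHit", "smith_waterman_positional", "align_two_pass",
           "render_alignment"]

try:  # numba accelerates the DP kernel roughly a hundredfold
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


DIAG, VERT, HORIZ, STOP = 1, 2, 3, 0


@njit(cache=False)
def _sw_fill(S, G, C):
    m, n = S.shape
    H = np.zeros((m + 1, n + 1))
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            vert = H[i - 1, j] - G[i - 1, j - 1]
            horiz = H[i, j - 1] - C[i - 1, j - 1]
            if diag >= vert and diag >= horiz:
                val = diag
                move = DIAG
            elif vert >= horiz:
                val = vert
                move = VERT
            else:
                val = horiz
                move = HORIZ
            if val <= 0.0:
                val = 0.0
                move = STOP
            H[i, j] = val
            ptr[i, j] = move
            if val > best:
                best = val
                bi = i
                bj = j
    return H, ptr, best, bi, bj


@dataclass
class AlignmentHit:
    """One local profile-profile alignment with its statistics.

    ``pairs`` lists (i, j) for aligned positions and (i, None)/(None, j) for
    gapped steps; coordinates are 0-based, ends half-open.
    """

    pairs: list = field(default_factory=list)
    score: float = 0.0
    start1: int = 0
    end1: int = 0
    start2: int = 0
    end2: int = 0
    evalue: float = float("nan")
    pvalue: float = float("nan")
    query: str = ""
    target: str = ""

    @property
    def aligned_length(self) -> int:
        return sum(1 for i, j in self.pairs if i is not None and j is not None)


def smith_waterman_positional(scores: np.ndarray, G: np.ndarray,
                              C: np.ndarray) -> AlignmentHit:
    """Optimal local alignment under per-cell scores and gap costs."""
    scores = np.ascontiguousarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("empty score matrix")
    G = np.ascontiguousarray(np.broadcast_to(G, scores.shape), np.float64)
    C = np.ascontiguousarray(np.broadcast_to(C, scores.shape), np.float64)
    H, ptr, best, bi, bj = _sw_fill(scores, G, C)
    if best <= 0:
        return AlignmentHit(pairs=[], score=0.0)
    pairs = []
    i, j = bi, bj
    while ptr[i, j] != STOP:
        move = ptr[i, j]
        if move == DIAG:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif move == VERT:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    return AlignmentHit(pairs=pairs, score=float(best),
                        start1=i, end1=bi, start2=j, end2=bj)


def align_two_pass(profile1: Profile, profile2: Profile,
                   cfg: SearchConfig = SearchConfig(),
                   evd=None, lambda_ref: float | None = None,
                   global_params=None, search_space: float | None = None,
                   n_targets: int = 1):
    """Two-pass alignment of a profile pair with significance estimates.

    Returns ``(hit, system)``.  ``evd`` is an
    :class:`~coma.stats.EVDReference` (the packaged synthetic calibration by
    default); ``global_params`` optionally carries a database's
    (lambda_u, K_u) reference pair, ``search_space`` the m*n product to use
    in the E-value (defaults to the product of profile lengths) and
    ``n_targets`` the number of database sequences for edge correction.
    """
    from . import stats as _stats

    if evd is None:
        evd = _stats.shipped_reference()
    if global_params is not None:
        lambda_ref = global_params[0]
    system = build_pair_system(profile1, profile2, cfg, lambda_ref=lambda_ref)
    m, n = system.shape
    mn = search_space if search_space is not None else float(m) * float(n)

    z1 = widen_z1(system.H, cfg.zeta, cfg.z_max)
    gm1 = build_gap_model(system.scores, profile1, profile2, cfg, z=z1)
    hit1 = smith_waterman_positional(system.scores, gm1.G, gm1.C)

    # initial per-hit E-value from the analytical ungapped statistics
    e1 = system.K * mn * np.exp(-system.lambda_ * hit1.score)
    z2 = widen_z2(e1, cfg.x, cfg.y, cfg.z_max)
    gm2 = build_gap_model(system.scores, profile1, profile2, cfg, z=z2)
    hit = smith_waterman_positional(system.scores, gm2.G, gm2.C)

    if global_params is not None:
        lam_u, K_u = global_params
    else:
        lam_u, K_u = system.lambda_ref, system.K
    lam_g, K_g = _stats.pair_gapped_params(system.lambda_, system.K,
                                           lam_u, K_u, evd)
    params = _stats.SignificanceParams(
        lambda_g=lam_g, K_g=K_g, m=m, n=mn / m if m else 1.0,
        H=system.H, n_targets=n_targets)
    hit.evalue, hit.pvalue = _stats.evalue(
        hit.score, params, edge_correction=cfg.edge_correction)
    hit.query, hit.target = profile1.name, profile2.name
    return hit, system


def render_alignment(hit: AlignmentHit, profile1: Profile, profile2: Profile,
                     width: int = 60) -> str:
    """Side-by-side rendering with a match line, 1-based coordinates.

    Profile positions are shown by their most probable residue (lower case
    when the position is variable); '+' marks positively scoring pairs.
    """
    from .alphabet import AMINO_ACIDS

    def consensus(profile, idx):
        row = profile.target[idx]
        a = AMINO_ACIDS[int(row.argmax())]
        return a if row.max() >= 0.5 else a.lower()

    top, mid, bot = [], [], []
    for i, j in hit.pairs:
        if i is not None and j is not None:
            c1, c2 = consensus(profile1, i), consensus(profile2, j)
            pair_score = float(profile1.scores[i] @ profile2.obs_freq[j]
                               + profile2.scores[j] @ profile1.obs_freq[i])
            mark = c1.upper() if c1.upper() == c2.upper() else (
                "+" if pair_score > 0 else " ")
        elif i is not None:
            c1, c2, mark = consensus(profile1, i), "-", " "
        else:
            c1, c2, mark = "-", consensus(profile2, j), " "
        top.append(c1)
        mid.append(mark)
        bot.append(c2)

    lines = [
        f"{hit.query} vs {hit.target}  score={hit.score:.1f} "
        f"E={hit.evalue:.3g} P={hit.pvalue:.3g} "
        f"aligned={hit.aligned_length}",
    ]
    p1, p2 = hit.start1 + 1, hit.start2 + 1  # 1-based inclusive display
    for k in range(0, len(top), width):
        t, b = top[k:k + width], bot[k:k + width]
        n1 = sum(1 for c in t if c != "-")
        n2 = sum(1 for c in b if c != "-")
        lines.append(f"Q {p1:5d} {''.join(t)} {p1 + n1 - 1}")
        lines.append(f"        {''.join(mid[k:k + width])}")
        lines.append(f"T {p2:5d} {''.join(b)} {p2 + n2 - 1}")
        lines.append("")
        p1 += n1
        p2 += n2
    return "\n".join(lines)
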