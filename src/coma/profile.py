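"""Profile construction from multiple sequence alignments.

A profile stores, for every unmasked alignment column with at least one
residue: weighted observed residue frequencies (with the gap frequency kept
separately), pseudocount-smoothed target probabilities, the effective number
of sequences of the position's reduced alignment, generalized deletion and
raw insertion probabilities, the relative entropy of the position and the
per-residue log-odds scores.  Scores are expressed in the units of the
initial substitution table and are compositionally adjusted so that the
profile's solved ungapped scale parameter equals that of the table.

Position-specific quantities are computed from *reduced* alignments: at
column i only sequences whose residue at i is strictly interior to their
aligned span participate.  This guards against sequence ends dominating the
weighting.  If a column's reduced alignment is empty, the fallback is all
sequences with a residue at the column; failing that, the query alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import (GAP_CODE, N_AA, InitialScoreTable, ambiguity_split,
                       robinson_background)
from .karlin import solve_lambda
from .msa import MultipleAlignment
from .seg import ComplexityParams, mask_complexity

__all__ = [
    "Profile", "BuildParams", "build_profile",
    "reduced_alignment", "henikoff_weights", "observed_frequencies",
    "target_probabilities", "deletion_probabilities",
    "insertion_probabilities", "thickness_adjust", "relative_entropy",
    "composition_adjust_profile",
]


@dataclass(frozen=True)
class BuildParams:
    pseudocount_weight: float = 10.0  # Tatusov pseudocount mass (beta)
    seg: bool = True
    seg_params: ComplexityParams = field(default_factory=ComplexityParams)


@dataclass
class Profile:
    """Per-position profile of a protein family.

    Arrays are indexed by profile position (masked / all-gap alignment
    columns are dropped, so ``length`` may be smaller than the alignment).
    """

    name: str
    obs_freq: np.ndarray      # (m, 20) residue frequencies, gap excluded
    gap_freq: np.ndarray      # (m,) weighted observed gap frequency
    target: np.ndarray        # (m, 20) target probabilities, rows sum to 1
    scores: np.ndarray        # (m, 20) positional log-odds, table units
    eff_seqs: np.ndarray      # (m,) effective sequences of reduced alignment
    del_prob: np.ndarray      # (m,) generalized deletion probability
    ins_prob: np.ndarray      # (m,) insertion probability
    rel_entropy: np.ndarray   # (m,) nats
    columns: np.ndarray       # (m,) source alignment column of each position
    table_name: str = "BLOSUM62"
    lambda_ref: float = float("nan")  # table lambda the scores are tuned to
    source: str = ""
    build_params: str = ""

    @property
    def length(self) -> int:
        return self.obs_freq.shape[0]

    def __post_init__(self):
        m = self.length
        for arr, cols in [(self.target, N_AA), (self.scores, N_AA)]:
            assert arr.shape == (m, cols)
        if m and not np.allclose(self.target.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("target probabilities must sum to 1 per position")


def reduced_alignment(msa: MultipleAlignment, column: int,
                      codes: np.ndarray | None = None,
                      spans: np.ndarray | None = None) -> np.ndarray:
    """Sequence indices with a strictly interior residue at ``column``.

    A residue is interior when it is neither the first nor the last aligned
    residue of its sequence.  The result may be empty; callers fall back to
    all residue-bearing sequences, then to the query alone.
    """
    if codes is None:
        codes = msa.codes()
    if spans is None:
        spans = msa.spans()
    has_res = codes[:, column] != GAP_CODE
    interior = (spans[:, 0] < column) & (column < spans[:, 1])
    return np.flatnonzero(has_res & interior)


def henikoff_weights(codes: np.ndarray,
                     columns: np.ndarray | None = None) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff).

    Each column distributes weight 1/(r * n_c) to every sequence, where r is
    the number of distinct symbol types in the column and n_c the count of
    the sequence's symbol; gaps count as a 21st symbol type.  Weights are
    normalized to sum to 1.
    """
    n, m = codes.shape
    if n == 1:
        return np.ones(1)
    if columns is not None:
        codes = codes[:, columns]
        m = codes.shape[1]
        if m == 0:
            return np.full(n, 1.0 / n)
    cols = np.arange(m)
    counts = np.zeros((24, m))
    np.add.at(counts, (codes, np.broadcast_to(cols, codes.shape)), 1.0)
    r = (counts > 0).sum(axis=0)
    contrib = 1.0 / (r[None, :] * counts[codes, cols])
    w = contrib.sum(axis=1)
    total = w.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return w / total


def observed_frequencies(codes_col: np.ndarray, weights: np.ndarray):
    """Weighted residue and gap frequencies of one column.

    ``codes_col`` and ``weights`` refer to the rows participating at the
    column; weights must sum to 1.  Ambiguity codes are redistributed.
    Returns ``(f, f_gap)`` with ``f.sum() + f_gap == 1``.
    """
    bg = robinson_background()
    f = np.zeros(N_AA)
    f_gap = 0.0
    for code, w in zip(codes_col, weights):
        if code == GAP_CODE:
            f_gap += w
        else:
            f += w * ambiguity_split(int(code), bg)
    return f, f_gap


def target_probabilities(f: np.ndarray, eff_seqs: float,
                         table: InitialScoreTable,
                         beta: float = 10.0) -> np.ndarray:
    """Tatusov pseudocount mixture t_a = (alpha f_a + beta g_a)/(alpha+beta).

    ``f`` is the residue-renormalized observed frequency vector (no gap
    mass), alpha = eff_seqs - 1 and g_a = sum_b f_b q_ab / p_b draws
    pseudocounts from the table's implied substitution behaviour.
    """
    if eff_seqs < 1:
        raise ValueError("effective number of sequences must be >= 1")
    g = (table.q / table.background[None, :]) @ f  # g_a = sum_b f_b q_ab/p_b
    alpha = eff_seqs - 1.0
    t = (alpha * f + beta * g) / (alpha + beta)
    return t / t.sum()


def _gap_runs(raw: np.ndarray):
    """Maximal runs of consecutive positions with raw probability > 0."""
    runs = []
    start = None
    for i, v in enumerate(raw):
        if v > 0 and start is None:
            start = i
        elif v <= 0 and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, raw.size - 1))
    return runs


def generalize_deletions(raw: np.ndarray) -> np.ndarray:
    """Linear generalization of raw deletion probabilities.

    Within every maximal run of positions with raw probability > 0, values
    are replaced by the straight line through the run's boundary values;
    single-position runs are unchanged.  Clipped to [0, 1].
    """
    out = raw.astype(float).copy()
    for lo, hi in _gap_runs(raw):
        if hi > lo:
            out[lo:hi + 1] = np.linspace(raw[lo], raw[hi], hi - lo + 1)
    return np.clip(out, 0.0, 1.0)


def deletion_probabilities(raw_gap: np.ndarray) -> np.ndarray:
    """Generalized per-position deletion probabilities from raw gap weight."""
    return generalize_deletions(raw_gap)


def insertion_probabilities(raw_gap: np.ndarray) -> np.ndarray:
    """Insertion probabilities: the raw weighted gap frequency, no smoothing.

    An insertion corresponds to residues of other sequences aligned against
    the gap, so the raw per-position value is used directly.
    """
    return np.clip(raw_gap.astype(float), 0.0, 1.0)


def thickness_adjust(prob, eff_seqs, u: float = 1.0, v: float = 2.0):
    """Damp indel probabilities of thin alignments.

    Multiplies ``prob`` by the logistic factor 1/(1 + exp(-t*u + v)) where t
    is the effective number of sequences; the factor approaches 1 for thick
    alignments and suppresses the 50%-gap-from-two-sequences pathology.
    """
    t = np.asarray(eff_seqs, dtype=float)
    return np.asarray(prob, dtype=float) / (1.0 + np.exp(-t * u + v))


def relative_entropy(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Kullback-Leibler divergence sum_a t_a log(t_a / p_a), in nats."""
    t = np.atleast_2d(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / p[None, :]), 0.0)
    r = terms.sum(axis=1)
    return r if r.size > 1 else float(r[0])


def composition_adjust_profile(profile: Profile, table: InitialScoreTable,
                               tol: float = 1e-4,
                               max_iter: int = 8) -> Profile:
    """Rescale positional scores so the profile's solved lambda matches the
    table's.

    The profile-versus-background score system assigns probability p_a / m to
    the score of residue a at each of the m positions.  Because solving is
    done on the continuous distribution, lambda(r*s) = lambda(s)/r and a
    single analytic rescale converges (iterated defensively up to ``tol``).
    """
    m = profile.length
    probs = np.repeat(table.background[None, :], m, axis=0).ravel() / m
    s = profile.scores.copy()
    if not (s > 0).any():
        raise ValueError("no positive score: profile is uninformative "
                         "(targets equal background everywhere)")
    for _ in range(max_iter):
        lam = solve_lambda(s.ravel(), probs)
        if abs(lam - table.lambda_) <= tol * table.lambda_:
            break
        s *= lam / table.lambda_
    profile.scores = s
    profile.lambda_ref = table.lambda_
    return profile


def _effective_count(counts: np.ndarray) -> float:
    """Mean number of distinct residue types per column (>= 1)."""
    residue_types = (counts[:GAP_CODE] > 0).sum(axis=0) + \
        (counts[GAP_CODE + 1:] > 0).sum(axis=0)
    occupied = residue_types > 0
    if not occupied.any():
        return 1.0
    return float(max(1.0, residue_types[occupied].mean()))


def build_profile(msa: MultipleAlignment, table: InitialScoreTable,
                  params: BuildParams = BuildParams(),
                  name: str = "", source: str = "") -> Profile:
    """Build a composition-adjusted profile from a multiple alignment."""
    if params.seg:
        msa = mask_complexity(msa, params.seg_params)
    codes = msa.codes()
    spans = msa.spans()
    n, m_cols = codes.shape
    unmasked = np.flatnonzero(msa.column_mask)

    weight_cache: dict[bytes, np.ndarray] = {}
    count_cache: dict[bytes, float] = {}

    def weights_for(rows: np.ndarray) -> np.ndarray:
        key = rows.tobytes()
        w = weight_cache.get(key)
        if w is None:
            w = henikoff_weights(codes[rows], unmasked)
            weight_cache[key] = w
        return w

    def eff_for(rows: np.ndarray) -> float:
        key = rows.tobytes()
        t = count_cache.get(key)
        if t is None:
            sub = codes[np.ix_(rows, unmasked)]
            counts = np.zeros((24, sub.shape[1]))
            np.add.at(counts, (sub, np.broadcast_to(
                np.arange(sub.shape[1]), sub.shape)), 1.0)
            t = _effective_count(counts)
            count_cache[key] = t
        return t

    positions, f_rows, gap_rows, eff_rows = [], [], [], []
    for col in unmasked:
        col_codes = codes[:, col]
        has_res = col_codes != GAP_CODE
        if not has_res.any():
            continue  # all-gap column: flagged out of the profile
        reduced = reduced_alignment(msa, col, codes, spans)
        if reduced.size == 0:
            reduced = np.flatnonzero(has_res)
        if reduced.size == 0:
            reduced = np.array([msa.query_index])
        # extended set: add rows whose gap at this column is interior
        interior_gap = (~has_res) & (spans[:, 0] < col) & (col < spans[:, 1])
        extended = np.union1d(reduced, np.flatnonzero(interior_gap))
        w = weights_for(extended)
        f, f_gap = observed_frequencies(codes[extended, col], w)
        positions.append(col)
        f_rows.append(f)
        gap_rows.append(f_gap)
        eff_rows.append(eff_for(reduced))

    if not positions:
        raise ValueError("no usable alignment columns (all masked or gapped)")

    m = len(positions)
    f_arr = np.array(f_rows)
    gap_arr = np.array(gap_rows)
    eff_arr = np.array(eff_rows)

    # residue-renormalized frequencies for target estimation
    res_tot = f_arr.sum(axis=1, keepdims=True)
    f_hat = np.where(res_tot > 0, f_arr / res_tot, 0.0)

    t_arr = np.empty((m, N_AA))
    for i in range(m):
        t_arr[i] = target_probabilities(f_hat[i], eff_arr[i], table,
                                        beta=params.pseudocount_weight)

    raw_d = 1.0 - f_arr.sum(axis=1)  # == gap fraction of the extended set
    raw_d[raw_d < 1e-9] = 0.0  # float residue must not seed deletion runs
    del_arr = deletion_probabilities(raw_d)
    ins_arr = insertion_probabilities(gap_arr)

    p = table.background
    r_arr = np.atleast_1d(relative_entropy(t_arr, p))
    scores = np.log(t_arr / p[None, :]) / table.lambda_

    profile = Profile(
        name=name or "profile",
        obs_freq=f_hat, gap_freq=gap_arr, target=t_arr, scores=scores,
        eff_seqs=eff_arr, del_prob=del_arr, ins_prob=ins_arr,
        rel_entropy=r_arr, columns=np.array(positions),
        table_name=table.name, lambda_ref=table.lambda_,
        source=source,
        build_params=f"beta={params.pseudocount_weight} seg={params.seg}",
    )
    try:
        composition_adjust_profile(profile, table)
    except ValueError:
        pass  # uninformative profile: keep unadjusted scores
    return profile
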