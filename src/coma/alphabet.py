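"""Amino-acid alphabet, background frequencies and the initial score table.

Profiles are built over the 20 standard amino acids.  Ambiguity codes are
resolved at counting time: 'B' is split between D and N, 'Z' between E and Q
(proportionally to their background frequencies) and 'X' is spread over the
whole background.  The initial score table supplies the residue substitution
scores, the implied joint target frequencies q_ab used by the pseudocount
method, and the ungapped Karlin-Altschul parameters (lambda, K, H) that anchor
composition-based statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

GAP = "-"
AMBIGUOUS = "BZX"
MSA_ALPHABET = set(AMINO_ACIDS) | set(AMBIGUOUS) | {GAP}

# integer codes used internally for alignment matrices
N_AA = 20
GAP_CODE = 20
B_CODE, Z_CODE, X_CODE = 21, 22, 23
N_CODES = 24
CHAR_TO_CODE = {**AA_INDEX, GAP: GAP_CODE, "B": B_CODE, "Z": Z_CODE, "X": X_CODE}
CODE_TO_CHAR = {v: k for k, v in CHAR_TO_CODE.items()}

# Robinson & Robinson amino-acid background frequencies (the backgrounds
# conventionally paired with BLOSUM62 in ungapped statistics).
_ROBINSON = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


def robinson_background() -> np.ndarray:
    """Background residue probabilities in AMINO_ACIDS order, normalized."""
    p = np.array([_ROBINSON[a] for a in AMINO_ACIDS], dtype=float)
    return p / p.sum()


def ambiguity_split(code: int, background: np.ndarray) -> np.ndarray:
    """Distribution over the 20 residues represented by one residue code.

    Standard residues map to a point mass; B/Z are split between their
    constituent residues at background-proportional weights; X follows the
    background.  Gap codes are not accepted here.
    """
    if code < N_AA:
        out = np.zeros(N_AA)
        out[code] = 1.0
        return out
    if code == B_CODE:
        idx = [AA_INDEX["D"], AA_INDEX["N"]]
    elif code == Z_CODE:
        idx = [AA_INDEX["E"], AA_INDEX["Q"]]
    elif code == X_CODE:
        return background.copy()
    else:
        raise ValueError(f"not a residue code: {code}")
    out = np.zeros(N_AA)
    w = background[idx]
    out[idx] = w / w.sum()
    return out


@dataclass
class InitialScoreTable:
    """Residue substitution score table with its solved ungapped statistics.

    Attributes
    ----------
    name : str
        Table identifier (e.g. ``"BLOSUM62"``).
    scores : (20, 20) ndarray
        Substitution scores in the table's native (integer) units.
    background : (20,) ndarray
        Background residue probabilities p_a.
    lambda_ : float
        Ungapped statistical parameter of the table in nats per score unit.
    q : (20, 20) ndarray
        Implied joint target frequencies q_ab = p_a p_b exp(lambda * s_ab).
    K : float
        Karlin-Altschul K of the table with its backgrounds.
    H : float
        Relative entropy of the table (nats per aligned pair).
    """

    name: str
    scores: np.ndarray
    background: np.ndarray
    lambda_: float
    q: np.ndarray = field(repr=False, default=None)
    K: float = float("nan")
    H: float = float("nan")

    def __post_init__(self):
        p = self.background
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("background probabilities must sum to 1")
        expected = float(np.einsum("a,b,ab->", p, p, self.scores))
        if expected >= 0:
            raise ValueError("expected score of the table must be negative")
        if not (self.scores > 0).any():
            raise ValueError("table must contain a positive score")
        if self.q is None:
            self.q = np.einsum("a,b,ab->ab", p, p,
                               np.exp(self.lambda_ * self.scores))

    @property
    def joint_sum(self) -> float:
        return float(self.q.sum())


def derive_initial_table(msas, name: str = "custom",
                         scale_bits: float = 0.5,
                         pseudocount: float = 1.0) -> InitialScoreTable:
    """Derive a substitution score table from a collection of alignments.

    BLOSUM-style counting: every column contributes its weighted residue
    pairs (sequence weights from the Henikoff position-based scheme, gaps
    skipped, ambiguity codes redistributed) to the joint frequencies q_ab;
    backgrounds are the marginals, and scores are
    s_ab = ln(q_ab/(p_a p_b)) / (scale_bits * ln 2) rounded to integers
    (half-bit units by default).  ``pseudocount`` Laplace mass keeps rare
    pairs finite.  The solved lambda, K and H of the derived table are
    attached, so the result can serve anywhere the shipped BLOSUM62 table
    does.
    """
    from .karlin import entropy_H, karlin_K, solve_lambda
    from .profile import henikoff_weights

    bg = robinson_background()
    counts = np.full((N_AA, N_AA), float(pseudocount))
    for msa in msas:
        codes = msa.codes()
        weights = henikoff_weights(codes)
        for col in range(msa.length):
            col_codes = codes[:, col]
            keep = col_codes != GAP_CODE
            if keep.sum() < 2:
                continue
            dist = np.zeros(N_AA)
            for code, w in zip(col_codes[keep], weights[keep]):
                dist += w * ambiguity_split(int(code), bg)
            total = dist.sum()
            if total <= 0:
                continue
            dist /= total
            # weighted unordered pair frequencies of the column
            counts += np.outer(dist, dist)
    counts = 0.5 * (counts + counts.T)
    q = counts / counts.sum()
    p = q.sum(axis=1)
    unit = scale_bits * np.log(2.0)
    s = np.rint(np.log(q / np.outer(p, p)) / unit)
    lam = solve_lambda(s.ravel(), np.outer(p, p).ravel())
    H = entropy_H(s.ravel(), np.outer(p, p).ravel(), lam)
    K = karlin_K(s.astype(int).ravel(), np.outer(p, p).ravel(), lam)
    return InitialScoreTable(name=name, scores=s, background=p,
                             lambda_=lam, K=K, H=H)


def load_initial_table(name: str = "BLOSUM62") -> InitialScoreTable:
    """Load a BLOSUM-style table and solve its ungapped statistics."""
    from Bio.Align import substitution_matrices

    from .karlin import entropy_H, karlin_K, solve_lambda

    mat = substitution_matrices.load(name)
    alpha = mat.alphabet
    s = np.empty((N_AA, N_AA))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            s[i, j] = mat[alpha.index(a), alpha.index(b)]
    p = robinson_background()
    probs = np.outer(p, p).ravel()
    lam = solve_lambda(s.ravel(), probs)
    H = entropy_H(s.ravel(), probs, lam)
    K = karlin_K(np.rint(s.ravel()).astype(int), probs, lam)
    return InitialScoreTable(name=name, scores=s, background=p,
                             lambda_=lam, K=K, H=H)
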