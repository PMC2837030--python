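"""Synthetic multiple-alignment generator with controlled statistics.

Families are emulated as independent columns: each position carries a
residue distribution drawn from a Dirichlet centred on the Robinson-Robinson
background, with a per-position concentration controlling conservation
(small concentration => spiky, conserved column; large => near-background,
variable column).  Sequences are sampled i.i.d. per column, the query row is
kept gapless, and deletion runs are inserted as contiguous gap blocks that
individual sequences adopt with a given probability — enough structure to
exercise sequence weighting, indel-probability estimation, gap-cost
interpolation and the end-to-end significance statistics.  Phylogenetic
correlation between sequences is deliberately not simulated.

Related pairs share their parent column distributions over a contiguous
block covering a chosen fraction of positions (`relatedness`), with the
remainder drawn independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import AMINO_ACIDS, robinson_background
from .msa import MultipleAlignment

__all__ = ["FixtureSpec", "sample_family_msa", "sample_related_pair",
           "default_conservation", "sample_unrelated_profiles"]

CONSERVED_CONCENTRATION = 0.5
VARIABLE_CONCENTRATION = 20.0


def default_conservation(n_positions: int, core: int = 8,
                         loop: int = 4) -> np.ndarray:
    """Alternating conserved-core / variable-loop concentration profile."""
    conc = np.empty(n_positions)
    period = core + loop
    for i in range(n_positions):
        conc[i] = (CONSERVED_CONCENTRATION if (i % period) < core
                   else VARIABLE_CONCENTRATION)
    return conc


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic family alignment."""

    n_positions: int = 200
    n_sequences: int = 50
    concentration: np.ndarray | None = None   # per-position Dirichlet conc.
    gap_runs: tuple = ((60, 6, 0.3), (140, 8, 0.4))  # (start, length, prob)
    seed: int = 0

    def resolved_concentration(self) -> np.ndarray:
        if self.concentration is not None:
            conc = np.asarray(self.concentration, dtype=float)
            if conc.size != self.n_positions:
                raise ValueError("concentration profile length mismatch")
            return conc
        return default_conservation(self.n_positions)


def _sample_column_distributions(conc: np.ndarray,
                                 rng: np.random.Generator) -> np.ndarray:
    bg = robinson_background()
    dists = np.empty((conc.size, bg.size))
    for i, c in enumerate(conc):
        # concentration = total Dirichlet mass: 0.5 gives spiky conserved
        # columns, 20 gives near-background variable columns
        dists[i] = rng.dirichlet(np.maximum(c * bg, 1e-8))
    return dists


def _msa_from_distributions(dists: np.ndarray, spec: FixtureSpec,
                            rng: np.random.Generator,
                            name: str) -> MultipleAlignment:
    m, n = dists.shape[0], spec.n_sequences
    aa = np.array(list(AMINO_ACIDS))
    rows_idx = np.empty((n, m), dtype=np.int64)
    for i in range(m):
        rows_idx[:, i] = rng.choice(dists.shape[1], size=n, p=dists[i])
    chars = aa[rows_idx]
    for start, length, gap_p in spec.gap_runs:
        stop = min(start + length, m)
        if stop <= start:
            continue
        # query row (0) stays gapless; others adopt the deletion run
        adopt = rng.random(n) < gap_p
        adopt[0] = False
        chars[adopt, start:stop] = "-"
    rows = ["".join(r) for r in chars]
    ids = [f"{name}_q" if k == 0 else f"{name}_s{k}" for k in range(n)]
    return MultipleAlignment(sequence_ids=ids, rows=rows)


def sample_family_msa(spec: FixtureSpec,
                      rng: np.random.Generator | None = None,
                      name: str = "fam") -> MultipleAlignment:
    """Sample one family alignment; bit-reproducible for a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    conc = spec.resolved_concentration()
    dists = _sample_column_distributions(conc, rng)
    return _msa_from_distributions(dists, spec, rng, name)


def sample_related_pair(spec: FixtureSpec, relatedness: float,
                        rng: np.random.Generator | None = None,
                        name: str = "pair"):
    """Two alignments sharing parent distributions on a leading block.

    ``relatedness`` is the fraction of positions drawn from the shared
    parent: 0 gives independent families, 1 the same family (two
    independent sequence samples of it).
    """
    if not 0.0 <= relatedness <= 1.0:
        raise ValueError("relatedness must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    conc = spec.resolved_concentration()
    shared = _sample_column_distributions(conc, rng)
    n_shared = int(round(relatedness * spec.n_positions))
    d_a = shared.copy()
    d_b = shared.copy()
    if n_shared < spec.n_positions:
        d_a[n_shared:] = _sample_column_distributions(conc[n_shared:], rng)
        d_b[n_shared:] = _sample_column_distributions(conc[n_shared:], rng)
    msa_a = _msa_from_distributions(d_a, spec, rng, f"{name}_A")
    msa_b = _msa_from_distributions(d_b, spec, rng, f"{name}_B")
    return msa_a, msa_b


def unrelated_pair_pvalues(n_profiles: int = 66,
                           spec: FixtureSpec | None = None,
                           cfg=None, seed: int = 777) -> np.ndarray:
    """P-values of all unordered pairs of independently generated profiles.

    The workhorse of the significance-calibration experiment: under the
    null (mutually unrelated families) the reported P-values should be
    roughly uniform, so the empirical fraction with P <= p tracks p.
    """
    from itertools import combinations

    from .align import align_two_pass
    from .config import SearchConfig
    from .stats import build_global_score_system, shipped_reference

    if spec is None:
        spec = FixtureSpec(seed=seed)
    if cfg is None:
        cfg = SearchConfig(seed=seed)
    rng = np.random.default_rng(seed)
    profiles = sample_unrelated_profiles(n_profiles, spec, rng=rng)
    gs = build_global_score_system(profiles, cfg, seed=seed)
    evd = shipped_reference()
    pvals = []
    for p1, p2 in combinations(profiles, 2):
        hit, _ = align_two_pass(p1, p2, cfg, evd=evd,
                                global_params=(gs.lambda_u, gs.K_u))
        pvals.append(hit.pvalue)
    return np.asarray(pvals)


def relatedness_separation(n_per_class: int = 100,
                           spec: FixtureSpec | None = None,
                           cfg=None, seed: int = 2024,
                           min_relatedness: float = 0.75):
    """E-value separation of related vs unrelated profile pairs.

    Generates ``n_per_class`` related pairs (shared-parent fraction drawn
    uniformly from [min_relatedness, 1]) and as many unrelated pairs, runs
    the full comparison pipeline and returns
    ``(auc, related_log10_e, unrelated_log10_e)`` where the AUC is the
    probability that a random related pair outranks (smaller E) a random
    unrelated one.
    """
    from .align import align_two_pass
    from .alphabet import load_initial_table
    from .config import SearchConfig
    from .profile import build_profile

    if spec is None:
        spec = FixtureSpec(seed=seed)
    if cfg is None:
        cfg = SearchConfig(seed=seed)
    table = load_initial_table()
    rng = np.random.default_rng(seed)

    def log_evalue(relatedness: float) -> float:
        msa_a, msa_b = sample_related_pair(spec, relatedness, rng)
        pa = build_profile(msa_a, table, name="a")
        pb = build_profile(msa_b, table, name="b")
        hit, _ = align_two_pass(pa, pb, cfg)
        return float(np.log10(max(hit.evalue, 1e-300)))

    related = np.array([log_evalue(float(rng.uniform(min_relatedness, 1.0)))
                        for _ in range(n_per_class)])
    unrelated = np.array([log_evalue(0.0) for _ in range(n_per_class)])
    # rank-based AUC (probability of correct ordering, ties count half)
    wins = (related[:, None] < unrelated[None, :]).sum()
    ties = (related[:, None] == unrelated[None, :]).sum()
    auc = (wins + 0.5 * ties) / (related.size * unrelated.size)
    return float(auc), related, unrelated


def sample_unrelated_profiles(n_profiles: int, spec: FixtureSpec,
                              table=None, build_params=None,
                              rng: np.random.Generator | None = None,
                              name: str = "db") -> list:
    """Build ``n_profiles`` mutually unrelated fixture profiles."""
    from .profile import BuildParams, build_profile
    from .alphabet import load_initial_table

    if table is None:
        table = load_initial_table()
    if build_params is None:
        build_params = BuildParams()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    profiles = []
    for k in range(n_profiles):
        msa = sample_family_msa(spec, rng, name=f"{name}{k:03d}")
        profiles.append(build_profile(msa, table, build_params,
                                      name=f"{name}{k:03d}"))
    return profiles
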