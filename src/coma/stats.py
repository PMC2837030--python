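"""Statistical significance of profile-profile alignment scores.

Ungapped statistics (lambda, K, H) are solved analytically per pair of
profiles from the discretized score distribution.  A database-wide *global
score system* — the score distribution over all unique profile position
vectors — supplies the reference parameters lambda_u and K_u used by
composition-based statistics, so that identical scores carry identical
significance across pairs.

Gapped alignment scores follow an extreme value (Gumbel) distribution whose
parameters cannot be derived analytically under the position-dependent gap
scheme; the reference scale and location (lambda_g, mu => K_g) are fitted on
scores of unrelated profile pairs with a progressive score-threshold
protocol: the lower bound is raised until the truncated-Gumbel estimates
stabilize, and the stabilized values describe the tail that matters for
significance.  Per-pair gapped parameters follow by the composition ratios

    lambda_g* = lambda_g * (lambda_u* / lambda_u),
    K_g*      = K_g * (K_u* / K_u),

and the E-value of a score s searched over space m*n is

    E = K_g* m' n' exp(-lambda_g* s),        P = 1 - exp(-E),

optionally with edge-corrected effective lengths m', n'.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gumbel_r

from .config import SearchConfig
from .karlin import (InadmissibleScoreSystem, entropy_H, karlin_K,
                     lattice_distribution, solve_lambda)
from .pairscore import composition_scale, correct_scores
from .profile import Profile

__all__ = [
    "EVDReference", "GlobalScoreSystem", "VectorIndex",
    "build_global_score_system", "composition_scale_pair",
    "fit_evd_reference", "pair_gapped_params", "SignificanceParams",
    "evalue", "shipped_reference", "calibrate_reference",
]


# ---------------------------------------------------------------------------
# EVD reference for gapped alignments

@dataclass
class EVDReference:
    """Gumbel reference parameters of gapped unrelated-pair scores."""

    lambda_g: float
    mu: float
    K_g: float
    search_space: float          # m*n the calibration scores were drawn at
    fit_threshold: float = float("nan")
    stderr_lambda: float = float("nan")
    stderr_mu: float = float("nan")
    n_scores: int = 0
    provenance: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EVDReference":
        return cls(**json.loads(text))


def _censored_gumbel_nll(params, x_tail, n_below, bound):
    mu, log_beta = params
    beta = np.exp(log_beta)
    z = (x_tail - mu) / beta
    ll = float((-np.log(beta) - z - np.exp(-z)).sum())
    if n_below:
        F = np.exp(-np.exp(-(bound - mu) / beta))
        if F <= 0:
            return 1e300
        ll += n_below * np.log(F)
    return -ll


def _fit_censored_gumbel(x_all: np.ndarray, bound: float):
    """Censored Gumbel MLE: exceedances enter with their densities, scores
    below the bound only through their count (type-I censoring).

    Unlike a conditional (truncated) fit, this anchors the unconditional
    exceedance probabilities, which is what E-values are built from.
    """
    x_tail = x_all[x_all >= bound]
    n_below = x_all.size - x_tail.size
    loc0, scale0 = gumbel_r.fit(x_all)
    res = minimize(_censored_gumbel_nll, x0=[loc0, np.log(scale0)],
                   args=(x_tail, n_below, bound), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    mu, beta = res.x[0], float(np.exp(res.x[1]))
    # standard errors from a finite-difference Hessian in (mu, beta)
    def nll_mb(mu_, beta_):
        return _censored_gumbel_nll([mu_, np.log(beta_)], x_tail, n_below,
                                    bound)
    h_mu, h_b = 1e-4 * max(abs(mu), 1.0), 1e-4 * beta
    f0 = nll_mb(mu, beta)
    d2mu = (nll_mb(mu + h_mu, beta) - 2 * f0 + nll_mb(mu - h_mu, beta)) / h_mu**2
    d2b = (nll_mb(mu, beta + h_b) - 2 * f0 + nll_mb(mu, beta - h_b)) / h_b**2
    dmb = (nll_mb(mu + h_mu, beta + h_b) - nll_mb(mu + h_mu, beta - h_b)
           - nll_mb(mu - h_mu, beta + h_b) + nll_mb(mu - h_mu, beta - h_b)
           ) / (4 * h_mu * h_b)
    info = np.array([[d2mu, dmb], [dmb, d2b]])
    try:
        cov = np.linalg.inv(info)
        se_mu = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_beta = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_mu = se_beta = float("nan")
    return mu, beta, se_mu, se_beta


def fit_evd_reference(scores, search_space: float | None = None,
                      min_tail: int = 200, n_bounds: int = 30,
                      stabil_tol: float = 0.02, consecutive: int = 3,
                      provenance: str = "") -> EVDReference:
    """Progressive-threshold Gumbel fit of gapped alignment scores.

    The lower score bound is raised over a grid; at each bound the
    exceeding scores are fitted by censored-Gumbel maximum likelihood.
    Stabilization is the first bound at which both lambda (=1/beta) and mu
    changed by less than ``stabil_tol`` over ``consecutive`` consecutive
    bounds; the parameters at that bound are returned.  ``search_space`` is
    the m*n product of the calibration comparisons, needed to convert mu
    into K_g via mu = ln(K_g m n) / lambda_g.
    """
    x = np.asarray(scores, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < min_tail:
        raise ValueError(f"need at least {min_tail} scores, got {x.size}")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate fit: scores are constant")

    lo, hi = float(x.min()), float(np.quantile(x, 0.98))
    if hi <= lo:
        raise ValueError("degenerate fit: no usable score range")
    bounds = np.linspace(lo, hi, n_bounds)

    lams, mus, fits = [], [], []
    for bound in bounds:
        tail = x[x >= bound]
        if tail.size < min_tail:
            break
        mu, beta, se_mu, se_beta = _fit_censored_gumbel(x, bound)
        lams.append(1.0 / beta)
        mus.append(mu)
        fits.append((bound, mu, beta, se_mu, se_beta, tail.size))
    if len(lams) <= consecutive:
        raise ValueError("tail too short: fewer usable score bounds than "
                         f"required before the tail dropped below {min_tail}")
    # Stabilization: the first bound whose estimates (a) change by less than
    # stabil_tol over the following `consecutive` bounds and (b) agree with
    # the deepest-bound estimate; (b) guards against a false plateau inside
    # a contaminated low-score region.
    lam_end = lams[-1]
    for i in range(len(lams) - consecutive):
        window_l = lams[i:i + consecutive + 1]
        window_m = mus[i:i + consecutive + 1]
        rel_l = np.abs(np.diff(window_l)) / max(abs(window_l[-1]), 1e-12)
        rel_m = np.abs(np.diff(window_m)) / max(abs(window_m[-1]), 1e-12)
        if ((rel_l < stabil_tol).all() and (rel_m < stabil_tol).all()
                and abs(lams[i] - lam_end) <= 5 * stabil_tol * abs(lam_end)):
            bound, mu, beta, se_mu, se_beta, n_tail = fits[i]
            lam = 1.0 / beta
            mn = search_space if search_space else 1.0
            K_g = float(np.exp(lam * mu) / mn)
            return EVDReference(
                lambda_g=lam, mu=float(mu), K_g=K_g, search_space=mn,
                fit_threshold=float(bound),
                stderr_lambda=se_beta / beta ** 2, stderr_mu=se_mu,
                n_scores=int(n_tail), provenance=provenance)
    raise ValueError("tail too short: parameters did not stabilize before "
                     f"the tail dropped below {min_tail} scores")


# ---------------------------------------------------------------------------
# global score system

class VectorIndex:
    """Content-addressed index of unique profile position vectors.

    Two-level lookup: a coarse first-level key (most probable residue and
    bucketed effective count) selects a bucket; within a bucket the fully
    rounded vector keys are kept sorted for binary search.  Guarantees exact
    deduplication under the stated rounding with O(log) retrieval.
    """

    def __init__(self, decimals: int = 4):
        self.decimals = decimals
        self._buckets: dict = {}
        self.vectors: list = []

    def _keys(self, target, obs, eff):
        full = (tuple(np.round(target, self.decimals)),
                tuple(np.round(obs, self.decimals)),
                round(float(eff), self.decimals))
        coarse = (int(np.argmax(target)), int(eff * 2))
        return coarse, full

    def add(self, target, obs, eff, payload) -> int:
        """Insert a vector; returns its index (existing index if duplicate)."""
        coarse, full = self._keys(target, obs, eff)
        bucket = self._buckets.setdefault(coarse, [])
        pos = bisect.bisect_left(bucket, (full,))
        if pos < len(bucket) and bucket[pos][0] == full:
            return bucket[pos][1]
        idx = len(self.vectors)
        bucket.insert(pos, (full, idx))
        self.vectors.append(payload)
        return idx

    def find(self, target, obs, eff):
        coarse, full = self._keys(target, obs, eff)
        bucket = self._buckets.get(coarse, [])
        pos = bisect.bisect_left(bucket, (full,))
        if pos < len(bucket) and bucket[pos][0] == full:
            return bucket[pos][1]
        return None

    def __len__(self):
        return len(self.vectors)


@dataclass
class GlobalScoreSystem:
    """Reference ungapped statistics of a profile database's vector space."""

    lambda_u: float
    K_u: float
    H_u: float
    n_vectors: int
    n_pairs_scored: int
    index: VectorIndex = field(default=None, repr=False)


def build_global_score_system(profiles, cfg: SearchConfig = SearchConfig(),
                              max_pairs: int = 1_000_000,
                              seed: int = 0) -> GlobalScoreSystem:
    """Compile unique position vectors and solve the reference parameters.

    All vector pairs are scored with the pair-cell formula (thickness
    correction included); if the full product exceeds ``max_pairs`` a
    uniform random sample of that many pairs is scored instead.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty profile database")
    lam_p = profiles[0].lambda_ref
    index = VectorIndex(decimals=4)
    for prof in profiles:
        for i in range(prof.length):
            index.add(prof.target[i], prof.obs_freq[i], prof.eff_seqs[i],
                      (prof.scores[i], prof.obs_freq[i],
                       float(prof.eff_seqs[i])))
    nv = len(index)
    S = np.array([v[0] for v in index.vectors])
    F = np.array([v[1] for v in index.vectors])
    eff = np.array([v[2] for v in index.vectors])

    if nv * nv <= max_pairs:
        L1 = S @ F.T
        mix = correct_scores(L1, L1.T, eff, eff)
        n_scored = nv * nv
    else:
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, nv, size=max_pairs)
        jj = rng.integers(0, nv, size=max_pairs)
        L1 = np.einsum("ka,ka->k", S[ii], F[jj])
        L2 = np.einsum("ka,ka->k", S[jj], F[ii])
        w1 = np.maximum(0, 1 - 1 / eff[ii])
        w2 = np.maximum(0, 1 - 1 / eff[jj])
        tot = w1 + w2
        mix = np.where(tot > 0, (w1 * L1 + w2 * L2) / np.where(tot > 0, tot, 1),
                       0.5 * (L1 + L2))
        n_scored = max_pairs
    mix = mix - np.log(np.exp(lam_p * mix).mean()) / lam_p
    try:
        values, probs = lattice_distribution(mix, c_bits=cfg.c_bits)
        lam_lat = solve_lambda(values, probs)
        lam_u = lam_lat * (1 << cfg.c_bits)
        H_u = entropy_H(values, probs, lam_lat)
        kv, kp = lattice_distribution(mix, c_bits=cfg.c_bits_K)
        K_u = karlin_K(kv, kp, lam_u / (1 << cfg.c_bits_K))
    except InadmissibleScoreSystem:
        # degenerate vector space (e.g. a single repeated column): the
        # dedup result is still reported, the reference parameters are not
        # defined
        lam_u = K_u = H_u = float("nan")
    return GlobalScoreSystem(lambda_u=lam_u, K_u=K_u, H_u=H_u,
                             n_vectors=nv, n_pairs_scored=n_scored,
                             index=index)


def composition_scale_pair(system, global_system: GlobalScoreSystem,
                           cfg: SearchConfig = SearchConfig()):
    """Rescale a pair score system onto the global reference lambda_u.

    Idempotent: a system already at lambda_u is returned unchanged (up to
    the discretization tolerance).
    """
    from .karlin import solve_lambda_scaled

    system.scores = composition_scale(system.scores, system.lambda_,
                                      global_system.lambda_u)
    system.lambda_ref = global_system.lambda_u
    system.lambda_ = solve_lambda_scaled(system.scores, c_bits=system.c_bits)
    return system


# ---------------------------------------------------------------------------
# E-values

def pair_gapped_params(lambda_u_star: float, K_u_star: float,
                       lambda_u: float, K_u: float,
                       evd: EVDReference):
    """Per-pair gapped parameters by the composition ratios."""
    return (evd.lambda_g * (lambda_u_star / lambda_u),
            evd.K_g * (K_u_star / K_u))


@dataclass
class SignificanceParams:
    lambda_g: float
    K_g: float
    m: float                      # query profile length
    n: float                      # database length (positions)
    H: float = float("nan")       # pair relative entropy, for edge correction
    n_targets: int = 1

    def __post_init__(self):
        if self.m < 1 or self.n < 1:
            raise ValueError("search space lengths must be >= 1")


def evalue(score: float, params: SignificanceParams,
           edge_correction: bool = False):
    """E- and P-value of an alignment score.

    E = K_g* m' n' exp(-lambda_g* s); P = 1 - exp(-E).  With edge
    correction on, the expected alignment length l(s) = lambda_g* s / H is
    subtracted from the query length (and, scaled by the number of database
    sequences, from the database length), floored at 1.
    """
    m, n = params.m, params.n
    if edge_correction and np.isfinite(params.H) and params.H > 0:
        ell = params.lambda_g * score / params.H
        m = max(1.0, m - ell)
        n = max(1.0, n - ell * params.n_targets)
    E = params.K_g * m * n * np.exp(-params.lambda_g * score)
    P = float(-np.expm1(-E))
    return float(E), P


# ---------------------------------------------------------------------------
# packaged calibration

def shipped_reference() -> EVDReference:
    """The packaged EVD reference, calibrated on synthetic unrelated pairs."""
    text = resources.files("coma").joinpath(
        "data/evd_reference.json").read_text()
    return EVDReference.from_json(text)


def calibrate_reference(profiles, cfg: SearchConfig = SearchConfig(),
                        use_global: bool = True,
                        provenance: str = "synthetic unrelated pairs"
                        ) -> EVDReference:
    """Fit an EVD reference from all-pairs alignments of unrelated profiles.

    Aligns every unordered pair of the given (mutually unrelated) profiles
    with the two-pass protocol, using a provisional EVD reference only to
    drive the pass-2 narrowing, and fits the progressive-threshold Gumbel to
    the resulting scores.
    """
    from .align import align_two_pass
    from itertools import combinations

    profiles = list(profiles)
    gp = None
    if use_global:
        gs = build_global_score_system(profiles, cfg, seed=cfg.seed)
        gp = (gs.lambda_u, gs.K_u)
    provisional = EVDReference(lambda_g=0.25, mu=30.0,
                               K_g=np.exp(0.25 * 30.0) / 200.0 ** 4,
                               search_space=200.0 ** 4)
    scores, spaces = [], []
    for p1, p2 in combinations(profiles, 2):
        try:
            hit, system = align_two_pass(p1, p2, cfg, evd=provisional,
                                         global_params=gp)
        except InadmissibleScoreSystem:
            continue
        scores.append(hit.score)
        spaces.append(p1.length * p2.length)
    ref = fit_evd_reference(np.array(scores),
                            search_space=float(np.mean(spaces)),
                            provenance=provenance)
    return ref
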