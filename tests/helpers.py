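"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: alignment scores
are found by exhaustive path enumeration, autocorrelations by explicit
double loops, and lambda by plain interval bisection.
"""

import numpy as np


def enumerate_best_local_score(S, G, C):
    """Maximum score over every local alignment path, by exhaustive DFS.

    A path starts with a matched cell (a, b) scoring S[a, b] and extends by
    diagonal (match S[a+1, b+1]), vertical (gap in profile 2, cost
    G[a+1, b]) or horizontal (gap in profile 1, cost C[a, b+1]) steps.
    """
    m, n = S.shape
    best = 0.0

    def dfs(a, b, acc):
        nonlocal best
        if acc > best:
            best = acc
        if a + 1 < m and b + 1 < n:
            dfs(a + 1, b + 1, acc + S[a + 1, b + 1])
        if a + 1 < m:
            dfs(a + 1, b, acc - G[a + 1, b])
        if b + 1 < n:
            dfs(a, b + 1, acc - C[a, b + 1])

    for a in range(m):
        for b in range(n):
            dfs(a, b, S[a, b])
    return best


def brute_characteristic_values(maxima, z=0.0):
    """Per-position sqrt(mean over unordered pairs of clipped products)."""
    maxima = np.atleast_2d(maxima)
    out = np.empty(maxima.shape[0])
    w = maxima.shape[1]
    for k, row in enumerate(maxima):
        total = 0.0
        count = 0
        for i in range(w):
            for j in range(i, w):
                total += max(row[i] + z, 0.0) * max(row[j] + z, 0.0)
                count += 1
        assert count == w * (w + 1) // 2
        out[k] = np.sqrt(max(total, 0.0) / count)
    return out


def brute_gap_cost_limits(char_values, omega, z=0.0):
    """Double-loop second-level autocorrelation over cyclic windows."""
    a = np.asarray(char_values, dtype=float)
    m = a.size
    out = np.empty(m)
    norm = omega * (omega + 1) / 2
    for i in range(m):
        window = [a[(i + k) % m] for k in range(omega)]
        total = 0.0
        for p in range(omega):
            for q in range(p, omega):
                total += max(window[p] + z, 0.0) * max(window[q] + z, 0.0)
        out[i] = np.sqrt(max(total, 0.0) / norm)
    return out


def bisect_lambda(values, probs, lo=1e-9, hi=60.0, iters=200):
    """Plain bisection for sum p exp(lambda s) = 1 on (0, hi]."""
    values = np.asarray(values, dtype=float)
    probs = np.asarray(probs, dtype=float)

    def f(lam):
        return probs @ np.exp(lam * values) - 1.0

    assert f(hi) > 0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def noisy_block_msa(rng, n_seq=60, conserved=25, noisy=20):
    """Conserved flanks around a uniformly random high-complexity block."""
    from coma import MultipleAlignment
    from coma.alphabet import AMINO_ACIDS

    aa = np.array(list(AMINO_ACIDS))
    left = np.tile(np.array(list("ACDEF" * 5))[:conserved], (n_seq, 1))
    right = np.tile(np.array(list("GHIKL" * 5))[:conserved], (n_seq, 1))
    noise = aa[rng.integers(0, 20, size=(n_seq, noisy))]
    rows = ["".join(r) for r in np.concatenate([left, noise, right], axis=1)]
    msa = MultipleAlignment(
        sequence_ids=[f"s{i}" for i in range(n_seq)], rows=rows)
    return msa, conserved, conserved + noisy


def random_admissible_distribution(rng, max_support=12):
    """Random integer score distribution with negative mean, positive max."""
    while True:
        k = rng.integers(2, max_support)
        values = rng.choice(np.arange(-10, 11), size=k, replace=False)
        probs = rng.dirichlet(np.ones(k))
        if (values * probs).sum() < -1e-3 and values[probs > 1e-9].max() > 0:
            return values.astype(float), probs
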