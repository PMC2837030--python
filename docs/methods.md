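# Methods

This note documents the model implemented by `coma`, the choices made where
the design was genuinely open, and what the shipped tests do and do not
demonstrate.

## Profile model

A multiple sequence alignment (aligned FASTA, query first) is reduced to a
profile: one record per usable alignment column.

**Column masking.**  Stretches of columns whose weighted residue
distributions are nearly uniform usually indicate misaligned or
structurally unrelated segments; optionally, very low-entropy stretches
(compositional repeats) can be masked too.  We score each column by its
normalized weighted Shannon entropy (gaps excluded, divided by ln 20, so
values lie in [0, 1]) and apply a SEG-style two-threshold scheme to the
windowed mean: windows above the trigger threshold seed segments that
extend while above the extension threshold.  Defaults: window 12 columns,
high trigger/extension 0.90/0.85, low trigger/extension 0.15/0.20 (low
filter off).  The thresholds sit well above what conserved families reach
and below the ~0.93–0.97 plateau of genuinely uniform columns in
alignments of ≳50 sequences; with few sequences the finite-sample entropy
bias (≈(k−1)/(2n ln 20)) lowers column entropies, making the high filter
conservative.  Masked columns are dropped from the profile entirely;
coordinates of the surviving columns are retained.

**Reduced alignments and weights.**  At column i only sequences whose
residue at i is strictly interior to their aligned span participate in
weighting and effective-count estimation; terminal residues are a known
source of degenerate weights.  If the reduced set is empty the fallback is
every sequence with a residue at i, then the query alone.  Sequence
weights are position-based (Henikoff–Henikoff): each column donates
1/(types × count) per sequence, gap counted as a 21st symbol type.  For
observed frequencies the row set is extended by sequences whose *gap* at i
is interior (a genuine deletion), so residue plus gap frequencies sum to
one per column.  The effective number of sequences t^(i) is the mean
number of distinct residue types per column of the reduced alignment,
floored at 1 — the PSI-BLAST convention, adopted because the quantity is
used only through 1 − 1/t and the logistic thickness factor, both of which
need a diversity scale, not a precise count.

**Target probabilities.**  Tatusov pseudocounts:
t_a = (α·f̂_a + β·g_a)/(α + β) with α = t^(i) − 1, β = 10 (the standard
pseudocount mass; exposed as `pseudocount_weight`), f̂ the
residue-renormalized frequencies and g_a = Σ_b f̂_b q_ab/p_b the
substitution-implied prior.  The initial score table is BLOSUM62 with
Robinson–Robinson backgrounds; its joint frequencies are reconstructed as
q_ab = p_a·p_b·e^{λ·s_ab} at the solved λ (0.3176 nats per matrix unit;
K = 0.134, H = 0.401 — matching the published ungapped values, which the
test suite asserts).  `B`/`Z` are split between their constituent residues
at background proportions, `X` follows the background.

**Indels.**  The raw deletion probability of a position is its weighted
gap frequency; maximal runs of consecutive positions with positive raw
values are replaced by the straight line through the run's end values
(single positions unchanged), reflecting the observation that deletion
probabilities vary approximately linearly across a deletion.  Values below
1e-9 are treated as exact zeros so floating-point residue cannot seed
spurious runs.  Insertion probabilities are the raw gap frequencies —
every insertion faces a real residue, so no smoothing is needed.  Both are
damped at use time by the logistic thickness factor 1/(1 + e^{−t·u + v}),
u = 1, v = 2: a 50% gap observed in a two-sequence alignment (t ≈ 2) is
halved, while t ≳ 8 passes through almost unchanged.

**Composition adjustment.**  Positional scores
s_ia = (1/λ_p)·ln(t_a/p_a) are uniformly rescaled until the profile's own
solved ungapped λ (profile-versus-background system, cell probability
p_a/m) equals the table's λ_p within 1e-4 relative.  Because
λ(r·s) = λ(s)/r holds exactly for the continuous solve, one analytic step
converges; the loop is kept as a safeguard.  A profile whose targets equal
the background everywhere has no positive score and is rejected.

## Pair score system

For profiles P (length m) and Q (length n) define
L1_ij = Σ_a f̂'_a^(j)·s_ia and L2_ij = Σ_a f̂_a^(i)·s'_ja — each profile's
log-odds averaged over the other's observed frequencies.  The thickness
correction mixes them with weights w1 = 1 − 1/t^(i), w2 = 1 − 1/t'^(j)
(falling back to the even mixture when both vanish, i.e. two
single-sequence profiles get no correction): the thin profile's
pseudocount-dominated targets contribute less, and in the single-sequence
limit the score degenerates to the partner profile's log-odds at the
sequence's residues.  The normalizer N is the mean over all m·n cells of
e^{λ_p·mix} for the uncorrected mixture, and
s_ij = mix_ij − ln(N)/λ_p, which makes the implied target probabilities of
the pair sum to one under the uniform cell background (each cell weight
1/(m·n)).

Positions with relative entropy r^(i) = Σ_a t_a·ln(t_a/p_a) below
τ = κ/(−ln E) are uninformative; their rows/columns are multiplied by 0.5
(`downscale_factor`).  κ = 1 and the per-hit expected E-value E = 1e-4
give τ ≈ 0.11 nats, which in practice touches only near-background
positions.  E ≥ 1 disables the threshold.

The scale parameter λ of the finished system is the positive root of
Σ_k p(s_k)·e^{λ·s_k} = 1 on scores multiplied by 2^c and rounded to
integers (c = `c_bits` = 5; the root is bracketed on (1e-6, 50), solved by
Brent and polished by Newton to 1e-8).  H follows from the expectation
form H = λ·Σ p·s·e^{λs}.  K is evaluated with the classical lattice
series K = λ'·e^{−2σ}/(H·(1 − e^{−λ'})) after reduction to the lattice
span, with σ accumulated by convolution powers until three consecutive
terms fall below 1e-5 of the sum (up to 500 terms; near-zero-drift systems
converge slowly).  K uses a coarser lattice (`c_bits_K` = 2): it enters
E-values only through the ratio K_u*/K_u, and the coarser lattice cuts the
convolution cost roughly tenfold at ≲1% effect on the ratio.

**Composition-based statistics.**  All unique position vectors of a
profile database (rounded to 4 decimals; two-level index with sorted
buckets for exact dedup) form the global score system: all vector pairs —
or a uniform 10⁶-pair sample with a fixed seed when the full product is
larger — are scored with the same cell formula, and the solved λ_u, K_u,
H_u become the database's reference.  Every pair system's scores are then
multiplied by λ*/λ_u (the identity λ(r·s) = λ(s)/r), so identical scores
carry identical significance across pairs.  In pairwise mode (no
database) the initial table's λ_p serves as the reference.

## Alignment

A modified Smith–Waterman recurrence over the pair score system: diagonal
moves add s_ij, vertical moves subtract G(i, j), horizontal moves subtract
C(i, j), cells floor at zero, ties break diagonal > vertical > horizontal,
and the single best local alignment is traced back from the global
maximum.  Gap costs are charged per traversed cell at the current partner
position (they are per-position costs, not open/extend pairs).

**Gap model.**  For each row of the score system the w = 4 largest scores
(padded by repeating the smallest kept value when fewer exist) are
autocorrelated — all unordered pairs of multipliers including self-pairs,
w(w+1)/2 products — and the square root of the mean product is that
position's characteristic value; the same operation over a forward-cyclic
window of ω = 4 characteristic values gives the gap cost limit A^(i)
(B^(j) columnwise).  Multipliers are floored at zero: negative scores
carry no gap-cost signal, and the floor makes the limits monotone in the
widening term.  Non-positive product sums give a limit of zero.  The
widening term z is added to every multiplier at both levels: pass 1 uses
z₁ = ζ/√H (ζ = 1) — weak score systems (small H) get inflated limits so
that runs of low positive scores cannot assemble spuriously high-scoring
gapped alignments — and after an initial alignment with analytical
ungapped E-value, pass 2 uses z₂ = −y/(ln E + x), clamped to [0, 10].
x = 0 and y = 10: with these values the narrowing sets in gradually
(z₂ ≈ 4.3 at E = 0.1, ≈1.1 at E = 1e-4), which keeps the unrelated-score
distribution on a stable extreme-value tail; a much smaller y collapses
the limits as soon as E < 1 and visibly deforms the null score tail away
from the Gumbel shape the significance model assumes.  Final costs:
G(i, j) = A^(i)·(1 − (c·D^(i) + I'^(j) − c·D^(i)·I'^(j))) — a
probabilistic OR of the down-weighted own-deletion signal (c = 0.6) and
the partner's insertion signal — and symmetrically for C(i, j).

## Significance

Gapped-score statistics cannot be derived analytically under this gap
scheme, so the reference scale and location of the Gumbel tail are fitted
empirically on scores of unrelated profile pairs.  The fit is a *censored*
maximum-likelihood Gumbel fit: scores above a lower bound contribute their
densities, scores below only their count.  This anchors the unconditional
exceedance probabilities (what E-values are made of), stays consistent at
any bound for genuinely Gumbel data, and recovers the tail under low-score
contamination.  The bound rises over a 30-point grid; stabilization is the
first bound whose λ and μ change by under 2% across three consecutive
bounds *and* whose λ agrees with the deepest usable bound within 10% — the
second condition rejects false plateaus inside a contaminated low-score
region.  Standard errors come from a finite-difference Hessian.  K_g
follows from μ = ln(K_g·m·n)/λ_g at the calibration search space.

The packaged reference (`src/coma/data/evd_reference.json`) is a
*synthetic* calibration: all 11 175 unordered pairs of 150 independently
generated fixture profiles (200 positions × 50 sequences, seed 12345),
λ_g ≈ 0.193, μ ≈ 22.0.  `coma calibrate` refits it from any score list or
profile database.

Per pair, λ_g* = λ_g·(λ_u*/λ_u) (≡ λ_g after composition scaling) and
K_g* = K_g·(K_u*/K_u); then E = K_g*·m·n·e^{−λ_g*·s}, P = 1 − e^{−E}.
In database searches n is the total position count of the database, in
pairwise mode the partner profile's length.  The edge-effect correction
(expected alignment length ℓ(s) = λ_g*·s/H subtracted from the lengths,
floored at 1) is implemented but off by default: the packaged calibration
and the E-value formula then invert each other exactly, which is what the
null-model uniformity of P-values relies on.  Turning it on is appropriate
when comparing very short profiles at large scores.

## Synthetic data

The generator emulates exactly the statistical structure the method
feeds on: per-position residue distributions drawn from a Dirichlet
centred on the Robinson–Robinson background, with the total concentration
controlling conservation (0.5 → spiky conserved columns, 20 → near-
background variable columns, alternating 8-column cores and 4-column
loops by default); sequences sampled i.i.d. per column; planted deletion
runs adopted per sequence with a set probability; a gapless query row.
Related pairs share parent distributions over a contiguous block covering
a chosen fraction of positions.

It deliberately does **not** simulate phylogenetic correlation between
sequences, insertion-length variation, alignment errors, or the domain
length/composition heterogeneity of real databases.  Passing tests
therefore demonstrate internal correctness and calibration under the
model's own assumptions — independent columns and Gumbel-tailed null
scores — not benchmark performance on real protein families.

## Numerical and testing choices

* Natural logarithms throughout; λ in nats per score unit; scores in the
  initial table's units.
* Profile serialization prints 8 decimals (round-trips asserted at 1e-6);
  targets are renormalized on read.
* Per-position weight computations are cached by row-subset, since gap
  patterns repeat across columns.
* The DP kernel is JIT-compiled with numba (a pure-Python fallback keeps
  the package importable without it).
* Test problem sizes: null calibration uses all 2 145 pairs of 66
  independent 200×50 profiles; discrimination uses 100 related (shared
  fraction ≥ 0.75) and 100 unrelated pairs of the same size; DP
  correctness is checked against exhaustive path enumeration on 200 random
  systems up to 6×6; EVD recovery uses 50 000 Gumbel draws.

## Known limitations

* The shipped initial score table is BLOSUM62; `derive_initial_table`
  builds a table from any alignment collection (BLOSUM-style weighted pair
  counting), but no curated-alignment table ships with the package.
* Only the single best local alignment per pair is reported; sub-optimal
  alignments are out of scope.
* The packaged EVD reference describes the synthetic null; searches on
  real profile collections should recalibrate with `coma calibrate`.
* α/β-style edge-effect parameters are approximated by the analytic
  expected-length form rather than fitted per database.
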