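# coma — profile–profile comparison for remote homology detection

Detecting that two protein families share a common evolutionary origin is
far easier from *profiles* (per-position residue statistics distilled from
multiple sequence alignments) than from single sequences.  `coma`
implements a complete profile–profile search method in the COMA
(Comparison Of Multiple Alignments) style, for computational biologists who
need calibrated significance estimates for matches between distantly
related families:

* **Profile construction** — SEG-style compositional-complexity masking of
  alignment columns, position-specific reduced alignments, modified
  Henikoff–Henikoff sequence weights, Tatusov pseudocount target
  probabilities t_a^(i), per-position deletion/insertion probabilities
  D^(i), I^(i) (deletions linearly generalized across gap runs), and
  composition adjustment of the positional log-odds scores
  s_ia = (1/λ_p)·ln(t_a^(i)/p_a) onto the initial table's λ_p.
* **Pair score system** — the cell score s_ij for matching position i of
  one profile with position j of another is a symmetric cross log-odds:
  each profile's scores averaged over the partner's observed frequencies,
  mixed with thickness weights w = 1 − 1/t (t = effective sequences, so
  pseudocount-dominated thin profiles are down-weighted), normalized so
  the implied target probabilities sum to one, and scaled down (×0.5) at
  positions of low relative entropy.
* **Position-dependent gap costs** — gap cost limits A^(i), B^(j) from a
  two-level autocorrelation of the score system's row/column maxima
  (w = ω = 4), widened by z = ζ/√H and re-estimated as z = −y/(log E + x)
  after an initial alignment; final two-sided costs combine the limits
  with the indel probabilities, G^(i) = A^(i)·(1 − (c·D^(i) ∨ I^(j))),
  c = 0.6.  Gaps are cheap where the families tolerate indels, expensive
  at conserved cores.
* **Statistics** — Karlin–Altschul λ, K, H solved analytically per pair
  from the discretized score distribution; composition-based rescaling onto
  a database-wide *global score system* of unique profile vectors
  (λ_u, K_u); a Gumbel (EVD) reference for gapped scores
  (λ_g, μ → K_g) fitted on unrelated-pair scores with a progressive
  score-threshold protocol; per-pair gapped parameters by the ratio rules
  λ_g* = λ_g·λ_u*/λ_u, K_g* = K_g·K_u*/K_u; finally
  E = K_g*·m·n·exp(−λ_g*·s) and P = 1 − exp(−E).

A synthetic-fixture generator (Dirichlet column distributions around
Robinson–Robinson backgrounds, planted gap runs, tunable relatedness)
makes the whole method testable without external databases.

## Worked example

`python examples/pairwise_compare.py` builds two families that share 70%
of their positions and compares them:

```
pair score system: lambda=0.3177, K=0.0752, H=0.2427
alignment score 518.5, 141 aligned positions, E=1.36e-42, P=1.36e-42
(E is the expected number of chance hits this strong; E << 1 indicates homology)

famA vs famB  score=518.5 E=1.36e-42 P=1.36e-42 aligned=141
Q     1 TlnlpklsdtpapsGPasPGsipapcDFehlandnpDalLvemsalggDrAELsPappel 60
        TLNLPKLS+++ PSGPASPGSIP++CDFEHLANDNPDALLVEM+++GGDRAEL+PA++EL
T     1 TLnlpklsaallpsGPasPGsipkicDFehlandnpDallvemprhggDrAeLdpatdel 60
...
unrelated control: score 21.9, E=0.572 (chance-level)
```

The solved λ of the pair system matches the BLOSUM62 reference (0.3176
nats) because of composition-based rescaling; the related pair scores
518.5 over 141 aligned positions, an E-value of 1.4·10⁻⁴², while the
unrelated control stays at chance level (E ≈ 0.6).  Upper case in the
rendered blocks marks confident consensus positions, `+` positively
scoring matched pairs.

The other scripts in `examples/` walk through profile construction
(`build_profile.py`), a query-vs-database search with the global score
system (`database_search.py`) and EVD recalibration plus a null-model
check (`calibrate_statistics.py`).

## Command line

```bash
coma build -i family.fa -o profiles/        # aligned FASTA -> .prof
coma makedb profiles/*.prof -o families.db  # database + global statistics
coma search -q query.fa -d families.db      # ranked TSV hit table
coma search --all-vs-all -d families.db     # each unordered pair once
coma pair a.prof b.prof --alignments        # one pair, rendered alignment
coma calibrate --db families.db -o evd.json # refit the EVD reference
coma fixtures -n 5 -o fixtures/             # synthetic MSA fixtures
```

Exit codes: 0 success, 2 input error, 3 numerical failure.

## Layout

```
src/coma/        alphabet, msa, seg, profile(+_io), pairscore, gaps,
                 align, karlin, stats, fixtures, config, cli
src/coma/data/   packaged EVD reference (synthetic calibration)
tests/           unit, property and acceptance tests (pytest + hypothesis)
examples/        narrative scripts, one per capability
docs/methods.md  model, assumptions, parameter choices, limitations
```
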