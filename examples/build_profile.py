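"""Build a sequence profile from a multiple alignment.

Generates a synthetic family alignment (conserved cores, variable loops,
one deletion run), converts it into a profile and prints the per-position
quantities the rest of the pipeline consumes.
"""

import numpy as np

from coma import BuildParams, FixtureSpec, build_profile, \
    load_initial_table, sample_family_msa

table = load_initial_table()                     # BLOSUM62 + solved stats
print(f"initial table {table.name}: lambda={table.lambda_:.4f} nats/unit, "
      f"K={table.K:.4f}, H={table.H:.4f} nats")

spec = FixtureSpec(n_positions=120, n_sequences=40,
                   gap_runs=((50, 6, 0.4),), seed=42)
msa = sample_family_msa(spec, np.random.default_rng(42), name="famA")
profile = build_profile(msa, table, BuildParams(), name="famA")

print(f"\nalignment: {msa.n_sequences} sequences x {msa.length} columns")
print(f"profile:   {profile.length} positions "
      f"({msa.length - profile.length} columns masked/dropped)")
print(f"effective sequences per position: "
      f"mean {profile.eff_seqs.mean():.2f}, "
      f"range [{profile.eff_seqs.min():.1f}, {profile.eff_seqs.max():.1f}]")
print(f"relative entropy (nats): mean {profile.rel_entropy.mean():.3f} "
      f"(high = conserved, informative positions)")

run = slice(48, 56)  # around the planted deletion run
print("\npositions around the deletion run (columns 50-55):")
print("pos  del_prob ins_prob  eff   rel_ent")
for i in range(*run.indices(profile.length)):
    print(f"{int(profile.columns[i]):3d}  {profile.del_prob[i]:7.3f} "
          f"{profile.ins_prob[i]:7.3f}  {profile.eff_seqs[i]:5.2f} "
          f"{profile.rel_entropy[i]:7.3f}")
print("\nGap-carrying positions show raised deletion/insertion "
      "probabilities;\nthe deletion profile is linear across the run.")
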