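"""Simulate profiles with known ground truth and recover the lineage.

Generates a 5-level binary haplogroup tree (32 leaves, 2 markers per
branch) whose composite reference carries the derived alleles of four
leaves — one per depth-2 subtree, emulating how the real Y reference mixes
several haplogroups. Error-free profiles must be assigned back to exactly
the simulated leaf; heavy call dropout pushes the sample into the
insufficient-quality regime.
"""

from amytree import SimSpec, assign, make_fixture, oracle_assign, simulate_profile

fx = make_fixture(SimSpec(n_levels=5, branching=2, markers_per_branch=2,
                          reference_lineages=4, seed=11))
leaves = [leaf.name for leaf in fx.tree.leaves()]
print(f"tree: {len(leaves)} leaves, {len(fx.markers)} markers; "
      f"reference lineages: {fx.reference_lineages}")

n_ok = 0
for leaf in leaves:
    profile = simulate_profile(fx, leaf, fp_rate=0.0, fn_rate=0.0, seed=1)
    result = assign(profile, fx.tree, fx.markers, fx.reference)
    assert oracle_assign(profile, fx) == {leaf}
    n_ok += result.final_alphanumeric == [leaf]
print(f"zero-error recovery: {n_ok}/{len(leaves)} leaves assigned exactly")

low = simulate_profile(fx, leaves[5], fp_rate=0.0, fn_rate=0.7, seed=4)
result = assign(low, fx.tree, fx.markers, fx.reference)
print(f"70% dropout: quality={result.quality.category}, "
      f"final={result.final_alphanumeric}")
print("warnings:")
for warning in result.warnings:
    print(f"  - {warning}")

# At zero error every leaf is recovered (and the exhaustive leaf-scoring
# oracle agrees); at 70% dropout the quality gate flags the profile, the
# horizontal descent stops at the root, and the assignment falls back to
# the vertical scan — here still recovering the true leaf, with cautions.
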