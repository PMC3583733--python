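"""Assign the packaged fictive sample to its sub-haplogroup.

The packaged fixture models an individual from sub-haplogroup Z2b3a on a
small tree with haplogroups X, Y and Z, against a composite reference that
carries the derived alleles of the X and Y backbone markers. The script
runs the full pipeline and prints each stage.
"""

from amytree import assign, walkthrough_fixture

fx = walkthrough_fixture()
result = assign(fx.profile, fx.tree, fx.markers, fx.reference)

print(f"call quality score : {result.quality.score:.3f} ({result.quality.category})")
print(f"vertical (true leaves)        : {sorted(result.vertical)}")
print(f"horizontal (descent)          : {sorted(result.horizontal)}")
print(f"combinatorial (intersection)  : {sorted(result.combinatorial)}")
print(f"specific (deepest)            : {sorted(result.specific)}")
print(f"final haplogroup              : {result.final_alphanumeric} "
      f"= {result.final_mutation_based}")

# The vertical scan alone reports three candidate leaves (X1a is a false
# positive from a single spurious call); the horizontal descent pins the
# lineage to Z2b, their combination keeps the two Z2b leaves, and the
# specific step resolves the paragroup Z2b* to the named subclade Z2b3a.
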