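"""Emit the tree-curation reports for the packaged sample.

Beyond the haplogroup call, an analysis produces three curation outputs:
the per-marker SNP status table, the mutant markers missing from the tree
(ConvNotTree), and the called SNPs unknown to the conversion table
(new / yupp-SNPs).
"""

import tempfile
from pathlib import Path

from amytree import (
    assign,
    build_status_table,
    walkthrough_fixture,
    find_conv_not_tree,
    find_yupp_snps,
    write_reports,
)

fx = walkthrough_fixture()
result = assign(fx.profile, fx.tree, fx.markers, fx.reference)
states = build_status_table(fx.markers, fx.profile, fx.reference)

print("marker states (state / provenance):")
for state in states:
    print(f"  {state.marker_name:6s} {state.state:>2d}  {state.provenance}")
print("excluded:", dict(sorted(states.excluded_markers.items())))

conv_not_tree = find_conv_not_tree(states, fx.markers, fx.tree)
print("mutant markers absent from the tree:",
      [(m.name, m.synonyms) for m in conv_not_tree])

yupp = find_yupp_snps(fx.profile, fx.markers)
print("novel SNPs (unknown position):",
      [(y.position, y.ref_allele, y.obs_allele) for y in yupp])

with tempfile.TemporaryDirectory() as tmp:
    paths = write_reports(result, states, conv_not_tree, yupp, tmp)
    print("\nanalysis file:")
    print(Path(paths["analysis"]).read_text())

# L999 is derived in the sample but on no branch of the tree -> a candidate
# for phylogenetic placement; the call at position 800 matches no known
# marker at all -> a yupp-SNP. V218 and the indel marker are excluded with
# their reasons in the status file.
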