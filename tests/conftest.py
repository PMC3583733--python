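import logging

import pytest

from amytree.synthetic_fixtures import SimSpec, walkthrough_fixture, make_fixture

logging.getLogger("amytree").setLevel(logging.ERROR)

#: Study conditions for the lineage-recovery fixture: a 5-level binary tree
#: (32 leaves), two markers per branch, composite reference carrying the
#: derived alleles of 4 leaves, one per depth-2 subtree.
RECOVERY_SPEC = SimSpec(n_levels=5, branching=2, markers_per_branch=2,
                        reference_lineages=4, seed=7)


@pytest.fixture(scope="session")
def walkthrough():
    return walkthrough_fixture()


@pytest.fixture(scope="session")
def recovery_fixture():
    return make_fixture(RECOVERY_SPEC)


@pytest.fixture()
def tiny_fixture():
    """2-level binary fixture: 4 leaves, 1 marker per branch, 6 markers."""
    return make_fixture(SimSpec(n_levels=2, branching=2, markers_per_branch=1,
                                reference_lineages=1, seed=3))


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chrY,length=100000>
##contig=<ID=chr7,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chrY\t100\t.\tA\tC\t50\tPASS\t.\tGT\t1
chr7\t200\t.\tG\tT\t50\tPASS\t.\tGT\t1
chrY\t300\t.\tAT\tA\t50\tPASS\t.\tGT\t1
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path
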