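"""Convert a VCF into the three-column Y-SNP profile format.

Builds a tiny VCF in a temporary directory (one Y SNP, one autosomal SNP,
one Y indel), converts it, and prints the classification counts. Every
input record lands in exactly one bucket.
"""

import tempfile
from pathlib import Path

from amytree import convert_vcf

VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chrY,length=100000>
##contig=<ID=chr7,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chrY\t100\t.\tA\tC\t50\tPASS\t.\tGT\t1
chr7\t200\t.\tG\tT\t50\tPASS\t.\tGT\t1
chrY\t300\t.\tAT\tA\t50\tPASS\t.\tGT\t1
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "sample.vcf"
    path.write_text(VCF)
    profile, stats = convert_vcf(path, "hg19")

print(f"input records : {stats.n_input_records}")
print(f"Y-SNPs kept   : {stats.n_y_snps_kept}")
print(f"non-Y skipped : {stats.n_non_y_skipped}")
print(f"non-SNP skipped: {stats.n_non_snp_skipped}")
for call in profile.calls:
    print(f"profile row   : {call.position}\t{call.ref_allele}\t{call.obs_allele}")

# Only the haploid Y-chromosome substitution survives: the autosomal SNP and
# the Y indel are counted in their skip buckets, never converted.
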