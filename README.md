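# amytree

Y-chromosome haplogroup assignment from whole-genome SNP calling profiles.

The non-recombining portion of the human Y chromosome is strictly paternally
inherited, so all Y chromosomes fall into a single rooted phylogeny of
haplogroups, each clade defined by shared derived alleles at binary markers
(Y-SNPs, e.g. M173: A→C with A ancestral, C derived). Whole-genome
sequencing produces thousands of Y-SNP calls per sample; `amytree` places a
sample into that phylogeny automatically, independent of the sequencing
platform and calling program, while tolerating mistakes in both the SNP
calling and the tree. It is aimed at population geneticists, genetic
genealogists and forensic scientists who need (sub-)haplogroup calls, and at
curators who need to spot markers missing from the tree and novel SNPs
worth placing.

## Method

Inputs: the sample's called Y-SNPs (position / reference allele / observed
allele), a haplogroup tree with defining markers on its branches, a marker
conversion table (names, synonyms, hg18/hg19 positions, ancestral→mutant
conversion), and the reference Y sequence used for calling.

1. **Allelic states.** Every non-indel marker gets a state: 1 (mutant),
   0 (ancestral) or −1 (other), from the explicit call at its position when
   one exists, otherwise from the reference base (reference fallback), with
   the provenance recorded.
2. **Call quality test.** The reference Y is a composite of several
   sub-haplogroups while an individual belongs to one, so calls at backbone
   markers are always expected. The score is the fraction of a backbone
   panel with an explicit, allele-consistent call; below the threshold the
   calling is *insufficient* and reference-derived states lose their vote.
3. **Node truth.** For each node, pct mutant = mutant states / (mutant +
   ancestral states) over its defining markers. *Sufficient* regime: node
   true iff pct > 85% (strict), reference-derived states included.
   *Insufficient* regime: reference-derived mutant states removed from
   numerator and denominator, true iff pct > 5% (strict).
4. **Tree search.** Four sub-algorithms: **vertical** (which leaves are
   true), **horizontal** (root-to-leaf descent through true internal nodes,
   returning the last true ones), **combinatorial** (vertical leaves with a
   horizontal ancestor), **specific** (drop every candidate that is an
   ancestor of another; a paragroup like Z2b\* yields to candidates inside
   its parent's subtree). The final call is reported in both nomenclatures,
   alphanumeric (`R1b1b2a2*`) and mutation-based (`R-P312*`).

Two curation lists accompany every run: **ConvNotTree** (markers in the
mutant state with known conversion but absent from the tree, synonyms
included) and **New SNPs** (called positions unknown to the conversion
table — SNPs with yet unknown phylogenetic position).

Markers with indel conversions are excluded (e.g. the 4G→3G conversion of
M17), as are V218 (recurrent mutation within haplogroup I) and MEH2
(ambiguous within haplogroup Q) by default.

## Worked example

```sh
python examples/assign_packaged_sample.py
```

runs the packaged fictive sample (an individual from sub-haplogroup Z2b3a
on a small tree with haplogroups X, Y and Z) and prints:

```
call quality score : 0.667 (sufficient)
vertical (true leaves)        : ['X1a', 'Z2b*', 'Z2b3a']
horizontal (descent)          : ['Z2b']
combinatorial (intersection)  : ['Z2b*', 'Z2b3a']
specific (deepest)            : ['Z2b3a']
final haplogroup              : ['Z2b3a'] = ['Z-M325']
```

The vertical scan alone lists three candidate leaves (X1a is a false
positive from one spurious call); the horizontal descent stops at Z2b; only
leaves below Z2b survive the combination; and the paragroup Z2b\* yields to
the named subclade, leaving Z2b3a. The other examples cover VCF conversion
(`convert_vcf_profile.py`), simulation with ground truth
(`simulate_and_recover.py`) and the curation reports
(`curation_reports.py`).

The same analysis from a shell:

```sh
amytree run --profile profile.tsv --tree tree.tsv --conv conversion.tsv \
            --ref chrY.fa --build hg19 --out results/
why --in sample.vcf --format vcf --build hg19 --out profile.tsv
amytree simulate --seed 11 --out fixture/
```

## Layout

- `src/amytree/core_model.py` — domain types, TSV/FASTA readers and writers
- `src/amytree/why_convert.py` — VCF / Complete Genomics var → profile
- `src/amytree/marker_status.py` — allelic-state resolution with provenance
- `src/amytree/call_quality.py` — the quality gate
- `src/amytree/assignment.py` — node truth and the four sub-algorithms
- `src/amytree/reports.py` — the four output files and curation lists
- `src/amytree/synthetic_fixtures.py` — ground-truth generator and oracles
- `docs/methods.md` — model, parameters, design choices, limitations
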