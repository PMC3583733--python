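# Methods

## Model and assumptions

The Y-chromosome phylogeny is a rooted tree of haplogroups; each branch
carries one or more binary markers whose derived (mutant) allele arose once
on that branch. Under strict paternal inheritance without recombination, an
individual's Y chromosome is derived for exactly the markers on one
root-to-leaf path (barring recurrent mutation and genotyping error). A
whole-genome SNP calling profile reports the positions where the sample
differs from the reference; positions not reported are assumed to match the
reference. Two facts complicate the naive read-off:

* the reference Y is itself a composite of several sub-haplogroups, so it
  carries derived alleles on several lineages; a sample can therefore be
  *ancestral* at positions where the reference is derived, and such
  differences are genuine calls;
* call sets contain false positives and, at low coverage, many false
  negatives.

The method therefore resolves marker states with provenance, gates the
analysis on a calling-quality test, and requires branch-level consensus
(percent-mutant thresholds) rather than single-marker evidence.

### Allelic states

For each non-indel marker with a position on the active build: if a call
exists at the position, the observed allele is compared with the
ancestral/mutant pair; otherwise the reference base is. State 1 = mutant,
0 = ancestral, −1 = neither; provenance `called` or `reference`. When the
observed allele matches neither allele, its reverse complement is tried
once before assigning −1 (`strand_rescue`, default on, recorded in the
state's note): published marker lists mix strand conventions, and the
rescue is flag-controlled because it trades a small risk of false matches
(complement-symmetric conversions) for robustness to strand mix-ups.

### Call quality test

The score is
`(# panel markers with an explicit call whose observed allele equals the
marker's ancestral or mutant allele) / |panel|`,
with verdict *sufficient* iff score ≥ `quality.threshold`. The default
panel is all markers defining nodes at depth ≤ 2 of the loaded tree (the
backbone of the major haplogroups); markers whose derived allele the
reference itself carries are additionally flagged as expected-call markers,
since a sample can never be derived for every composite-reference lineage
at once. Panel, threshold (default 0.5) and depth are configurable; the
defaults were chosen to reproduce the qualitative behaviour that matters —
high-coverage profiles pass, heavy-dropout profiles fail, and a large call
count does not imply a high score when the calls are allele-inconsistent —
while remaining honest that no published constant fixes them. The verdict
depends on the inputs only through the score, so re-runs are bit-identical.

### Node truth

Let m = number of the node's marker states equal to 1 and a = number equal
to 0 (−1 states carry no ancestral/mutant information and never enter the
denominator). Sufficient regime: true iff m/(m+a) > 0.85. Insufficient
regime: reference-derived mutant states are deleted from both m and the
denominator (the reference can no longer be trusted to speak for uncalled
sites), and true iff the remaining fraction > 0.05. Both thresholds are
strict inequalities: a node at exactly 85.0% or 5.0% is false. A node with
an empty denominator (e.g. all markers indel or unplaced on the build) is
*indeterminate*.

### Tree search

* **Vertical** — the set of true leaves. Indeterminate leaves are excluded
  and named in the warnings.
* **Horizontal** — a recursive descent from the root through *internal*
  nodes only: true internal children are followed, and a true internal node
  from which the descent finds nothing deeper contributes itself;
  indeterminate internal nodes are passed through (descent continues below
  them) but are never returnable. Leaves belong to the vertical method;
  keeping them out of the horizontal one is what lets the two methods
  cross-check each other, and is the reading under which the packaged
  walkthrough reproduces all printed stage outputs.
* **Combinatorial** — vertical leaves with at least one horizontal node
  among their ancestors (or equal to themselves).
* **Specific** — every candidate that is an ancestor of another is dropped.
  A paragroup leaf (`Z2b*`) has no markers of its own and borrows its
  parent's, so whenever it is true its parent's subtree is too; it is
  treated as an ancestor of its named siblings' subtrees and yields to any
  candidate there. Incomparable candidates are all returned.

When the horizontal method returns nothing (typical under heavy dropout:
the descent stops at the root), the final result falls back to
`specific(vertical)` with an explicit warning, rather than returning
nothing — low-coverage samples still get their best-supported leaves, with
the caution attached. An insufficient verdict always adds a caution
warning.

### Nomenclature

`<first letter of the haplogroup label>-<first defining marker>`, with the
paragroup `*` preserved (`R1b1b2a2*` + P312 → `R-P312*`). The root keeps
its own label; a node with no resolvable marker becomes `<letter>-?` plus a
warning.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sufficient_truth_threshold` | 0.85 | strict pct-mutant bound, sufficient regime |
| `insufficient_truth_threshold` | 0.05 | strict pct-mutant bound, insufficient regime |
| `quality.threshold` | 0.5 | score bound for a *sufficient* verdict |
| panel depth | 2 | tree depth whose markers form the default quality panel |
| `exclusions` | V218, MEH2 | markers removed before analysis (recurrent / ambiguous) |
| `strand_rescue` | on | complement retry for otherwise-unmatched alleles |

All are configurable through `AssignParams` / the `--config` file of the
CLI.

## Format conventions

Conversion table: TSV with header `name, synonyms, rs_id, pos_hg18,
pos_hg19, conversion`; extra trailing columns tolerated; a conversion not
of the form `X->Y` rejects the row with a warning; markers whose conversion
is not single-base↔single-base are indels and excluded downstream. Tree:
TSV `haplogroup, parent, defining_markers`; children keep file order; two
roots, orphan parents, cycles and duplicate names are errors naming the
row. Profile: headerless TSV `position, ref, obs`; multi-base rows are
skipped and counted; duplicate positions keep the first occurrence (order-
stable behaviour for merged call sets). Reference: FASTA, first record
whose id contains "Y". VCF conversion keeps haploid/homozygous-alt
single-base Y records; heterozygous genotypes on the haploid Y are
artifacts and are skipped with a warning; of multi-allelic records the
first genotype-carried ALT is taken. Complete Genomics var coordinates are
0-based half-open, converted to 1-based (`position = end` for a 1-base
SNP). All set-valued outputs are emitted sorted, making reports
byte-stable across re-runs.

## Synthetic data

`make_fixture` generates a complete `n_levels`-deep tree (default 5 levels,
branching 2 → 32 leaves) with `markers_per_branch` (default 2) unique
markers per branch at distinct positions drawn without replacement from
1..10·n_markers; the slack leaves non-marker positions for planting novel
SNPs. The reference carries the mutant allele exactly on branches ancestral
to the chosen `reference_lineages` (default: 4 leaves, one per depth-2
subtree) and the ancestral allele elsewhere — the composite-reference
model. `simulate_profile` emits the leaf/reference difference set, drops
each true call with probability `fn_rate`, and adds a spurious wrong-base
call at each remaining site with probability `fp_rate`. All randomness
comes from numpy's seeded PCG64 generator; no global state.

What this emulates: ascertainment of every known marker position,
coverage-driven dropout, and isolated miscalls. What it does not: read-level
error structure, linked/systematic artifacts, recurrent mutations, markers
missing from the tree by curation lag, and real marker density. Passing the
recovery tests therefore shows the search logic and gating are correct
under the stated error model, not that real-genome accuracy at any coverage
is guaranteed.

The four-reference-lineage default matters: with fewer lineages, a sample
from (or near) a reference lineage has almost no expected calls at backbone
markers and legitimately lands in the insufficient regime — the same effect
that makes samples phylogenetically close to the real reference composition
produce few calls.

The packaged walkthrough fixture (tree with haplogroups X, Y, Z; sample
from Z2b3a) is hand-built: its reference carries the derived alleles of the
X and Y backbone markers, its profile contains the corresponding
ancestral-allele calls, one spurious derived call at the X1a marker, one
derived marker absent from the tree (L999) and one call at a position
unknown to the conversion table — so a single run exercises every stage and
both curation lists. Its files are plain TSV/FASTA under
`src/amytree/data/` (the reference is synthetic, as its record id says).

## Verification

Each traversal has an independently written brute-force counterpart
(direct set definitions over ancestor lists) checked for exact equality on
hundreds of seeded random trees with random truth assignments including
indeterminate nodes and paragroups; `oracle_assign` re-derives the
assignment by exhaustive leaf scoring and must agree with the pipeline on
zero-error profiles for every leaf. The error injector's spurious-call
count is checked against its binomial expectation over 500 replicates.
Problem sizes (32-leaf recovery fixture, 200 random trees, ≤64 leaves)
were chosen as the smallest that exercise multi-level descent, paragroup
resolution and both regimes.

## Known limitations

* Indel-defined lineages cannot be called (indels are excluded wholesale),
  so end lineages defined only by indels are unreachable.
* Recurrent mutations are not modelled; the V218/MEH2 exclusion list is the
  blunt instrument, and users can extend it.
* The quality-test constants are package defaults, not published values;
  the score and panel size are reported in the analysis file so users can
  recalibrate.
* One sample per run; cross-sample aggregation of curation lists is out of
  scope.
* No liftover: a profile must match the build of the reference and marker
  positions used.
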