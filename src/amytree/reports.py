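"""The four output files of an analysis run, plus the tree-curation lists.

Besides the analysis file with the haplogroup assignment, three files make
it possible to check, correct and expand the phylogenetic tree:

* the SNP status file — the allelic state of every known marker, with the
  provenance (explicit call vs reference derivation);
* the ConvNotTree file — markers found in the mutant state whose conversion
  is known but which are absent from the phylogeny in use (candidates for
  placement; their synonyms are listed too);
* the New SNPs file — called SNPs with yet unknown phylogenetic position
  (yupp-SNPs), absent even from the conversion table.

All files are byte-stable across re-runs on identical inputs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from .assignment import AssignmentResult
from .core_model import MarkerDef, MarkerTable, PhyloTree, SnpProfile
from .marker_status import StatusTable

logger = logging.getLogger("amytree")

__all__ = [
    "YuppSnp", "find_conv_not_tree", "find_yupp_snps", "write_reports",
    "ANALYSIS_FILE", "STATUS_FILE", "CONV_NOT_TREE_FILE", "NEW_SNPS_FILE",
]

ANALYSIS_FILE = "analysis.txt"
STATUS_FILE = "snp_status.tsv"
CONV_NOT_TREE_FILE = "conv_not_tree.tsv"
NEW_SNPS_FILE = "new_snps.tsv"


@dataclass(frozen=True)
class YuppSnp:
    """A called SNP whose position matches no known marker on the build."""

    position: int
    ref_allele: str
    obs_allele: str


def _tree_marker_closure(tree: PhyloTree, markers: MarkerTable) -> set[str]:
    """Canonical names of every marker mentioned on any branch of the tree."""
    closure: set[str] = set()
    for node in tree.nodes():
        for name in node.defining_markers:
            closure.add(markers.canonical(name) or name)
    return closure


def find_conv_not_tree(states: StatusTable, markers: MarkerTable,
                       tree: PhyloTree) -> list[MarkerDef]:
    """Mutant-state markers of the conversion table absent from the tree.

    A marker present in the tree under any synonym is not reported (names
    are resolved through the synonym index before comparison). Sorted by
    canonical name.
    """
    in_tree = _tree_marker_closure(tree, markers)
    found = []
    for state in states:
        if state.state != 1:
            continue
        marker = markers.get(state.marker_name)
        if marker is None or marker.name in in_tree:
            continue
        found.append(marker)
    return sorted(found, key=lambda m: m.name)


def find_yupp_snps(profile: SnpProfile, markers: MarkerTable) -> list[YuppSnp]:
    """Called SNPs at positions with no marker on the active build, by position."""
    known = markers.positions(profile.build)
    return [
        YuppSnp(c.position, c.ref_allele, c.obs_allele)
        for c in profile.calls
        if c.position not in known
    ]


def write_reports(result: AssignmentResult, states: StatusTable,
                  conv_not_tree: list[MarkerDef], yupp: list[YuppSnp],
                  out_dir: str | Path) -> dict[str, Path]:
    """Write the four report files into ``out_dir``; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "analysis": out / ANALYSIS_FILE,
        "status": out / STATUS_FILE,
        "conv_not_tree": out / CONV_NOT_TREE_FILE,
        "new_snps": out / NEW_SNPS_FILE,
    }

    q = result.quality
    lines = [
        f"call_quality_score\t{q.score:.4f}",
        f"call_quality_category\t{q.category}",
        f"panel_markers_called\t{q.n_panel_called}",
        f"panel_markers_consistent\t{q.n_consistent}",
        "vertical\t" + ", ".join(sorted(result.vertical)),
        "horizontal\t" + ", ".join(sorted(result.horizontal)),
        "combinatorial\t" + ", ".join(sorted(result.combinatorial)),
        "specific\t" + ", ".join(sorted(result.specific)),
        "final_haplogroup\t" + ", ".join(result.final_alphanumeric),
        "final_haplogroup_mutation_based\t" + ", ".join(result.final_mutation_based),
    ]
    lines += [f"warning\t{w}" for w in result.warnings]
    paths["analysis"].write_text("\n".join(lines) + "\n")

    with open(paths["status"], "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["marker", "state", "provenance", "note"])
        for state in states:  # already sorted by marker name
            writer.writerow([state.marker_name, state.state, state.provenance, state.note])
        for name in sorted(states.excluded_markers):
            writer.writerow([name, "NA", "excluded", states.excluded_markers[name]])

    with open(paths["conv_not_tree"], "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["marker", "synonyms"])
        for marker in conv_not_tree:
            writer.writerow([marker.name, ",".join(marker.synonyms)])

    with open(paths["new_snps"], "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["position", "ref_allele", "obs_allele"])
        for snp in yupp:
            writer.writerow([snp.position, snp.ref_allele, snp.obs_allele])

    logger.info("reports written to %s", out)
    return paths
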