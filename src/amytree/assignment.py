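"""The tree-search algorithm assigning a sample to a (sub-)haplogroup.

Each node of the phylogeny receives a Boolean truth status from the allelic
states of its defining markers, under thresholds gated by the call quality
verdict. Four sub-algorithms then combine into the final call:

* **vertical** — which leaves of the tree are true (cheap, but every false
  positive at a leaf shows up);
* **horizontal** — a root-to-leaf descent through the internal nodes,
  returning the last true internal nodes on each branch;
* **combinatorial** — the vertical leaves that have a horizontal result
  among their ancestors (removes most vertical false positives);
* **specific** — of the survivors, the most specific (deepest) ones.

Final haplogroup names are reported in both nomenclatures: alphanumeric
(e.g. ``R1b1b2a2*``) and mutation-based (e.g. ``R-P312*``).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .call_quality import (
    DEFAULT_QUALITY_THRESHOLD,
    QualityPanel,
    QualityVerdict,
    default_panel,
    evaluate_quality,
)
from .core_model import HaplogroupNode, MarkerTable, PhyloTree, ReferenceSequence, SnpProfile
from .marker_status import DEFAULT_EXCLUSIONS, REFERENCE, StatusTable, build_status_table

logger = logging.getLogger("amytree")

__all__ = [
    "Truth", "AssignParams", "NodeStatus", "AssignmentResult",
    "node_marker_names", "node_truth", "compute_node_statuses",
    "vertical_scan", "horizontal_descend", "combine", "most_specific",
    "to_mutation_nomenclature", "assign",
]


class Truth(enum.Enum):
    TRUE = "true"
    FALSE = "false"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class AssignParams:
    """Thresholds of the node truth test.

    Both thresholds are strict ("more than"): with sufficient calling
    quality a node is true when more than 85% of its usable marker states
    are mutant; with insufficient quality, reference-derived mutant states
    are ignored entirely and more than 5% mutant suffices.
    """

    sufficient_truth_threshold: float = 0.85
    insufficient_truth_threshold: float = 0.05
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
    strand_rescue: bool = True

    def __post_init__(self) -> None:
        for t in (self.sufficient_truth_threshold, self.insufficient_truth_threshold):
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold {t} outside [0, 1]")


@dataclass(frozen=True)
class NodeStatus:
    node: str
    truth: Truth
    pct_mutant: Optional[float]  # None iff indeterminate
    n_used: int


@dataclass
class AssignmentResult:
    quality: QualityVerdict
    vertical: set[str]
    horizontal: set[str]
    combinatorial: set[str]
    specific: set[str]
    final_alphanumeric: list[str]
    final_mutation_based: list[str]
    warnings: list[str] = field(default_factory=list)
    node_statuses: dict[str, NodeStatus] = field(default_factory=dict)


def node_marker_names(node: HaplogroupNode, markers: MarkerTable | None = None) -> list[str]:
    """Canonical names of the markers defining a node.

    A paragroup leaf has no markers of its own and borrows its parent's.
    Names are resolved through the synonym index when a table is given.
    """
    names = node.defining_markers
    if not names and node.is_paragroup and node.parent is not None:
        names = node.parent.defining_markers
    if markers is None:
        return list(names)
    return [markers.canonical(n) or n for n in names]


def node_truth(node: HaplogroupNode, states: StatusTable, sufficient: bool,
               params: AssignParams = AssignParams(),
               markers: MarkerTable | None = None) -> NodeStatus:
    """Truth status of one node from its markers' allelic states.

    Sufficient regime: the denominator is the node's markers with state 0
    or 1 (states of -1 carry no ancestral/mutant information and are left
    out); true iff pct mutant > the 85% threshold. Insufficient regime:
    reference-derived mutant states are removed from numerator and
    denominator, and true iff pct mutant > the 5% threshold. A node with an
    empty denominator (e.g. all its markers are indels) is indeterminate.
    """
    marker_states = [
        s for name in node_marker_names(node, markers)
        if (s := states.get(name)) is not None
    ]
    used = [s for s in marker_states if s.state in (0, 1)]
    if not sufficient:
        used = [s for s in used if not (s.state == 1 and s.provenance == REFERENCE)]
    if not used:
        return NodeStatus(node.name, Truth.INDETERMINATE, None, 0)
    pct = sum(1 for s in used if s.state == 1) / len(used)
    threshold = params.sufficient_truth_threshold if sufficient \
        else params.insufficient_truth_threshold
    truth = Truth.TRUE if pct > threshold else Truth.FALSE
    return NodeStatus(node.name, truth, pct, len(used))


def compute_node_statuses(tree: PhyloTree, states: StatusTable, sufficient: bool,
                          params: AssignParams = AssignParams(),
                          markers: MarkerTable | None = None) -> dict[str, NodeStatus]:
    return {
        node.name: node_truth(node, states, sufficient, params, markers)
        for node in tree.nodes()
    }


def vertical_scan(tree: PhyloTree, statuses: Mapping[str, NodeStatus]) -> set[str]:
    """The true leaves of the tree (indeterminate leaves are not returned)."""
    return {leaf.name for leaf in tree.leaves()
            if statuses[leaf.name].truth is Truth.TRUE}


def horizontal_descend(tree: PhyloTree, statuses: Mapping[str, NodeStatus]) -> set[str]:
    """Root-to-leaf descent through the internal nodes.

    Starting at the root, true internal children are followed; a true
    internal node none of whose internal children leads further contributes
    itself. Indeterminate internal nodes are passed through — the descent
    continues below them but they are never returnable themselves. Leaves
    belong to the vertical method and are not visited. If no internal child
    of the root is true (or reachable through indeterminate nodes), the
    result is empty.
    """

    def descend(node: HaplogroupNode) -> set[str]:
        found: set[str] = set()
        for child in node.children:
            if child.is_leaf:
                continue
            truth = statuses[child.name].truth
            if truth is Truth.TRUE:
                deeper = descend(child)
                found |= deeper if deeper else {child.name}
            elif truth is Truth.INDETERMINATE:
                found |= descend(child)
        return found

    return descend(tree.root)


def combine(vertical: set[str], horizontal: set[str], tree: PhyloTree) -> set[str]:
    """Vertical leaves that have at least one horizontal node as ancestor.

    A horizontal node equal to the leaf itself also counts. Empty horizontal
    input yields an empty result; the fallback for that case lives in
    :func:`assign`.
    """
    return {
        v for v in vertical
        if horizontal & (set(tree.ancestors(v)) | {v})
    }


def most_specific(candidates: set[str], tree: PhyloTree) -> set[str]:
    """Drop every candidate that is an ancestor of another candidate.

    A paragroup (e.g. ``Z2b*``) represents "the parent haplogroup but none
    of its named subclades", so it additionally yields to any candidate
    lying in its parent's subtree (its named siblings and their
    descendants). Incomparable candidates are all retained.
    """
    keep: set[str] = set()
    for name in candidates:
        others = candidates - {name}
        if any(tree.is_ancestor(name, other) for other in others):
            continue
        node = tree[name]
        if node.is_paragroup and node.parent is not None:
            above = set(tree.ancestors(name)) | {name}
            if any(other not in above and tree.in_subtree(node.parent.name, other)
                   for other in others):
                continue
        keep.add(name)
    return keep


def to_mutation_nomenclature(node: HaplogroupNode, markers: MarkerTable) -> str:
    """Mutation-based name: main haplogroup letter + first defining marker.

    ``R1b1b2a2*`` defined by P312 becomes ``R-P312*``; the trailing ``*`` of
    paragroups is preserved (paragroups use their parent's markers). The
    root keeps its own label. A node with no resolvable marker is named
    ``<letter>-?`` (the caller adds a warning).
    """
    if node.parent is None:
        return node.name
    letter = node.name[0]
    names = node_marker_names(node, markers)
    first = names[0] if names else "?"
    star = "*" if node.name.endswith("*") else ""
    return f"{letter}-{first}{star}"


def assign(profile: SnpProfile, tree: PhyloTree, markers: MarkerTable,
           reference: ReferenceSequence,
           panel: QualityPanel | None = None,
           params: AssignParams = AssignParams(),
           quality: QualityVerdict | None = None) -> AssignmentResult:
    """Run the full pipeline: quality gate, node truths, four sub-algorithms.

    When the horizontal method returns nothing (typical for low-coverage
    profiles, where the descent stops at the root), the final result falls
    back to the most specific vertical leaves, with a warning. An
    insufficient quality verdict always adds a caution to the warnings.
    """
    warnings: list[str] = []
    if panel is None:
        panel = default_panel(tree, markers, reference)
    if quality is None:
        quality = evaluate_quality(profile, panel, markers, reference,
                                   threshold=params.quality_threshold)
    if not quality.sufficient:
        warnings.append(
            "Call quality test: insufficient Y-SNP calling quality "
            f"(score {quality.score:.3f}); reference-derived mutant states are "
            "ignored and results must be interpreted with caution."
        )

    states = build_status_table(markers, profile, reference,
                                exclusions=params.exclusions,
                                strand_rescue=params.strand_rescue)
    if states.excluded_markers:
        skipped = sorted(n for n, r in states.excluded_markers.items()
                         if r.startswith("no position"))
        if skipped:
            warnings.append(
                f"markers without a position on build {profile.build} were skipped: "
                + ", ".join(skipped)
            )

    statuses = compute_node_statuses(tree, states, quality.sufficient, params, markers)
    indeterminate = sorted(n for n, s in statuses.items() if s.truth is Truth.INDETERMINATE)
    if indeterminate:
        warnings.append("nodes with indeterminate status (no usable marker states): "
                        + ", ".join(indeterminate))

    vertical = vertical_scan(tree, statuses)
    horizontal = horizontal_descend(tree, statuses)
    combinatorial = combine(vertical, horizontal, tree)
    specific = most_specific(combinatorial, tree)

    if not horizontal and vertical:
        warnings.append(
            "the horizontal algorithm stopped at the root; "
            "only the vertical algorithm revealed results"
        )
        final = most_specific(vertical, tree)
    else:
        final = specific
    if not final:
        warnings.append("no (sub-)haplogroup could be determined")
    if len(final) > 1:
        warnings.append(
            "multiple incompatible (sub-)haplogroups remain: " + ", ".join(sorted(final))
        )

    final_alpha = sorted(final)
    final_mut = []
    for name in final_alpha:
        mut = to_mutation_nomenclature(tree[name], markers)
        if mut.endswith("-?") or mut.endswith("-?*"):
            warnings.append(f"no defining marker resolvable for {name}")
        final_mut.append(mut)

    return AssignmentResult(
        quality=quality,
        vertical=vertical,
        horizontal=horizontal,
        combinatorial=combinatorial,
        specific=specific,
        final_alphanumeric=final_alpha,
        final_mutation_based=final_mut,
        warnings=warnings,
        node_statuses=statuses,
    )
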