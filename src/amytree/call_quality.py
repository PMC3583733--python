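"""Call quality test: is the Y-SNP calling of a profile trustworthy?

The reference Y chromosome is a composite of several sub-haplogroups
(including G and R lineages) while any individual belongs to exactly one,
so a genuine whole-genome calling run always produces calls at a set of
well-known backbone markers — either the sample is derived where the
reference is ancestral, or ancestral where the reference is derived. The
test surveys a panel of such markers: the score is the fraction of panel
markers with an explicit, allele-consistent call, and the verdict gates how
node truth is computed downstream (an insufficient verdict makes the
assignment stop trusting reference-derived mutant states).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .core_model import MarkerTable, PhyloTree, ReferenceSequence, SnpProfile

logger = logging.getLogger("amytree")

__all__ = [
    "SUFFICIENT", "INSUFFICIENT", "DEFAULT_QUALITY_THRESHOLD", "DEFAULT_PANEL_DEPTH",
    "QualityPanel", "QualityVerdict", "default_panel", "read_panel_file", "evaluate_quality",
]

SUFFICIENT = "sufficient"
INSUFFICIENT = "insufficient"

DEFAULT_QUALITY_THRESHOLD = 0.5
DEFAULT_PANEL_DEPTH = 2


@dataclass(frozen=True)
class QualityPanel:
    """Backbone markers surveyed by the quality test.

    ``expected_call_markers`` is the subset whose derived allele is carried
    by the reference itself (composite-reference diagnostics): a sample can
    never be derived for all composite-reference lineages at once, so
    explicit calls at some of these sites are always expected.
    """

    panel_markers: tuple[str, ...]
    expected_call_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not set(self.expected_call_markers) <= set(self.panel_markers):
            raise ValueError("expected_call_markers must be a subset of panel_markers")


@dataclass(frozen=True)
class QualityVerdict:
    score: float
    category: str
    n_panel_called: int
    n_consistent: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def sufficient(self) -> bool:
        return self.category == SUFFICIENT


def default_panel(tree: PhyloTree, markers: MarkerTable,
                  reference: ReferenceSequence | None = None,
                  max_depth: int = DEFAULT_PANEL_DEPTH) -> QualityPanel:
    """Panel = the markers defining nodes at depth <= ``max_depth`` of the tree.

    These are the backbone markers of the major haplogroups. When the
    reference is given, panel markers whose reference base equals the mutant
    allele are flagged as expected-call markers.
    """
    names: list[str] = []
    for node in tree.nodes():
        if node.depth <= max_depth:
            names.extend(node.defining_markers)
    panel = []
    expected = []
    for name in dict.fromkeys(names):  # de-duplicate, keep tree order
        marker = markers.get(name)
        if marker is None or marker.is_indel:
            continue
        panel.append(marker.name)
        if reference is not None:
            pos = marker.position(reference.build)
            if pos is not None and 1 <= pos <= len(reference) \
                    and reference.base(pos) == marker.mutant:
                expected.append(marker.name)
    return QualityPanel(tuple(panel), tuple(expected))


def read_panel_file(path: str | Path) -> tuple[str, ...]:
    """Read a panel file: one marker name per line, ``#`` comments allowed."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return tuple(names)


def evaluate_quality(profile: SnpProfile, panel: QualityPanel, markers: MarkerTable,
                     reference: ReferenceSequence | None = None,
                     threshold: float = DEFAULT_QUALITY_THRESHOLD) -> QualityVerdict:
    """Score the profile's calling quality against the panel.

    score = (number of panel markers with an explicit call whose observed
    allele equals the marker's ancestral or mutant allele) / |panel|.
    Markers contribute only when explicitly called — uncalled sites say
    nothing, and an inconsistent observed allele does not count. The verdict
    is ``sufficient`` iff score >= threshold; it depends on the inputs only
    through the score, so re-runs are bit-identical.
    """
    effective = []
    for name in panel.panel_markers:
        marker = markers.get(name)
        if marker is None or marker.is_indel:
            continue
        if marker.position(profile.build) is None:
            continue
        effective.append(marker)
    if not effective:
        raise ValueError("quality panel is empty after intersection with the marker table")

    n_called = 0
    n_consistent = 0
    for marker in effective:
        call = profile.get(marker.position(profile.build))
        if call is None:
            continue
        n_called += 1
        if call.obs_allele in (marker.ancestral, marker.mutant):
            n_consistent += 1
    score = n_consistent / len(effective)
    category = SUFFICIENT if score >= threshold else INSUFFICIENT
    logger.info("call quality: %d/%d panel markers consistently called, score %.3f -> %s",
                n_consistent, len(effective), score, category)
    return QualityVerdict(score=score, category=category,
                          n_panel_called=n_called, n_consistent=n_consistent)
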