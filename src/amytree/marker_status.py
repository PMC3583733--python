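"""Allelic-state resolution: 0 (ancestral) / 1 (mutant) / -1 (other).

Every known marker receives a state by comparing the sample's call at the
marker's position with the marker's ancestral->mutant conversion; when a
marker is not called, the allelic state of the reference genome is used
instead, and the provenance records which of the two happened. The
reference fallback is what makes low-coverage samples tractable at all; the
quality gate downstream decides how much to trust it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .core_model import MarkerDef, MarkerTable, ReferenceSequence, SnpProfile

logger = logging.getLogger("amytree")

__all__ = [
    "CALLED", "REFERENCE", "DEFAULT_EXCLUSIONS",
    "AlleleState", "StatusTable", "determine_state", "build_status_table",
]

CALLED = "called"
REFERENCE = "reference"

#: Markers excluded from assignment by default: V218 shows a recurrent
#: mutation within haplogroup I (its mutant allele otherwise characterises
#: A2), and MEH2 gives ambiguous results within haplogroup Q.
DEFAULT_EXCLUSIONS = ("V218", "MEH2")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class AlleleState:
    """State of one marker in one sample, with provenance."""

    marker_name: str
    state: int  # 0 ancestral, 1 mutant, -1 other
    provenance: str  # CALLED or REFERENCE
    observed: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.state not in (0, 1, -1):
            raise ValueError(f"state must be 0, 1 or -1, got {self.state}")
        if self.provenance not in (CALLED, REFERENCE):
            raise ValueError(f"unknown provenance {self.provenance!r}")


class StatusTable:
    """One :class:`AlleleState` per eligible marker, plus the exclusions.

    Eligible means: non-indel, not on the exclusion list, and positioned on
    the active build. Excluded markers are kept with the reason so reports
    can show why they are missing.
    """

    def __init__(self, build: str):
        self.build = build
        self._states: dict[str, AlleleState] = {}
        self.excluded_markers: dict[str, str] = {}

    def add(self, state: AlleleState) -> None:
        if state.marker_name in self._states:
            raise ValueError(f"marker {state.marker_name!r} already has a state")
        self._states[state.marker_name] = state

    def exclude(self, marker_name: str, reason: str) -> None:
        self.excluded_markers[marker_name] = reason

    def get(self, marker_name: str) -> Optional[AlleleState]:
        return self._states.get(marker_name)

    @property
    def states(self) -> list[AlleleState]:
        return [self._states[name] for name in sorted(self._states)]

    def __contains__(self, marker_name: str) -> bool:
        return marker_name in self._states

    def __iter__(self) -> Iterator[AlleleState]:
        return iter(self.states)

    def __len__(self) -> int:
        return len(self._states)


def determine_state(marker: MarkerDef, profile: SnpProfile,
                    reference: ReferenceSequence,
                    strand_rescue: bool = True) -> AlleleState:
    """Resolve one marker's allelic state.

    If the profile has a call at the marker's position, the observed allele
    is compared with the ancestral and mutant alleles; otherwise the
    reference base at that position is compared instead (reference
    fallback). With ``strand_rescue`` (default on), an observed allele that
    matches neither is re-tried as its reverse complement before falling
    through to -1; published marker lists mix strand conventions, and a
    rescue is recorded in the note.

    The caller must pre-filter: indel markers and markers without a position
    on the active build are errors here.
    """
    if marker.is_indel:
        raise ValueError(f"{marker.name}: indel markers have no allelic state")
    pos = marker.position(profile.build)
    if pos is None:
        raise ValueError(f"{marker.name}: no position on build {profile.build}")

    call = profile.get(pos)
    if call is not None:
        observed, provenance = call.obs_allele, CALLED
    else:
        observed, provenance = reference.base(pos), REFERENCE

    state, note = _match(observed, marker, strand_rescue)
    return AlleleState(marker.name, state, provenance, observed=observed, note=note)


def _match(observed: str, marker: MarkerDef, strand_rescue: bool) -> tuple[int, str]:
    if observed == marker.mutant:
        return 1, ""
    if observed == marker.ancestral:
        return 0, ""
    if strand_rescue:
        flipped = observed.translate(_COMPLEMENT)
        if flipped == marker.mutant:
            return 1, "complement-strand match"
        if flipped == marker.ancestral:
            return 0, "complement-strand match"
    return -1, f"observed {observed} matches neither {marker.conversion}"


def build_status_table(markers: MarkerTable, profile: SnpProfile,
                       reference: ReferenceSequence,
                       exclusions: Sequence[str] = DEFAULT_EXCLUSIONS,
                       strand_rescue: bool = True) -> StatusTable:
    """State every eligible marker of the table; record why the rest are not.

    Indels, exclusion-listed markers and markers without a position on the
    active build go to ``excluded_markers``. Several markers at the same
    position each get their own state from the same call. The result is
    independent of marker iteration order (states are keyed and emitted by
    name).
    """
    if profile.build != reference.build:
        raise ValueError(
            f"profile build {profile.build} != reference build {reference.build}"
        )
    excluded = set(exclusions)
    table = StatusTable(profile.build)
    for marker in markers:
        if marker.name in excluded:
            table.exclude(marker.name, "on exclusion list")
        elif marker.is_indel:
            table.exclude(marker.name, f"indel conversion {marker.conversion}")
        elif marker.position(profile.build) is None:
            table.exclude(marker.name, f"no position on build {profile.build}")
        else:
            table.add(determine_state(marker, profile, reference, strand_rescue))
    return table
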