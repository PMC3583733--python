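"""Domain types and file I/O for haplogroup assignment.

The four inputs of an analysis are modelled here:

* the marker conversion table (``MarkerTable`` of ``MarkerDef``) listing,
  for every published Y-SNP, its synonyms, rs identifier, positions on the
  hg18 and hg19 builds and its ancestral->mutant allele conversion;
* the haplogroup phylogeny (``PhyloTree`` of ``HaplogroupNode``), a rooted
  tree whose branches carry defining markers;
* the sample's SNP calling profile (``SnpProfile`` of ``SnpCall``);
* the reference Y-chromosome sequence (``ReferenceSequence``).

All three tabular formats are simple tab-separated values so that the output
of any SNP caller (after conversion, see :mod:`amytree.why_convert`) and any
user-curated tree can be used.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger("amytree")

BASES = frozenset("ACGT")
BUILDS = ("hg18", "hg19")

__all__ = [
    "BASES",
    "BUILDS",
    "MarkerDef",
    "MarkerTable",
    "HaplogroupNode",
    "PhyloTree",
    "SnpCall",
    "SnpProfile",
    "ReferenceSequence",
    "read_conversion_file",
    "write_conversion_file",
    "read_tree_file",
    "write_tree_file",
    "read_profile",
    "write_profile",
    "read_reference",
]


def _check_build(build: str) -> str:
    if build not in BUILDS:
        raise ValueError(f"unknown genome build {build!r}; expected one of {BUILDS}")
    return build


# ---------------------------------------------------------------------------
# Marker conversion table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerDef:
    """One named Y-SNP with its mutation conversion.

    The conversion states which allele is ancestral and which is mutant
    (derived), e.g. M173: A->C. Markers whose conversion is not a simple
    single-base substitution (e.g. the 4G->3G indel of M17) are flagged
    ``is_indel`` and excluded from assignment downstream.
    """

    name: str
    synonyms: tuple[str, ...] = ()
    rs_id: Optional[str] = None
    pos_hg18: Optional[int] = None
    pos_hg19: Optional[int] = None
    ancestral: str = "A"
    mutant: str = "C"

    def __post_init__(self) -> None:
        if self.ancestral == self.mutant:
            raise ValueError(f"{self.name}: ancestral and mutant alleles are equal")
        if self.name in self.synonyms:
            raise ValueError(f"{self.name}: marker listed among its own synonyms")

    @property
    def is_indel(self) -> bool:
        return not (
            len(self.ancestral) == 1
            and len(self.mutant) == 1
            and self.ancestral in BASES
            and self.mutant in BASES
        )

    def position(self, build: str) -> Optional[int]:
        _check_build(build)
        return self.pos_hg18 if build == "hg18" else self.pos_hg19

    @property
    def conversion(self) -> str:
        return f"{self.ancestral}->{self.mutant}"


class MarkerTable:
    """Collection of :class:`MarkerDef`, indexed by name/synonym and position.

    Lookup by any synonym resolves to the same definition as lookup by the
    canonical name. Several markers may share a genomic position (co-located
    markers are reported, never fatal).
    """

    def __init__(self, markers: Iterable[MarkerDef] = ()):
        self._markers: list[MarkerDef] = []
        self._by_name: dict[str, MarkerDef] = {}
        self._by_pos: dict[tuple[str, int], list[MarkerDef]] = {}
        for m in markers:
            self.add(m)

    def add(self, marker: MarkerDef) -> None:
        existing = self._by_name.get(marker.name)
        if existing is not None and existing.name == marker.name:
            raise ValueError(f"duplicate marker name {marker.name!r}")
        self._markers.append(marker)
        self._by_name[marker.name] = marker
        for syn in marker.synonyms:
            if syn in self._by_name:
                logger.warning(
                    "synonym %s of %s collides with an existing name; keeping the first",
                    syn, marker.name,
                )
                continue
            self._by_name[syn] = marker
        for build in BUILDS:
            pos = marker.position(build)
            if pos is not None:
                self._by_pos.setdefault((build, pos), []).append(marker)

    def get(self, name: str) -> Optional[MarkerDef]:
        return self._by_name.get(name)

    def canonical(self, name: str) -> Optional[str]:
        m = self._by_name.get(name)
        return None if m is None else m.name

    def markers_at(self, build: str, position: int) -> list[MarkerDef]:
        return list(self._by_pos.get((_check_build(build), position), ()))

    def positions(self, build: str) -> set[int]:
        return {pos for (b, pos) in self._by_pos if b == build}

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[MarkerDef]:
        return iter(self._markers)

    def __len__(self) -> int:
        return len(self._markers)


def read_conversion_file(path: str | Path) -> MarkerTable:
    """Read a marker conversion table.

    TSV with a header row and six columns: ``name``, ``synonyms``
    (comma-separated, may be empty), ``rs_id``, ``pos_hg18``, ``pos_hg19``,
    ``conversion`` (exact form ``<anc>-><mut>``). Extra trailing columns are
    ignored. Rows whose conversion string is malformed are rejected with a
    logged warning; a duplicate canonical name is an error.
    """
    table = MarkerTable()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return table
        _require_columns(header, ["name", "synonyms", "rs_id", "pos_hg18", "pos_hg19", "conversion"], path)
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            row = row + [""] * (6 - len(row))
            name, syns, rs_id, p18, p19, conv = (c.strip() for c in row[:6])
            if "->" not in conv:
                logger.warning("%s:%d: malformed conversion %r for %s; row rejected", path, lineno, conv, name)
                continue
            anc, _, mut = conv.partition("->")
            try:
                marker = MarkerDef(
                    name=name,
                    synonyms=tuple(s.strip() for s in syns.split(",") if s.strip()),
                    rs_id=rs_id or None,
                    pos_hg18=int(p18) if p18 else None,
                    pos_hg19=int(p19) if p19 else None,
                    ancestral=anc,
                    mutant=mut,
                )
            except ValueError as exc:
                logger.warning("%s:%d: %s; row rejected", path, lineno, exc)
                continue
            table.add(marker)
    return table


def write_conversion_file(table: MarkerTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "synonyms", "rs_id", "pos_hg18", "pos_hg19", "conversion"])
        for m in table:
            writer.writerow([
                m.name,
                ",".join(m.synonyms),
                m.rs_id or "",
                m.pos_hg18 if m.pos_hg18 is not None else "",
                m.pos_hg19 if m.pos_hg19 is not None else "",
                m.conversion,
            ])


def _require_columns(header: Sequence[str], expected: Sequence[str], path) -> None:
    got = [h.strip() for h in header[: len(expected)]]
    if got != list(expected):
        raise ValueError(
            f"{path}: unexpected column layout {got!r}; expected {list(expected)!r}"
        )


# ---------------------------------------------------------------------------
# Haplogroup phylogeny
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class HaplogroupNode:
    """A (sub-)haplogroup in the phylogeny.

    ``defining_markers`` are the Y-SNPs on the branch leading to this node.
    A name ending in ``*`` denotes a paragroup: chromosomes belonging to the
    parent haplogroup but to none of its named subclades. Paragroups are
    always leaves and carry no markers of their own.
    """

    name: str
    parent: Optional["HaplogroupNode"] = field(default=None, repr=False)
    children: list["HaplogroupNode"] = field(default_factory=list, repr=False)
    defining_markers: tuple[str, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_paragroup(self) -> bool:
        return self.name.endswith("*")

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def __repr__(self) -> str:  # keep recursion out of reprs
        return f"HaplogroupNode({self.name!r})"


class PhyloTree:
    """Rooted haplogroup hierarchy with name-indexed nodes."""

    def __init__(self, root: HaplogroupNode):
        self.root = root
        self._nodes: dict[str, HaplogroupNode] = {}
        for node in self._walk(root):
            if node.name in self._nodes:
                raise ValueError(f"duplicate haplogroup name {node.name!r}")
            self._nodes[node.name] = node
        for node in self._nodes.values():
            if node.is_paragroup and not node.is_leaf:
                raise ValueError(f"paragroup {node.name!r} must be a leaf")

    @staticmethod
    def _walk(node: HaplogroupNode) -> Iterator[HaplogroupNode]:
        stack = [node]
        seen: set[int] = set()
        while stack:
            n = stack.pop()
            if id(n) in seen:
                raise ValueError(f"cycle detected at haplogroup {n.name!r}")
            seen.add(id(n))
            yield n
            stack.extend(reversed(n.children))

    def __getitem__(self, name: str) -> HaplogroupNode:
        try:
            return self._nodes[name]
        except KeyError:
            raise KeyError(f"unknown haplogroup {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def nodes(self) -> Iterator[HaplogroupNode]:
        """Pre-order traversal from the root (file order of children)."""
        return self._walk(self.root)

    def leaves(self) -> list[HaplogroupNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def ancestors(self, name: str) -> list[str]:
        """Names on the path from the root to the node's parent (root first)."""
        node = self[name]
        path: list[str] = []
        while node.parent is not None:
            node = node.parent
            path.append(node.name)
        return path[::-1]

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        return ancestor in self.ancestors(descendant)

    def in_subtree(self, top: str, name: str) -> bool:
        """True iff *name* equals *top* or lies below it."""
        return name == top or self.is_ancestor(top, name)


def read_tree_file(path: str | Path) -> PhyloTree:
    """Read a phylogenetic tree table.

    TSV with a header row and three columns: ``haplogroup``, ``parent``
    (empty for the root), ``defining_markers`` (comma-separated). Parent rows
    may appear after child rows. Children keep file order. Two roots, an
    orphan parent reference, a cycle or a duplicate haplogroup name are
    errors naming the offending row.
    """
    rows: list[tuple[int, str, str, tuple[str, ...]]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty tree file")
        _require_columns(header, ["haplogroup", "parent", "defining_markers"], path)
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            row = row + [""] * (3 - len(row))
            name, parent, markers = (c.strip() for c in row[:3])
            rows.append((lineno, name, parent, tuple(m.strip() for m in markers.split(",") if m.strip())))

    nodes: dict[str, HaplogroupNode] = {}
    for lineno, name, _, markers in rows:
        if name in nodes:
            raise ValueError(f"{path}:{lineno}: duplicate haplogroup {name!r}")
        nodes[name] = HaplogroupNode(name=name, defining_markers=markers)

    root: Optional[HaplogroupNode] = None
    for lineno, name, parent, _ in rows:
        node = nodes[name]
        if not parent:
            if root is not None:
                raise ValueError(f"{path}:{lineno}: second root {name!r} (root already {root.name!r})")
            root = node
            continue
        if parent not in nodes:
            raise ValueError(f"{path}:{lineno}: parent {parent!r} of {name!r} not defined in file")
        node.parent = nodes[parent]
        nodes[parent].children.append(node)
    if root is None:
        raise ValueError(f"{path}: no root row (empty parent column) found")

    tree = PhyloTree(root)
    unreachable = set(nodes) - {n.name for n in tree.nodes()}
    if unreachable:
        raise ValueError(f"{path}: haplogroups not reachable from root (cycle or disconnected): {sorted(unreachable)}")
    return tree


def write_tree_file(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["haplogroup", "parent", "defining_markers"])
        for node in tree.nodes():
            writer.writerow([
                node.name,
                node.parent.name if node.parent is not None else "",
                ",".join(node.defining_markers),
            ])


# ---------------------------------------------------------------------------
# SNP calling profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpCall:
    """One called Y-chromosome SNP: 1-based position, reference and observed allele."""

    position: int
    ref_allele: str
    obs_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for allele in (self.ref_allele, self.obs_allele):
            if allele not in BASES:
                raise ValueError(f"allele {allele!r} is not a single base in ACGT")


class SnpProfile:
    """The sample's called Y-chromosome SNPs, unique by position."""

    def __init__(self, build: str, calls: Iterable[SnpCall] = (), sample_id: str = "sample",
                 n_skipped_non_snp: int = 0):
        self.build = _check_build(build)
        self.sample_id = sample_id
        self.n_skipped_non_snp = n_skipped_non_snp
        self._calls: dict[int, SnpCall] = {}
        for call in calls:
            self.add(call)

    def add(self, call: SnpCall) -> None:
        if call.position in self._calls:
            logger.warning(
                "%s: duplicate call at position %d; keeping the first (%s), dropping %s",
                self.sample_id, call.position,
                self._calls[call.position].obs_allele, call.obs_allele,
            )
            return
        self._calls[call.position] = call

    def get(self, position: int) -> Optional[SnpCall]:
        return self._calls.get(position)

    @property
    def calls(self) -> list[SnpCall]:
        return [self._calls[p] for p in sorted(self._calls)]

    @property
    def positions(self) -> set[int]:
        return set(self._calls)

    def __contains__(self, position: int) -> bool:
        return position in self._calls

    def __len__(self) -> int:
        return len(self._calls)


def read_profile(path: str | Path, build: str, sample_id: Optional[str] = None) -> SnpProfile:
    """Read a SNP calling profile: headerless TSV ``position / ref / obs``.

    Rows that are not single-base substitutions (indels, multi-base alleles)
    are skipped and counted in ``n_skipped_non_snp``; rows with an
    unparseable position are rejected with a warning. Duplicate positions
    keep the first occurrence.
    """
    profile = SnpProfile(build, sample_id=sample_id or Path(path).stem)
    skipped = 0
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 3:
                logger.warning("%s:%d: expected 3 columns, got %d; row rejected", path, lineno, len(row))
                continue
            pos_s, ref, obs = (c.strip() for c in row[:3])
            try:
                pos = int(pos_s)
            except ValueError:
                logger.warning("%s:%d: unparseable position %r; row rejected", path, lineno, pos_s)
                continue
            ref, obs = ref.upper(), obs.upper()
            if not (len(ref) == 1 and len(obs) == 1 and ref in BASES and obs in BASES):
                skipped += 1
                continue
            profile.add(SnpCall(pos, ref, obs))
    profile.n_skipped_non_snp = skipped
    if skipped:
        logger.info("%s: skipped %d non-SNP rows", path, skipped)
    return profile


def write_profile(profile: SnpProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for call in profile.calls:
            writer.writerow([call.position, call.ref_allele, call.obs_allele])


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------

class ReferenceSequence:
    """Random-access Y-chromosome reference with 1-based addressing."""

    def __init__(self, build: str, sequence: str, name: str = "chrY"):
        self.build = _check_build(build)
        self.sequence = sequence.upper()
        self.name = name

    def base(self, position: int) -> str:
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside reference of length {len(self.sequence)}")
        return self.sequence[position - 1]

    def __len__(self) -> int:
        return len(self.sequence)


def read_reference(path: str | Path, build: str) -> ReferenceSequence:
    """Load the Y-chromosome record from a FASTA file.

    The first record whose identifier contains "Y" (case-insensitive, so both
    ``Y`` and ``chrY`` are accepted) is used.
    """
    for record in SeqIO.parse(str(path), "fasta"):
        if "Y" in record.id.upper():
            return ReferenceSequence(build, str(record.seq), name=record.id)
    raise ValueError(f"{path}: no Y-chromosome record found in FASTA")
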