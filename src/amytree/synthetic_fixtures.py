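"""Synthetic fixtures with known ground truth, and brute-force oracles.

The generator emulates the structure of the real inputs: a rooted
haplogroup tree with unique markers on every branch, a composite reference
sequence that carries the derived alleles of one or more chosen lineages
(the real hg18/hg19 Y reference is a mosaic of several sub-haplogroups,
including G and R lineages), and call profiles with tunable false-positive
and false-negative rates. Because the generator knows every marker's true
state for every leaf, recovery of the simulated lineage can be checked
exactly.

The module also provides brute-force counterparts of the four search
sub-algorithms and an exhaustive leaf-scoring oracle, written independently
of the tree-traversal code they verify, plus the packaged illustrative
fixture (haplogroups X, Y and Z, sample from Z2b3a).

All randomness flows through one named PRNG (numpy PCG64 via
``default_rng``) with an explicit seed in every API; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core_model import (
    HaplogroupNode,
    MarkerDef,
    MarkerTable,
    PhyloTree,
    ReferenceSequence,
    SnpCall,
    SnpProfile,
    read_conversion_file,
    read_profile,
    read_reference,
    read_tree_file,
    write_conversion_file,
    write_profile,
    write_tree_file,
)
from .assignment import NodeStatus, Truth

__all__ = [
    "SimSpec", "Fixture", "make_fixture", "simulate_profile", "oracle_assign",
    "random_tree", "random_statuses",
    "brute_vertical", "brute_horizontal", "brute_combine", "brute_specific",
    "walkthrough_fixture", "write_fixture",
]

_BASES = "ACGT"
_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic fixture.

    ``reference_lineages`` may be explicit leaf names or an integer k, in
    which case k leaves spread evenly across the tree are chosen (one per
    major clade when k divides the leaf count) — mirroring how the real
    reference mixes a handful of distinct lineages.
    """

    n_levels: int = 5
    branching: int | tuple[int, ...] = 2
    markers_per_branch: int = 2
    reference_lineages: int | tuple[str, ...] = 4
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.fp_rate, self.fn_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.markers_per_branch < 1:
            raise ValueError("markers_per_branch must be >= 1")

    def branching_at(self, level: int) -> int:
        if isinstance(self.branching, tuple):
            return self.branching[level]
        return self.branching


@dataclass
class Fixture:
    """A generated tree + markers + composite reference + ground truth."""

    spec: SimSpec
    tree: PhyloTree
    markers: MarkerTable
    reference: ReferenceSequence
    reference_lineages: tuple[str, ...]
    #: leaf name -> set of canonical marker names derived in that leaf
    ground_truth: dict[str, frozenset[str]]

    def leaf_allele(self, leaf: str, marker: MarkerDef) -> str:
        return marker.mutant if marker.name in self.ground_truth[leaf] else marker.ancestral


def _haplogroup_name(parent: HaplogroupNode, index: int, level: int) -> str:
    if level == 1:
        return chr(ord("A") + index)
    # real nomenclature alternates digits and letters below the main letter
    suffix = str(index + 1) if level % 2 == 0 else _LETTERS[index]
    return parent.name + suffix


def make_fixture(spec: SimSpec, build: str = "hg19") -> Fixture:
    """Build a fixture, fully determined by the simulation seed.

    Every branch gets ``markers_per_branch`` markers at distinct positions
    drawn without replacement from 1..10*n_markers (the slack leaves room to
    plant novel SNPs at non-marker positions). The reference base equals the
    mutant allele exactly on branches ancestral to (or part of) the
    reference lineages, and the ancestral allele elsewhere.
    """
    rng = np.random.default_rng(spec.seed)

    root = HaplogroupNode(name="ROOT")
    frontier = [root]
    branches: list[HaplogroupNode] = []
    for level in range(1, spec.n_levels + 1):
        nxt: list[HaplogroupNode] = []
        for parent in frontier:
            for i in range(spec.branching_at(level - 1)):
                child = HaplogroupNode(name=_haplogroup_name(parent, i, level), parent=parent)
                parent.children.append(child)
                branches.append(child)
                nxt.append(child)
        frontier = nxt
    tree = PhyloTree(root)

    n_markers = len(branches) * spec.markers_per_branch
    genome_len = 10 * n_markers
    positions = rng.choice(genome_len, size=n_markers, replace=False) + 1

    leaves = [n.name for n in tree.leaves()]
    if isinstance(spec.reference_lineages, int):
        k = spec.reference_lineages
        ref_lineages = tuple(leaves[i * len(leaves) // k] for i in range(k))
    else:
        ref_lineages = tuple(spec.reference_lineages)
        unknown = [l for l in ref_lineages if l not in set(leaves)]
        if unknown:
            raise ValueError(f"reference lineages are not leaves: {unknown}")
    ref_path_nodes: set[str] = set()
    for leaf in ref_lineages:
        ref_path_nodes.update(tree.ancestors(leaf))
        ref_path_nodes.add(leaf)

    seq = rng.choice(list(_BASES), size=genome_len)
    table = MarkerTable()
    midx = 0
    for node in branches:  # deterministic order: level by level, file order
        names = []
        for _ in range(spec.markers_per_branch):
            midx += 1
            pos = int(positions[midx - 1])
            anc, mut = rng.choice(list(_BASES), size=2, replace=False)
            marker = MarkerDef(
                name=f"S{midx}", pos_hg18=pos, pos_hg19=pos,
                ancestral=str(anc), mutant=str(mut),
            )
            table.add(marker)
            names.append(marker.name)
            seq[pos - 1] = marker.mutant if node.name in ref_path_nodes else marker.ancestral
        node.defining_markers = tuple(names)

    reference = ReferenceSequence(build, "".join(seq), name="chrY_synthetic")

    ground_truth: dict[str, frozenset[str]] = {}
    for leaf in leaves:
        path = tree.ancestors(leaf)[1:] + [leaf]  # skip root, include leaf
        derived: set[str] = set()
        for name in path:
            derived.update(tree[name].defining_markers)
        ground_truth[leaf] = frozenset(derived)

    return Fixture(spec=spec, tree=tree, markers=table, reference=reference,
                   reference_lineages=ref_lineages, ground_truth=ground_truth)


def simulate_profile(fixture: Fixture, leaf: str,
                     fp_rate: Optional[float] = None,
                     fn_rate: Optional[float] = None,
                     seed: Optional[int] = None) -> SnpProfile:
    """Error-injected call profile for an individual from the given leaf.

    True calls are the positions where the leaf's allele differs from the
    composite reference (derived markers the reference lacks, and ancestral
    alleles where the reference is derived). Each true call is dropped with
    probability ``fn_rate``; each remaining site — markers where leaf and
    reference agree, and non-marker positions — yields a spurious call with
    probability ``fp_rate`` (a random wrong base).
    """
    if leaf not in fixture.ground_truth:
        raise KeyError(f"unknown leaf {leaf!r}")
    fp = fixture.spec.fp_rate if fp_rate is None else fp_rate
    fn = fixture.spec.fn_rate if fn_rate is None else fn_rate
    rng = np.random.default_rng(fixture.spec.seed + 1 if seed is None else seed)
    build = fixture.reference.build

    true_calls: list[SnpCall] = []
    marker_positions: set[int] = set()
    agreeing_markers: list[MarkerDef] = []
    for marker in fixture.markers:
        pos = marker.position(build)
        marker_positions.add(pos)
        allele = fixture.leaf_allele(leaf, marker)
        ref = fixture.reference.base(pos)
        if allele != ref:
            true_calls.append(SnpCall(pos, ref, allele))
        else:
            agreeing_markers.append(marker)
    true_calls.sort(key=lambda c: c.position)

    profile = SnpProfile(build, sample_id=f"sim_{leaf}")
    keep = rng.random(len(true_calls)) >= fn
    for call, kept in zip(true_calls, keep):
        if kept:
            profile.add(call)

    if fp > 0:
        hit = rng.random(len(agreeing_markers)) < fp
        for marker, h in zip(agreeing_markers, hit):
            if not h:
                continue
            pos = marker.position(build)
            ref = fixture.reference.base(pos)
            allele = fixture.leaf_allele(leaf, marker)
            wrong = marker.mutant if allele == marker.ancestral else marker.ancestral
            profile.add(SnpCall(pos, ref, wrong))
        non_marker = np.array(sorted(set(range(1, len(fixture.reference) + 1)) - marker_positions))
        hit = rng.random(len(non_marker)) < fp
        for pos in non_marker[hit]:
            ref = fixture.reference.base(int(pos))
            wrong = str(rng.choice([b for b in _BASES if b != ref]))
            profile.add(SnpCall(int(pos), ref, wrong))
    return profile


def oracle_assign(profile: SnpProfile, fixture: Fixture) -> set[str]:
    """Exhaustive leaf scoring, independent of the tree search.

    Every leaf is scored by the fraction of the markers on its root-to-leaf
    path that are in the derived state (state resolved exactly as in the
    status stage: explicit call first, reference base otherwise); the
    arg-max set is returned.
    """
    build = profile.build
    scores: dict[str, float] = {}
    for leaf, derived in fixture.ground_truth.items():
        path_markers = [fixture.markers.get(n) for n in sorted(derived)]
        n_mut = 0
        for marker in path_markers:
            pos = marker.position(build)
            call = profile.get(pos)
            obs = call.obs_allele if call is not None else fixture.reference.base(pos)
            if obs == marker.mutant:
                n_mut += 1
        scores[leaf] = n_mut / len(path_markers) if path_markers else 0.0
    best = max(scores.values())
    return {leaf for leaf, s in scores.items() if s == best}


# ---------------------------------------------------------------------------
# Random trees and brute-force sub-algorithm oracles
# ---------------------------------------------------------------------------

def random_tree(rng: np.random.Generator, max_levels: int = 6,
                max_leaves: int = 64, paragroup_prob: float = 0.2) -> PhyloTree:
    """A random rooted topology for traversal testing.

    Internal nodes may receive a paragroup leaf child (named with a
    trailing ``*``). The leaf budget caps growth; node count and shape vary
    with the generator state.
    """
    counter = 0

    def grow(parent: HaplogroupNode, level: int, leaf_budget: list[int]) -> None:
        nonlocal counter
        n_children = int(rng.integers(0, 4)) if level < max_levels else 0
        made_internal = False
        for _ in range(n_children):
            if leaf_budget[0] <= 1:
                break
            counter += 1
            child = HaplogroupNode(name=f"N{counter}", parent=parent)
            parent.children.append(child)
            made_internal = True
            leaf_budget[0] -= 1
            grow(child, level + 1, leaf_budget)
        if made_internal and rng.random() < paragroup_prob and leaf_budget[0] > 0:
            star = HaplogroupNode(name=parent.name + "*", parent=parent)
            parent.children.append(star)
            leaf_budget[0] -= 1

    root = HaplogroupNode(name="N0")
    counter = 0
    budget = [max_leaves]
    grow(root, 1, budget)
    if not root.children:  # guarantee a non-trivial tree
        for i in range(2):
            counter += 1
            root.children.append(HaplogroupNode(name=f"N{counter}", parent=root))
    return PhyloTree(root)


def random_statuses(rng: np.random.Generator, tree: PhyloTree,
                    p_true: float = 0.45, p_indeterminate: float = 0.1
                    ) -> dict[str, NodeStatus]:
    """Uniform random truth assignment over all nodes (root included)."""
    statuses = {}
    for node in tree.nodes():
        u = rng.random()
        if u < p_true:
            truth, pct = Truth.TRUE, 1.0
        elif u < p_true + p_indeterminate:
            truth, pct = Truth.INDETERMINATE, None
        else:
            truth, pct = Truth.FALSE, 0.0
        statuses[node.name] = NodeStatus(node.name, truth, pct, 0 if pct is None else 1)
    return statuses


def brute_vertical(tree: PhyloTree, statuses: Mapping[str, NodeStatus]) -> set[str]:
    return {n.name for n in tree.nodes()
            if n.is_leaf and statuses[n.name].truth is Truth.TRUE}


def _passable(name: str, statuses: Mapping[str, NodeStatus]) -> bool:
    return statuses[name].truth in (Truth.TRUE, Truth.INDETERMINATE)


def brute_horizontal(tree: PhyloTree, statuses: Mapping[str, NodeStatus]) -> set[str]:
    """Deepest true internal nodes reachable from the root.

    A true internal node qualifies when every strict ancestor below the root
    is true or indeterminate, and no true internal descendant is reachable
    from it through true-or-indeterminate intermediate nodes.
    """
    internal_true = [
        n.name for n in tree.nodes()
        if not n.is_leaf and n.parent is not None and statuses[n.name].truth is Truth.TRUE
    ]
    result = set()
    for name in internal_true:
        ancestors = tree.ancestors(name)
        if not all(_passable(a, statuses) for a in ancestors[1:]):  # skip root
            continue
        blocked = False
        for other in internal_true:
            if other == name or not tree.is_ancestor(name, other):
                continue
            between = tree.ancestors(other)
            between = between[between.index(name) + 1:]
            if all(_passable(b, statuses) for b in between):
                blocked = True
                break
        if not blocked:
            result.add(name)
    return result


def brute_combine(vertical: set[str], horizontal: set[str], tree: PhyloTree) -> set[str]:
    kept = set()
    for v in vertical:
        for h in horizontal:
            if h == v or tree.is_ancestor(h, v):
                kept.add(v)
                break
    return kept


def brute_specific(candidates: set[str], tree: PhyloTree) -> set[str]:
    """Pairwise ancestor-matrix evaluation of the most-specific rule."""
    names = sorted(candidates)
    anc = {a: set(tree.ancestors(a)) for a in names}
    dropped = set()
    for a in names:
        node = tree[a]
        for b in names:
            if a == b:
                continue
            if a in anc[b]:
                dropped.add(a)
            elif node.is_paragroup and node.parent is not None \
                    and b not in anc[a] \
                    and (b == node.parent.name or node.parent.name in anc[b]):
                dropped.add(a)
    return set(names) - dropped


# ---------------------------------------------------------------------------
# Packaged illustrative fixture (haplogroups X, Y, Z; sample from Z2b3a)
# ---------------------------------------------------------------------------

@dataclass
class PackagedFixture:
    tree: PhyloTree
    markers: MarkerTable
    reference: ReferenceSequence
    profile: SnpProfile
    paths: dict[str, Path]


def walkthrough_fixture() -> PackagedFixture:
    """Load the packaged fictive fixture.

    A fictive individual belonging to sub-haplogroup Z2b3a on a fictive tree
    with haplogroups X, Y and Z; the reference carries the derived alleles
    of the X and Y backbone markers (composite-reference effect), so the
    packaged profile contains ancestral-allele calls there. Running the
    full pipeline yields vertical {X1a, Z2b*, Z2b3a}, horizontal {Z2b},
    combinatorial {Z2b*, Z2b3a}, final {Z2b3a}.
    """
    data = resources.files("amytree") / "data"
    paths = {
        "tree": Path(str(data / "walkthrough_tree.tsv")),
        "conversion": Path(str(data / "walkthrough_conversion.tsv")),
        "reference": Path(str(data / "walkthrough_reference.fa")),
        "profile": Path(str(data / "walkthrough_profile.tsv")),
    }
    return PackagedFixture(
        tree=read_tree_file(paths["tree"]),
        markers=read_conversion_file(paths["conversion"]),
        reference=read_reference(paths["reference"], "hg19"),
        profile=read_profile(paths["profile"], "hg19", sample_id="fictive_Z2b3a"),
        paths=paths,
    )


def write_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Dump a generated fixture to the standard file formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.tsv",
        "conversion": out / "conversion.tsv",
        "reference": out / "reference.fa",
    }
    write_tree_file(fixture.tree, paths["tree"])
    write_conversion_file(fixture.markers, paths["conversion"])
    seq = fixture.reference.sequence
    with open(paths["reference"], "w") as fh:
        fh.write(f">{fixture.reference.name}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")
    return paths
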