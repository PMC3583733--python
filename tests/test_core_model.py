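"""Domain types, TSV readers/writers and tree queries."""

import numpy as np
import pytest

from amytree.core_model import (
    MarkerDef,
    MarkerTable,
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
from amytree.synthetic_fixtures import random_tree


class TestMarkerTable:
    def test_row_parsing_with_synonyms_and_positions(self, tmp_path):
        path = tmp_path / "conv.tsv"
        path.write_text(
            "name\tsynonyms\trs_id\tpos_hg18\tpos_hg19\tconversion\n"
            "M173\tP241,Page29\trs2032624\t14017305\t15026424\tA->C\n"
        )
        table = read_conversion_file(path)
        m = table.get("M173")
        assert m.synonyms == ("P241", "Page29")
        assert m.ancestral == "A" and m.mutant == "C"
        assert not m.is_indel
        assert m.position("hg18") == 14017305 and m.position("hg19") == 15026424

    def test_synonym_lookup_resolves_to_canonical(self, walkthrough):
        for syn in ("P911", "Page11"):
            assert walkthrough.markers.get(syn) is walkthrough.markers.get("M111")
        assert walkthrough.markers.canonical("PL9") == "L999"

    def test_empty_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "conv.tsv"
        path.write_text("name\tsynonyms\trs_id\tpos_hg18\tpos_hg19\tconversion\n")
        assert len(read_conversion_file(path)) == 0

    def test_indel_conversion_flagged(self, walkthrough):
        m17 = walkthrough.markers.get("M17")
        assert m17.is_indel
        assert m17.conversion == "4G->3G"

    def test_malformed_conversion_rejected_not_fatal(self, tmp_path, caplog):
        path = tmp_path / "conv.tsv"
        path.write_text(
            "name\tsynonyms\trs_id\tpos_hg18\tpos_hg19\tconversion\n"
            "BAD\t\t\t1\t1\tAC\n"
            "OK\t\t\t2\t2\tA->G\n"
        )
        table = read_conversion_file(path)
        assert table.get("BAD") is None and table.get("OK") is not None

    def test_duplicate_canonical_name_is_error(self, tmp_path):
        path = tmp_path / "conv.tsv"
        path.write_text(
            "name\tsynonyms\trs_id\tpos_hg18\tpos_hg19\tconversion\n"
            "M1\t\t\t1\t1\tA->G\nM1\t\t\t2\t2\tC->T\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_conversion_file(path)

    def test_colocated_markers_both_reported(self):
        table = MarkerTable([
            MarkerDef(name="M1", pos_hg19=5, ancestral="A", mutant="G"),
            MarkerDef(name="M2", pos_hg19=5, ancestral="A", mutant="T"),
        ])
        assert {m.name for m in table.markers_at("hg19", 5)} == {"M1", "M2"}

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            MarkerDef(name="M1", ancestral="A", mutant="A")
        with pytest.raises(ValueError):
            MarkerDef(name="M1", synonyms=("M1",), ancestral="A", mutant="C")

    def test_round_trip(self, walkthrough, tmp_path):
        out = tmp_path / "conv.tsv"
        write_conversion_file(walkthrough.markers, out)
        again = read_conversion_file(out)
        assert len(again) == len(walkthrough.markers)
        for m in walkthrough.markers:
            assert again.get(m.name) == m


class TestPhyloTree:
    def test_three_row_tree(self, tmp_path):
        path = tmp_path / "tree.tsv"
        path.write_text("haplogroup\tparent\tdefining_markers\nZ\t\tM1\nZ1\tZ\tM2\nZ2\tZ\tM3\n")
        tree = read_tree_file(path)
        assert tree.root.name == "Z"
        assert [c.name for c in tree.root.children] == ["Z1", "Z2"]

    def test_packaged_fixture_topology(self, walkthrough):
        tree = walkthrough.tree
        leaf_names = {n.name for n in tree.leaves()}
        assert {"X1a", "Z1", "Z2b*", "Z2b3a"} <= leaf_names
        assert not tree["Z2b"].is_leaf
        assert tree["Z2b*"].is_paragroup

    def test_orphan_parent_named_in_error(self, tmp_path):
        path = tmp_path / "tree.tsv"
        path.write_text("haplogroup\tparent\tdefining_markers\nA\t\tM1\nB\tQ9\tM2\n")
        with pytest.raises(ValueError, match="Q9"):
            read_tree_file(path)

    @pytest.mark.parametrize("body,match", [
        ("A\t\tM1\nB\t\tM2\n", "root"),                 # two roots
        ("A\t\tM1\nB\tA\tM2\nB\tA\tM3\n", "duplicate"),  # duplicate name
        ("A\tB\tM1\nB\tA\tM2\n", "root"),                # cycle, no root
    ])
    def test_bad_files_rejected(self, tmp_path, body, match):
        path = tmp_path / "tree.tsv"
        path.write_text("haplogroup\tparent\tdefining_markers\n" + body)
        with pytest.raises(ValueError, match=match):
            read_tree_file(path)

    def test_ancestors_walk(self, walkthrough):
        assert walkthrough.tree.ancestors("Z2b3a") == ["Root", "Z", "Z2", "Z2b"]
        assert walkthrough.tree.ancestors("Root") == []
        with pytest.raises(KeyError):
            walkthrough.tree.ancestors("Q9")

    @pytest.mark.parametrize("seed", range(5))
    def test_ancestor_properties_on_random_trees(self, seed):
        tree = random_tree(np.random.default_rng(seed))
        nodes = list(tree.nodes())
        assert len(nodes) == 1 + sum(len(n.children) for n in nodes)
        depth = {n.name: n.depth for n in nodes}
        for n in nodes:
            anc = tree.ancestors(n.name)
            assert n.name not in anc
            for a in anc:
                assert depth[a] < depth[n.name]
                assert n.name not in tree.ancestors(a)

    def test_round_trip(self, walkthrough, tmp_path):
        out = tmp_path / "tree.tsv"
        write_tree_file(walkthrough.tree, out)
        again = read_tree_file(out)
        assert {n.name for n in again.nodes()} == {n.name for n in walkthrough.tree.nodes()}
        for node in walkthrough.tree.nodes():
            assert again[node.name].defining_markers == node.defining_markers
            assert again.ancestors(node.name) == walkthrough.tree.ancestors(node.name)


class TestProfile:
    def test_two_valid_rows(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("100\tA\tC\n200\tG\tT\n")
        profile = read_profile(path, "hg19")
        assert len(profile) == 2
        assert profile.get(100) == SnpCall(100, "A", "C")

    def test_multibase_rows_skipped_and_counted(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("100\tA\tC\n200\tG\tAT\n")
        profile = read_profile(path, "hg19")
        assert len(profile) == 1
        assert profile.n_skipped_non_snp == 1

    def test_unparseable_position_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("oops\tA\tC\n300\tG\tT\n")
        assert len(read_profile(path, "hg19")) == 1

    def test_duplicate_position_keeps_first_order_independent(self, tmp_path):
        a = tmp_path / "a.tsv"
        a.write_text("100\tA\tC\n100\tA\tG\n")
        b = tmp_path / "b.tsv"
        b.write_text("100\tA\tG\n100\tA\tC\n")
        assert read_profile(a, "hg19").get(100).obs_allele == "C"
        assert read_profile(b, "hg19").get(100).obs_allele == "G"  # first occurrence wins

    def test_round_trip(self, tmp_path):
        profile = SnpProfile("hg18", [SnpCall(5, "A", "T"), SnpCall(2, "G", "C")])
        out = tmp_path / "p.tsv"
        write_profile(profile, out)
        again = read_profile(out, "hg18")
        assert again.calls == profile.calls

    def test_call_validation(self):
        with pytest.raises(ValueError):
            SnpCall(0, "A", "C")
        with pytest.raises(ValueError):
            SnpCall(1, "A", "N")


class TestReference:
    def test_picks_y_record(self, tmp_path):
        path = tmp_path / "ref.fa"
        path.write_text(">chr1\nAAAA\n>chrY test\nACGT\n")
        ref = read_reference(path, "hg19")
        assert ref.name == "chrY"
        assert ref.base(1) == "A" and ref.base(4) == "T"

    def test_no_y_record_is_error(self, tmp_path):
        path = tmp_path / "ref.fa"
        path.write_text(">chr1\nAAAA\n")
        with pytest.raises(ValueError, match="no Y"):
            read_reference(path, "hg19")

    def test_one_based_bounds(self, walkthrough):
        assert walkthrough.reference.base(100) == "G"
        with pytest.raises(IndexError):
            walkthrough.reference.base(0)
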