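"""Format readers/writers: field mapping, invariants, round-trips."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lbdtrace.errors import ParseError, ValidationError
from lbdtrace.formats_io import (
    AnnotatedGeneTree,
    CollinearBlock,
    DomainHit,
    GeneLocus,
    HomologyPair,
    normalize_support,
    read_collinearity,
    read_domain_table,
    read_gene_table,
    read_newick_tree,
    write_collinearity,
    write_gene_table,
)

GENE_HEADER = "species\tgene_id\tchromosome\tstart\tend\tstrand\tlocus_id\tprotein_length\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGeneTable:
    def test_field_mapping(self, tmp_path):
        p = _write(
            tmp_path, "g.tsv",
            GENE_HEADER + "ath\tAT1G01010.1\tChr1\t100\t900\t+\tAT1G01010\t300\n",
        )
        (locus,) = read_gene_table(p)
        assert locus == GeneLocus(
            "AT1G01010.1", "ath", "Chr1", 100, 900, "+", "AT1G01010", 300
        )

    def test_start_after_end_rejected(self, tmp_path):
        p = _write(
            tmp_path, "g.tsv",
            GENE_HEADER + "ath\tA1\tChr1\t900\t100\t+\tA1\t300\n",
        )
        with pytest.raises(ValidationError, match="start"):
            read_gene_table(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        row = "ath\tA1\tChr1\t100\t900\t+\tA1\t300\n"
        p = _write(tmp_path, "g.tsv", GENE_HEADER + row + row)
        with pytest.raises(ValidationError, match="duplicate"):
            read_gene_table(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path, "g.tsv", GENE_HEADER + "ath\tA1\tChr1\n")
        with pytest.raises(ParseError, match=":2"):
            read_gene_table(p)

    def test_round_trip(self, tmp_path):
        loci = [
            GeneLocus("A1", "ath", "Chr1", 100, 900, "+", "L1", 300),
            GeneLocus("A2", "ath", "Chr2", 5, 10, "-", "L2", 42),
        ]
        p = tmp_path / "g.tsv"
        write_gene_table(loci, p)
        assert read_gene_table(p) == loci


class TestDomainTable:
    def test_field_mapping(self, tmp_path):
        p = _write(
            tmp_path, "h.tsv",
            "protein_id\tprofile_name\tprofile_length\thmm_from\thmm_to\tevalue\tscore\n"
            "P1\tDUF260\t100\t10\t95\t1e-20\t80.1\n",
        )
        (hit,) = read_domain_table(p)
        assert (hit.hmm_from, hit.hmm_to) == (10, 95)
        assert hit.evalue == 1e-20

    def test_empty_file(self, tmp_path):
        p = _write(tmp_path, "h.tsv", "")
        assert read_domain_table(p) == []

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(hmm_from=10, hmm_to=120, evalue=1e-20),  # beyond profile
            dict(hmm_from=10, hmm_to=95, evalue=-1.0),  # negative E-value
            dict(hmm_from=50, hmm_to=10, evalue=1e-20),  # inverted
        ],
    )
    def test_invalid_hits_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            DomainHit("P1", "DUF260", 100, score=1.0, **kwargs)


class TestHomologyPair:
    def test_self_pair_rejected(self):
        with pytest.raises(ValidationError):
            HomologyPair("a", "a", 1e-10)


class TestCollinearity:
    TWO_BLOCKS = (
        "############### Parameters ###############\n"
        "## Alignment 0: score=500.0 N=3 c1&c2 plus\n"
        "0-  0:\tf1\tf2\t1e-50\n"
        "0-  1:\tx1\tx2\t1e-40\n"
        "0-  2:\tx3\tx4\t1e-30\n"
        "## Alignment 1: score=200.0 N=2 c1&c3 plus\n"
        "1-  0:\tf1\tf3\t1e-20\n"
        "1-  1:\tx5\tx6\t1e-10\n"
    )

    def test_two_blocks(self, tmp_path):
        p = _write(tmp_path, "b.collinearity", self.TWO_BLOCKS)
        blocks = read_collinearity(p)
        assert [len(b.anchors) for b in blocks] == [3, 2]
        assert blocks[0].anchors[0] == ("f1", "f2")
        assert blocks[0].score == 500.0
        assert (blocks[0].region_a, blocks[0].region_b) == ("c1", "c2")

    def test_comment_only_file(self, tmp_path):
        p = _write(tmp_path, "b.collinearity", "############\n# MATCH_SCORE: 50\n")
        assert read_collinearity(p) == []

    def test_anchor_outside_block(self, tmp_path):
        p = _write(tmp_path, "b.collinearity", "0-  0:\tf1\tf2\t1e-50\n")
        with pytest.raises(ParseError, match="outside"):
            read_collinearity(p)

    def test_unknown_gene_with_cross_check(self, tmp_path):
        p = _write(tmp_path, "b.collinearity", self.TWO_BLOCKS)
        loci = [
            GeneLocus(g, "ath", "Chr1", i * 10 + 1, i * 10 + 5, "+", g, 10)
            for i, g in enumerate(["f1", "f2", "x1", "x2", "x3", "x4"])
        ]
        with pytest.raises(ValidationError, match="f3"):
            read_collinearity(p, loci)

    def test_round_trip(self, tmp_path):
        blocks = [
            CollinearBlock("0", "a", "b", [("g1", "g2"), ("g3", "g4")], 9.0, "c1", "c2"),
            CollinearBlock("1", "a", "a", [("g5", "g6")], None),
        ]
        p = tmp_path / "b.collinearity"
        write_collinearity(blocks, p)
        back = read_collinearity(p)
        assert [b.anchors for b in back] == [b.anchors for b in blocks]
        assert back[0].score == 9.0


class TestNewick:
    def test_percentage_support_normalized(self):
        agt = AnnotatedGeneTree.from_newick("((a:1,b:1)95:1,c:1);")
        supports = [
            n.support for n in agt.tree.postorder_node_iter() if not n.is_leaf()
        ]
        assert 0.95 in supports

    def test_fraction_support_kept(self):
        agt = AnnotatedGeneTree.from_newick("((a,b)0.95,c);")
        supports = [
            n.support for n in agt.tree.postorder_node_iter() if not n.is_leaf()
        ]
        assert 0.95 in supports

    def test_missing_support_is_missing_not_zero(self):
        agt = AnnotatedGeneTree.from_newick("((a,b),c);")
        inner = [
            n for n in agt.tree.postorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert inner[0].support is None

    def test_unbalanced_parentheses(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((a,b),c;")
        with pytest.raises(ParseError):
            read_newick_tree(p)

    def test_round_trip(self, tmp_path):
        p = _write(tmp_path, "t.nwk", "((a_1:1,b:2)0.87:1,(c:1,d:1)95:3);")
        agt = read_newick_tree(p)
        p2 = tmp_path / "t2.nwk"
        agt.write(p2)
        back = read_newick_tree(p2)
        assert sorted(back.leaf_gene_ids()) == ["a_1", "b", "c", "d"]
        sup = sorted(
            round(n.support, 6)
            for n in back.tree.postorder_node_iter()
            if not n.is_leaf() and n.support is not None
        )
        assert sup == [0.87, 0.95]

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_normalize_support_idempotent(self, value):
        once = normalize_support(value)
        assert 0 <= once <= 1
        assert math.isclose(normalize_support(once), once)

    @pytest.mark.parametrize("bad", [-0.5, 101.0, float("nan")])
    def test_out_of_range_support_rejected(self, bad):
        with pytest.raises(ValidationError):
            normalize_support(bad)
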