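"""Duplication typing: rank index, priority cascade, per-species summary."""

import random

import pytest

from conftest import oracle_duplication_label
from lbdtrace.duplication_classifier import (
    ClassifierConfig,
    DuplicationLabel,
    assign_ranks,
    classify,
    duplication_summary,
)
from lbdtrace.errors import ValidationError
from lbdtrace.formats_io import CollinearBlock, GeneLocus, HomologyPair


def locus(gid, chrom="c1", start=100, species="ath"):
    return GeneLocus(gid, species, chrom, start, start + 10, "+", gid, 100)


class TestAssignRanks:
    def test_ranks_follow_start_order(self):
        loci = [locus("a", start=100), locus("b", start=50), locus("c", start=900)]
        ranks = assign_ranks(loci)
        assert [ranks[g].rank for g in "abc"] == [1, 0, 2]

    def test_chromosomes_rank_independently(self):
        loci = [locus("a", "c1", 100), locus("b", "c2", 50), locus("c", "c1", 10)]
        ranks = assign_ranks(loci)
        assert ranks["a"].rank == 1 and ranks["c"].rank == 0
        assert ranks["b"].rank == 0

    def test_single_gene(self):
        assert assign_ranks([locus("a")])["a"].rank == 0

    def test_identical_coordinates_tie_break(self):
        loci = [locus("b", start=100), locus("a", start=100)]
        ranks = assign_ranks(loci)
        assert (ranks["a"].rank, ranks["b"].rank) == (0, 1)


def chain(*starts, chrom="c1"):
    return [locus(f"g{i}", chrom, s) for i, s in enumerate(starts)]


class TestClassifyCascade:
    def test_block_anchor_wins_over_adjacency(self):
        loci = chain(10, 20)
        ranks = assign_ranks(loci)
        pairs = [HomologyPair("g0", "g1", 1e-20)]
        blocks = [CollinearBlock("0", "ath", "ath", [("g0", "gX")])]
        ranks["gX"] = ranks["g0"]  # anchor partner elsewhere, ranked
        labels = dict(
            (l.gene_id, l.label)
            for l in classify(["g0", "g1"], pairs, blocks, ranks)
        )
        assert labels["g0"] == "wgd"
        assert labels["g1"] == "tandem"

    def test_adjacent_homologs_are_tandem(self):
        loci = [locus(f"g{i}", start=(i + 1) * 100) for i in range(7)]
        ranks = assign_ranks(loci)
        pairs = [HomologyPair("g5", "g6", 1e-30)]
        labels = {
            l.gene_id: l.label
            for l in classify(["g5", "g6"], pairs, [], ranks)
        }
        assert labels == {"g5": "tandem", "g6": "tandem"}

    @pytest.mark.parametrize(
        "distance,expected", [(15, "proximal"), (19, "proximal"), (20, "dispersed"), (25, "dispersed")]
    )
    def test_window_boundary(self, distance, expected):
        loci = [locus(f"g{i}", start=(i + 1) * 100) for i in range(30)]
        ranks = assign_ranks(loci)
        pairs = [HomologyPair("g0", f"g{distance}", 1e-30)]
        labels = {
            l.gene_id: l.label
            for l in classify(["g0", f"g{distance}"], pairs, [], ranks)
        }
        assert labels["g0"] == expected

    def test_cross_species_partner_does_not_make_duplicate(self):
        loci = [locus("a", species="ath"), locus("b", species="osa")]
        ranks = assign_ranks(loci)
        pairs = [HomologyPair("a", "b", 1e-30)]
        labels = {l.gene_id: l.label for l in classify(["a", "b"], pairs, [], ranks)}
        assert labels == {"a": "singleton", "b": "singleton"}

    def test_unranked_pair_gene_is_error(self):
        ranks = assign_ranks([locus("a")])
        with pytest.raises(ValidationError, match="ghost"):
            classify(["a"], [HomologyPair("a", "ghost", 1e-10)], [], ranks)

    def test_partition_property(self):
        loci = [locus(f"g{i}", start=(i + 1) * 10) for i in range(10)]
        ranks = assign_ranks(loci)
        labels = classify([g.gene_id for g in loci], [], [], ranks)
        assert sorted(l.gene_id for l in labels) == sorted(g.gene_id for g in loci)
        assert all(l.label == "singleton" for l in labels)


def test_matches_cascade_oracle_on_random_genomes():
    rng = random.Random(42)
    cfg = ClassifierConfig()
    for _ in range(40):
        n = rng.randint(5, 60)
        loci = [
            locus(
                f"g{i}",
                chrom=f"c{rng.randint(1, 3)}",
                start=rng.randint(1, 5000),
                species=rng.choice(["ath", "osa"]),
            )
            for i in range(n)
        ]
        ranks = assign_ranks(loci)
        genes = [g.gene_id for g in loci]
        pairs = []
        for _ in range(rng.randint(0, 2 * n)):
            a, b = rng.sample(genes, 2)
            pairs.append(HomologyPair(a, b, 1e-10))
        blocks = []
        for bi in range(rng.randint(0, 3)):
            anchors = [tuple(rng.sample(genes, 2)) for _ in range(rng.randint(1, 4))]
            blocks.append(CollinearBlock(str(bi), "ath", "ath", anchors))
        got = {l.gene_id: l.label for l in classify(genes, pairs, blocks, ranks, cfg)}
        for g in genes:
            assert got[g] == oracle_duplication_label(
                g, pairs, blocks, ranks, cfg.proximal_window
            )
        anchored = {x for b in blocks for a in b.anchors for x in a}
        assert all(got[g] == "wgd" for g in anchored if g in got)


class TestSummary:
    def test_proportions(self):
        labels = (
            [DuplicationLabel(f"w{i}", "wgd") for i in range(4)]
            + [DuplicationLabel(f"d{i}", "dispersed") for i in range(3)]
            + [DuplicationLabel(f"t{i}", "tandem") for i in range(2)]
            + [DuplicationLabel("p0", "proximal")]
        )
        family = {l.gene_id for l in labels}
        species = dict.fromkeys(family, "ath")
        table = duplication_summary(labels, family, species)
        row = table.loc["ath"]
        assert row["wgd"] == 0.4 and row["dispersed"] == 0.3
        assert row["tandem"] == 0.2 and row["proximal"] == 0.1
        assert abs(row.sum() - 1.0) < 1e-12

    def test_empty_species_omitted_with_warning(self):
        labels = [DuplicationLabel("a", "singleton")]
        species = {"a": "ath", "b": "osa"}
        with pytest.warns(UserWarning, match="osa"):
            table = duplication_summary(labels, {"a"}, species)
        assert list(table.index) == ["ath"]

    def test_simulated_proportions_match_truth(self, default_sim):
        ds, truth = default_sim
        ranks = assign_ranks(ds.loci)
        labels = classify(
            (g.gene_id for g in ds.loci), ds.pairs, ds.intra_blocks(), ranks
        )
        species = {g.gene_id: g.species for g in ds.loci}
        table = duplication_summary(labels, truth.family, species)
        truth_labels = truth.labels()
        for sp in table.index:
            fam_sp = [g for g in truth.family if species[g] == sp]
            for lab in table.columns:
                want = sum(truth_labels[g] == lab for g in fam_sp) / len(fam_sp)
                assert abs(table.loc[sp, lab] - want) < 1e-12
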