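"""Ancestral lineage inference: rooting, minimal clades, depth searches."""

import random

import pytest

from conftest import (
    oracle_minimal_clades,
    random_gene_tree,
    species_config_for_oracle,
)
from lbdtrace.ancestry_inference import (
    Clause,
    LineageCluster,
    ancestry_report,
    collinearity_support,
    find_ancient_lineages,
    find_angiosperm_ancestors,
    find_seed_ancestors,
    minimal_complete_clades,
    requirement_each_of,
    root_tree,
)
from lbdtrace.collinearity_grouping import CollinearGroup
from lbdtrace.errors import ConfigError, ValidationError
from lbdtrace.formats_io import AnnotatedGeneTree, SpeciesConfig
from lbdtrace.synthetic_data import perturb


def tree_of(newick, species):
    return AnnotatedGeneTree.from_newick(newick).annotate(species)


class TestRootTree:
    def test_outgroup_rooting(self):
        agt = tree_of("((a:1,b:1):1,(c:1,d:1):1);", {})
        rooted = root_tree(agt, {"a"})
        sides = [
            {l.taxon.label for l in ch.leaf_iter()}
            for ch in rooted.tree.seed_node.child_nodes()
        ]
        assert {"a"} in sides

    def test_idempotent_when_already_rooted(self):
        agt = tree_of("((a:1,b:1):1,(c:1,d:1):1);", {})
        rooted = root_tree(agt, {"a", "b"})
        again = root_tree(rooted, {"a", "b"})
        assert {
            frozenset(l.taxon.label for l in ch.leaf_iter())
            for ch in again.tree.seed_node.child_nodes()
        } == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_scattered_outgroup_reports_violators(self):
        agt = tree_of("((a:1,b:1):1,(c:1,d:1):1);", {})
        with pytest.raises(ValidationError, match="monophyletic"):
            root_tree(agt, {"a", "c"})


class TestMinimalCompleteClades:
    SPECIES = {"d1": "D1", "m1": "M1", "d2": "D2", "m2": "M2"}

    def req(self):
        return [Clause(frozenset({"D1", "D2"})), Clause(frozenset({"M1", "M2"}))]

    def test_two_mixed_cherries(self):
        agt = tree_of("((d1,m1),(d2,m2));", self.SPECIES)
        assert len(minimal_complete_clades(agt, self.req())) == 2

    def test_segregated_tree_yields_root(self):
        agt = tree_of("((d1,d2),(m1,m2));", self.SPECIES)
        clades = minimal_complete_clades(agt, self.req())
        assert len(clades) == 1
        assert clades[0].parent_node is None

    def test_unknown_species_in_requirement(self):
        agt = tree_of("((d1,m1),(d2,m2));", self.SPECIES)
        with pytest.raises(ConfigError, match="unknown"):
            minimal_complete_clades(
                agt, [Clause(frozenset({"Xx"}))], known_species={"D1", "M1"}
            )

    def test_matches_bruteforce_oracle(self):
        rng = random.Random(3)
        pool = ["D1", "D2", "M1", "M2", "G1"]
        for _ in range(60):
            agt = random_gene_tree(rng, rng.randint(3, 40), pool)
            clauses = []
            for _ in range(rng.randint(1, 3)):
                subset = frozenset(rng.sample(pool, rng.randint(1, 3)))
                clauses.append(Clause(subset, rng.randint(1, len(subset))))
            min_support = rng.choice([None, 0.6, 0.9])
            got = {
                agt.node_genes(n)
                for n in minimal_complete_clades(agt, clauses, min_support)
            }
            assert got == oracle_minimal_clades(agt, clauses, min_support)


class TestFixtureCounts:
    """The canonical class topology: 7 ancient, 11 seed, 18 angiosperm."""

    def test_ancient_lineages(self, fixture_tree):
        agt, spc = fixture_tree
        clusters = find_ancient_lineages(agt, spc)
        assert len(clusters) == 7
        by_class = {}
        for c in clusters:
            key = "IA" if c.class_label.startswith("IA") else c.class_label
            by_class[key] = by_class.get(key, 0) + 1
        assert by_class == {"IA": 2, "IB": 1, "IC1/ID": 1, "IC2": 1, "IE": 1, "II": 1}

    def test_seed_ancestors_and_class_distribution(self, fixture_tree):
        agt, spc = fixture_tree
        clusters = find_seed_ancestors(agt, spc)
        assert len(clusters) == 11
        by_class = {}
        for c in clusters:
            key = "IA" if c.class_label.startswith("IA") else c.class_label
            by_class[key] = by_class.get(key, 0) + 1
        assert by_class == {"IC1/ID": 3, "IA": 2, "IB": 2, "II": 2, "IC2": 1, "IE": 1}

    def test_angiosperm_ancestors(self, fixture_tree):
        agt, spc = fixture_tree
        assert len(find_angiosperm_ancestors(agt, spc)) == 18

    def test_counts_invariant_under_leaf_rotation(self, fixture_sim):
        ds, _ = fixture_sim
        shuffled = perturb(ds, "shuffle_leaf_order", seed=99)
        agt = shuffled.tree()
        spc = shuffled.species_config
        assert len(find_ancient_lineages(agt, spc)) == 7
        assert len(find_seed_ancestors(agt, spc)) == 11
        assert len(find_angiosperm_ancestors(agt, spc)) == 18

    def test_report_depth_counts_and_nesting(self, fixture_tree):
        agt, spc = fixture_tree
        ancient = find_ancient_lineages(agt, spc)
        seed = find_seed_ancestors(agt, spc)
        angio = find_angiosperm_ancestors(agt, spc)
        report = ancestry_report(ancient, seed, angio)
        assert report.counts_tuple() == (7, 11, 18)
        assert report.containment_violations == []
        # every angiosperm gene resolves through seed to an ancient lineage
        assert report.paths
        for gene, ang, sd, anc in report.paths:
            if ang != "unassigned":
                assert sd != "unassigned" and anc != "unassigned"


class TestAncientCriteria:
    SPECIES = {
        "p1": "B1", "s1": "L1", "g1": "G1",
        "d1": "D1", "d2": "D2", "m1": "M1", "m2": "M2",
    }

    def spc(self):
        return species_config_for_oracle()

    def test_sister_missing_one_seed_species_fails_strict_clause(self):
        # sister clade lacks species M2 entirely
        agt = tree_of("((p1,s1),(g1,((d1,d2),m1)));", self.SPECIES)
        assert find_ancient_lineages(agt, self.spc()) == []

    def test_relaxed_clause_is_monotone(self):
        agt = tree_of("((p1,s1),(g1,((d1,d2),m1)));", self.SPECIES)
        relaxed = [
            Clause(frozenset({"G1"})),
            Clause(frozenset({"D1", "D2", "M1", "M2"})),
        ]
        strict = find_ancient_lineages(agt, self.spc())
        loose = find_ancient_lineages(agt, self.spc(), sister_requirement=relaxed)
        assert len(loose) >= len(strict)
        assert len(loose) == 1

    def test_zero_attestations_is_valid(self):
        agt = tree_of("((p1,g1),(s1,d1));", self.SPECIES)
        assert find_ancient_lineages(agt, self.spc()) == []


class TestSeedCriteria:
    SPECIES = {
        "g1": "G1", "g2": "G1", "d1": "D1", "d2": "D2", "m1": "M1", "m2": "M2",
        "g1b": "G1", "d1b": "D1", "d2b": "D2", "m1b": "M1", "m2b": "M2",
    }

    def test_gymnosperm_outside_complete_clades(self):
        spc = SpeciesConfig({"G1": "gymnosperm", "D1": "dicot", "M1": "monocot"})
        agt = tree_of("(g1,(d1,m1));", {"g1": "G1", "d1": "D1", "m1": "M1"})
        # root qualifies; but with the gymnosperm as the root's own child the
        # only qualifying clade is the whole tree
        clusters = find_seed_ancestors(agt, spc)
        assert len(clusters) == 1
        agt2 = tree_of("((d1,m1),(d2,m2));", TestMinimalCompleteClades.SPECIES)
        spc2 = SpeciesConfig(
            {"G1": "gymnosperm", "D1": "dicot", "D2": "dicot",
             "M1": "monocot", "M2": "monocot"}
        )
        assert find_seed_ancestors(agt2, spc2) == []

    def test_no_gymnosperm_configured_is_error(self):
        spc = SpeciesConfig({"D1": "dicot", "M1": "monocot"})
        agt = tree_of("(d1,m1);", {"d1": "D1", "m1": "M1"})
        with pytest.raises(ConfigError, match="gymnosperm"):
            find_seed_ancestors(agt, spc)

    def test_duplicating_a_qualifying_clade_adds_exactly_one(self):
        spc = species_config_for_oracle()
        base = "((g1,((d1,d2),(m1,m2))),(g2,((d1c,d2c),(m1c,m2c))));"
        species = dict(self.SPECIES)
        species.update({"d1c": "D1", "d2c": "D2", "m1c": "M1", "m2c": "M2", "g2": "G1"})
        agt = tree_of(base, species)
        n_base = len(find_seed_ancestors(agt, spc))
        dup = (
            "(((g1,((d1,d2),(m1,m2))),(g1b,((d1b,d2b),(m1b,m2b)))),"
            "(g2,((d1c,d2c),(m1c,m2c))));"
        )
        agt_dup = tree_of(dup, species | self.SPECIES)
        assert len(find_seed_ancestors(agt_dup, spc)) == n_base + 1


class TestAngiospermCriteria:
    def test_one_species_per_group_default(self):
        spc = SpeciesConfig({"D1": "dicot", "M1": "monocot", "G1": "gymnosperm"})
        agt = tree_of(
            "((d1,m1),(d2,m2));",
            {"d1": "D1", "m1": "M1", "d2": "D1", "m2": "M1"},
        )
        assert len(find_angiosperm_ancestors(agt, spc)) == 2

    def test_non_angiosperm_leaves_are_transparent(self):
        spc = species_config_for_oracle()
        # a gymnosperm gene interleaved inside the dicot+monocot clade
        agt = tree_of(
            "(((d1,g1),(d2,(m1,m2))),p1);",
            {"d1": "D1", "d2": "D2", "g1": "G1", "m1": "M1", "m2": "M2",
             "p1": "B1"},
        )
        clusters = find_angiosperm_ancestors(agt, spc)
        assert len(clusters) == 1
        assert "g1" in clusters[0].members  # transparent, not excluded

    def test_lowering_dicot_min_never_decreases(self):
        rng = random.Random(8)
        spc = species_config_for_oracle()
        pool = ["D1", "D2", "M1", "M2"]
        for _ in range(25):
            agt = random_gene_tree(rng, rng.randint(4, 30), pool)
            full = len(find_angiosperm_ancestors(agt, spc))
            relaxed = len(find_angiosperm_ancestors(agt, spc, dicot_min=1))
            assert relaxed >= full

    def test_missing_group_is_error(self):
        spc = SpeciesConfig({"D1": "dicot", "G1": "gymnosperm"})
        agt = tree_of("(d1,d2);", {"d1": "D1", "d2": "D1"})
        with pytest.raises(ConfigError, match="monocot"):
            find_angiosperm_ancestors(agt, spc)


class TestSupportGating:
    def test_downgraded_defining_node_removes_cluster(self, fixture_sim):
        ds, _ = fixture_sim
        agt = ds.tree()
        spc = ds.species_config
        clusters = find_seed_ancestors(agt, spc, min_support=0.95)
        assert len(clusters) == 11  # all simulated supports are 1.0
        target = clusters[0].members
        nodes = {
            agt.node_genes(n): n
            for n in agt.tree.preorder_node_iter()
            if not n.is_leaf()
        }
        nodes[target].support = 0.5
        after = find_seed_ancestors(agt, spc, min_support=0.95)
        assert target not in {c.members for c in after}


class TestCollinearitySupport:
    def grp(self, gid, members, scope="dicot"):
        return CollinearGroup(gid, frozenset(members), frozenset(), scope)

    def cluster(self, members):
        return LineageCluster(depth="angiosperm", members=frozenset(members))

    def test_single_group_per_clade_supported(self):
        cl = self.cluster({"da", "db", "ma"})
        (out,) = collinearity_support(
            [cl],
            [self.grp("G1", {"da", "db"})],
            [self.grp("H3", {"ma", "mb"}, "monocot")],
        )
        assert out.collinearity_supported is True

    def test_split_across_groups_unsupported(self):
        cl = self.cluster({"da", "db"})
        (out,) = collinearity_support(
            [cl],
            [self.grp("G1", {"da", "dx"}), self.grp("G2", {"db", "dy"})],
            [],
        )
        assert out.collinearity_supported is False

    def test_no_grouped_member_unsupported(self):
        cl = self.cluster({"da", "ma"})
        (out,) = collinearity_support([cl], [self.grp("G1", {"dx", "dy"})], [])
        assert out.collinearity_supported is False

    def test_wrong_depth_rejected(self):
        cl = LineageCluster(depth="seed", members=frozenset({"a", "b"}))
        with pytest.raises(ValidationError):
            collinearity_support([cl], [], [])


class TestReportEdgeCases:
    def test_empty_report(self):
        report = ancestry_report([], [], [])
        assert report.counts_tuple() == (0, 0, 0)
        assert report.paths == []

    def test_overlapping_clusters_rejected(self):
        a = LineageCluster(depth="seed", members=frozenset({"x", "y"}), cluster_id="S1")
        b = LineageCluster(depth="seed", members=frozenset({"y", "z"}), cluster_id="S2")
        with pytest.raises(ValidationError, match="overlap"):
            ancestry_report([], [a, b], [])
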