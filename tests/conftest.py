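"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings

from lbdtrace.formats_io import AnnotatedGeneTree, SpeciesConfig
from lbdtrace.synthetic_data import SimConfig, fixture_config, simulate

settings.register_profile(
    "ci",
    max_examples=60,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One full simulated dataset at default settings (with events)."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_sim():
    """The bare ancestry fixture: canonical lineage topology, no events."""
    return simulate(fixture_config(seed=5))


@pytest.fixture()
def fixture_tree(fixture_sim):
    ds, _ = fixture_sim
    return ds.tree(), ds.species_config


# ---------------------------------------------------------------------------
# random instance generators (seeded, deterministic)
# ---------------------------------------------------------------------------


def random_gene_tree(
    rng: random.Random,
    n_leaves: int,
    species_pool: list[str],
    support_prob: float = 0.7,
) -> AnnotatedGeneTree:
    """A random binary tree over n_leaves genes with random species labels
    and randomly present supports."""
    leaves = [f"g{i}" for i in range(n_leaves)]
    subtrees = [f"{l}:1" for l in leaves]
    while len(subtrees) > 1:
        i = rng.randrange(len(subtrees))
        a = subtrees.pop(i)
        j = rng.randrange(len(subtrees))
        b = subtrees.pop(j)
        if rng.random() < support_prob:
            sup = round(rng.uniform(0.3, 1.0), 2)
            subtrees.append(f"({a},{b}){sup}:1")
        else:
            subtrees.append(f"({a},{b}):1")
    newick = subtrees[0]
    if newick.endswith(":1"):
        newick = newick[:-2]
    agt = AnnotatedGeneTree.from_newick(newick + ";")
    agt.annotate({l: rng.choice(species_pool) for l in leaves})
    return agt


def oracle_minimal_clades(agt, requirement, min_support=None):
    """Brute force: enumerate every clade, filter qualifying, keep those
    with no qualifying proper-subset clade. Returns a set of leaf frozensets."""
    nodes = list(agt.tree.postorder_node_iter())

    def leafset(n):
        return frozenset(l.taxon.label for l in n.leaf_iter())

    def speciesset(n):
        return frozenset(agt.species[g] for g in leafset(n))

    def support_ok(n):
        if min_support is None or n.is_leaf():
            return True
        s = getattr(n, "support", None)
        if s is None:
            return all(c.is_leaf() for c in n.child_nodes())
        return s >= min_support

    qualifying = [
        n
        for n in nodes
        if support_ok(n)
        and all(
            len(cl.species & speciesset(n)) >= cl.min_species for cl in requirement
        )
    ]
    qsets = [leafset(n) for n in qualifying]
    return {s for s in qsets if not any(o < s for o in qsets)}


def oracle_components(pairs):
    """Transitive closure by iterated merging, no graph library."""
    comps: list[set[str]] = []
    for a, b in pairs:
        touching = [c for c in comps if a in c or b in c]
        merged = {a, b}
        for c in touching:
            merged |= c
            comps.remove(c)
        comps.append(merged)
    return {frozenset(c) for c in comps if len(c) >= 2}


def oracle_duplication_label(gene, pairs, blocks, ranks, window):
    """Independent rule-cascade evaluation for one gene."""
    for b in blocks:
        for x, y in b.anchors:
            if gene in (x, y):
                return "wgd"
    pos = ranks[gene]
    partners = set()
    for p in pairs:
        if p.query_id == gene:
            partners.add(p.subject_id)
        if p.subject_id == gene:
            partners.add(p.query_id)
    partners = {h for h in partners if ranks[h].species == pos.species}
    same_chrom = [
        abs(ranks[h].rank - pos.rank)
        for h in partners
        if ranks[h].chromosome == pos.chromosome
    ]
    if any(d == 1 for d in same_chrom):
        return "tandem"
    if any(1 < d < window for d in same_chrom):
        return "proximal"
    if partners:
        return "dispersed"
    return "singleton"


def species_config_for_oracle() -> SpeciesConfig:
    return SpeciesConfig(
        {
            "B1": "bryophyte",
            "L1": "lycophyte",
            "G1": "gymnosperm",
            "D1": "dicot",
            "D2": "dicot",
            "M1": "monocot",
            "M2": "monocot",
        }
    )
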