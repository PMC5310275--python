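"""Ancestral gene-lineage inference from a species-annotated gene tree.

The model: a gene family in land plants descends from a small set of
ancestral genes at three successive evolutionary depths —

* **ancient** lineages, genes already present in early land plants.
  Evidence: a maximal clade consisting exclusively of bryophyte/lycophyte
  genes whose sister clade contains genes of every analyzed seed-plant
  species ("neighbors with" all seed plants).
* **seed-plant** ancestors, genes present before the gymnosperm/angiosperm
  split. Evidence: a *minimal* clade containing at least one gymnosperm
  gene together with at least one gene from every analyzed angiosperm
  species (a stringent criterion guarding against long-branch artifacts).
* **angiosperm** ancestors, genes present in the last common ancestor of
  dicots and monocots. Evidence: a minimal clade containing genes from
  (by default) every analyzed dicot and every analyzed monocot species.
  Non-angiosperm leaves inside such a clade are transparent: presence
  clauses are never falsified by extra leaves, so interleaved gymnosperm
  orthologs do not break the count.

Minimal qualifying clades are provably pairwise disjoint, so counting them
counts ancestral genes. Angiosperm clusters can additionally be
cross-checked against collinear ortholog groups (phylogeny x synteny).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .collinearity_grouping import CollinearGroup
from .errors import ConfigError, ValidationError
from .formats_io import AnnotatedGeneTree, SpeciesConfig

DEPTHS = ("ancient", "seed", "angiosperm")


@dataclass(frozen=True)
class Clause:
    """One requirement: >= min_species distinct species of this set present.

    With min_species=1 this reads "at least one gene of (some species in)
    the set"; a clause per single species expresses "a gene from every
    analyzed species".
    """

    species: frozenset[str]
    min_species: int = 1

    def __post_init__(self) -> None:
        if self.min_species < 1:
            raise ConfigError("clause minimum must be >= 1")
        if not self.species:
            raise ConfigError("clause has an empty species set")

    def satisfied_by(self, present: frozenset[str]) -> bool:
        return len(self.species & present) >= self.min_species


TaxonRequirement = Sequence[Clause]


def requirement_each_of(species: Iterable[str]) -> list[Clause]:
    """One clause per species: a gene from every one of them is required."""
    return [Clause(frozenset({s})) for s in sorted(species)]


@dataclass
class LineageCluster:
    """One inferred ancestral gene lineage."""

    depth: str
    members: frozenset[str]
    class_label: str | None = None
    support: float | None = None
    collinearity_supported: bool | None = None  # None = not applicable
    cluster_id: str = ""
    # leaf set used for containment queries (ancient: basal clade + sister)
    scope: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.depth not in DEPTHS:
            raise ValidationError(f"unknown depth {self.depth!r}")
        if not self.scope:
            self.scope = self.members


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------


def root_tree(
    agt: AnnotatedGeneTree, outgroup: Iterable[str] | str = "midpoint"
) -> AnnotatedGeneTree:
    """Root on the edge separating an outgroup, or at the midpoint.

    The outgroup must form one side of an edge in the unrooted tree
    (i.e. be monophyletic once rooted); otherwise the violating leaves are
    reported. Midpoint rooting requires branch lengths.
    """
    agt = agt.clone()
    tree = agt.tree
    if isinstance(outgroup, str):
        if outgroup != "midpoint":
            raise ConfigError(f"outgroup must be a gene set or 'midpoint'")
        tree.reroot_at_midpoint(update_bipartitions=True, suppress_unifurcations=True)
        return agt

    wanted = set(outgroup)
    all_leaves = set(agt.leaf_gene_ids())
    unknown = sorted(wanted - all_leaves)
    if unknown:
        raise ValidationError(f"outgroup leaves not in tree: {unknown}")
    if wanted == all_leaves:
        raise ValidationError("outgroup cannot be the whole tree")

    # already rooted this way? leave untouched (idempotence)
    for child in tree.seed_node.child_nodes():
        if {l.taxon.label for l in child.leaf_iter()} == wanted:
            return agt

    # view the tree as unrooted from a reference leaf outside the outgroup
    ref = next(
        l for l in tree.leaf_node_iter() if l.taxon.label not in wanted
    )
    tree.reroot_at_edge(ref.edge, update_bipartitions=True)
    taxa = [l.taxon for l in tree.leaf_node_iter() if l.taxon.label in wanted]
    mrca = tree.mrca(taxa=taxa)
    got = {l.taxon.label for l in mrca.leaf_iter()}
    if got != wanted:
        raise ValidationError(
            f"outgroup is not monophyletic; clade also contains "
            f"{sorted(got - wanted)}"
        )
    tree.reroot_at_edge(mrca.edge, update_bipartitions=True)
    for node in tree:
        if not hasattr(node, "support"):
            node.support = None
    return agt


# ---------------------------------------------------------------------------
# minimal taxon-complete clades
# ---------------------------------------------------------------------------


def _support_ok(node: dendropy.Node, min_support: float | None) -> bool:
    if min_support is None or node.is_leaf():
        return True
    s = getattr(node, "support", None)
    if s is None:
        # cherries straight above leaves carry no meaningful support label
        return all(c.is_leaf() for c in node.child_nodes())
    return s >= min_support


def minimal_complete_clades(
    agt: AnnotatedGeneTree,
    requirement: TaxonRequirement,
    min_support: float | None = None,
    known_species: Iterable[str] | None = None,
) -> list[dendropy.Node]:
    """Minimal clades whose leaf species satisfy every clause.

    Post-order scan; a node qualifies if all clauses hold on its leaf
    species and its support passes the gate; returned nodes have no
    qualifying strict descendant and are therefore pairwise disjoint.
    """
    if known_species is not None:
        known = set(known_species)
        for cl in requirement:
            bad = sorted(cl.species - known)
            if bad:
                raise ConfigError(f"requirement references unknown species: {bad}")
    results: list[dendropy.Node] = []
    spset: dict[int, frozenset[str]] = {}
    has_q: dict[int, bool] = {}  # node or a strict descendant qualifies
    for node in agt.tree.postorder_node_iter():
        if node.is_leaf():
            gene = node.taxon.label
            sp = agt.species.get(gene)
            if sp is None:
                raise ValidationError(f"leaf {gene!r} has no species annotation")
            spset[id(node)] = frozenset({sp})
            sub = False
        else:
            acc: set[str] = set()
            sub = False
            for child in node.child_nodes():
                acc |= spset[id(child)]
                sub = sub or has_q[id(child)]
            spset[id(node)] = frozenset(acc)
        qualifies = (
            all(cl.satisfied_by(spset[id(node)]) for cl in requirement)
            and _support_ok(node, min_support)
        )
        if qualifies and not sub:
            results.append(node)
        has_q[id(node)] = qualifies or sub
    return results


# ---------------------------------------------------------------------------
# depth-specific searches
# ---------------------------------------------------------------------------


def _majority_class(agt: AnnotatedGeneTree, genes: Iterable[str]) -> str | None:
    counts: dict[str, int] = {}
    for g in genes:
        lab = agt.class_labels.get(g)
        if lab is not None:
            counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    return sorted(c for c, n in counts.items() if n == best)[0]


def _cluster_from_node(
    agt: AnnotatedGeneTree,
    node: dendropy.Node,
    depth: str,
    scope: frozenset[str] | None = None,
) -> LineageCluster:
    members = agt.node_genes(node)
    return LineageCluster(
        depth=depth,
        members=members,
        class_label=_majority_class(agt, members),
        support=getattr(node, "support", None),
        scope=scope or members,
    )


def _assign_ids(clusters: list[LineageCluster], prefix: str) -> list[LineageCluster]:
    clusters.sort(key=lambda c: min(c.members))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"{prefix}{i:02d}"
    return clusters


def find_ancient_lineages(
    agt: AnnotatedGeneTree,
    species_cfg: SpeciesConfig,
    min_support: float | None = None,
    sister_requirement: TaxonRequirement | None = None,
) -> list[LineageCluster]:
    """Ancient lineages: maximal basal (bryophyte/lycophyte-only) clades
    whose sister contains genes of every analyzed seed-plant species.

    The sister requirement is configurable; the default demands all
    gymnosperm, dicot and monocot species of the config. The min_support
    gate applies at the basal clade's node. Zero attestations is a valid
    result.
    """
    basal = species_cfg.species_in("bryophyte", "lycophyte")
    if not basal:
        raise ConfigError("no bryophyte/lycophyte species configured")
    seed_species = species_cfg.species_in("gymnosperm", "dicot", "monocot")
    if sister_requirement is None:
        sister_requirement = requirement_each_of(seed_species)

    clusters: list[LineageCluster] = []
    for node in agt.tree.preorder_node_iter():
        node_sp = agt.node_species(node)
        if not node_sp or not node_sp <= basal:
            continue
        parent = node.parent_node
        if parent is None:
            continue  # whole tree basal: no sister to attest anything
        if agt.node_species(parent) <= basal:
            continue  # not maximal
        if not _support_ok(node, min_support):
            continue
        sister_species: set[str] = set()
        for sib in parent.child_nodes():
            if sib is not node:
                sister_species |= agt.node_species(sib)
        if all(cl.satisfied_by(frozenset(sister_species)) for cl in sister_requirement):
            clusters.append(
                _cluster_from_node(
                    agt, node, "ancient", scope=agt.node_genes(parent)
                )
            )
    return _assign_ids(clusters, "ANC")


def find_seed_ancestors(
    agt: AnnotatedGeneTree,
    species_cfg: SpeciesConfig,
    min_support: float | None = None,
) -> list[LineageCluster]:
    """Seed-plant ancestors: minimal clades with >=1 gymnosperm gene and
    >=1 gene from every analyzed angiosperm species."""
    gymnosperms = species_cfg.species_in("gymnosperm")
    if not gymnosperms:
        raise ConfigError("no gymnosperm species configured")
    angiosperms = species_cfg.species_in("dicot", "monocot")
    req = [Clause(gymnosperms, 1)] + requirement_each_of(angiosperms)
    nodes = minimal_complete_clades(
        agt, req, min_support, known_species=species_cfg.species
    )
    clusters = [_cluster_from_node(agt, n, "seed") for n in nodes]
    return _assign_ids(clusters, "SEED")


def find_angiosperm_ancestors(
    agt: AnnotatedGeneTree,
    species_cfg: SpeciesConfig,
    min_support: float | None = None,
    dicot_min: int | None = None,
    monocot_min: int | None = None,
) -> list[LineageCluster]:
    """Angiosperm ancestors: minimal clades spanning >= dicot_min dicot and
    >= monocot_min monocot species (defaults: all of each). Non-angiosperm
    leaves are transparent — presence clauses are never blocked by them."""
    dicots = species_cfg.species_in("dicot")
    monocots = species_cfg.species_in("monocot")
    if not dicots or not monocots:
        raise ConfigError("need at least one dicot and one monocot species")
    dicot_min = len(dicots) if dicot_min is None else dicot_min
    monocot_min = len(monocots) if monocot_min is None else monocot_min
    req = [Clause(dicots, dicot_min), Clause(monocots, monocot_min)]
    nodes = minimal_complete_clades(
        agt, req, min_support, known_species=species_cfg.species
    )
    clusters = [_cluster_from_node(agt, n, "angiosperm") for n in nodes]
    return _assign_ids(clusters, "ANG")


# ---------------------------------------------------------------------------
# collinearity cross-support
# ---------------------------------------------------------------------------


def collinearity_support(
    clusters: Sequence[LineageCluster],
    dicot_groups: Sequence[CollinearGroup],
    monocot_groups: Sequence[CollinearGroup],
) -> list[LineageCluster]:
    """Flag angiosperm clusters supported by collinear ortholog groups.

    Supported iff all grouped dicot members fall in one single dicot group,
    all grouped monocot members fall in one single monocot group, and at
    least one member is grouped at all. Mutates and returns the clusters.
    """
    gene_to_dicot = {g: grp.group_id for grp in dicot_groups for g in grp.members}
    gene_to_monocot = {g: grp.group_id for grp in monocot_groups for g in grp.members}
    for cl in clusters:
        if cl.depth != "angiosperm":
            raise ValidationError("collinearity support applies at angiosperm depth")
        d_ids = {gene_to_dicot[m] for m in cl.members if m in gene_to_dicot}
        m_ids = {gene_to_monocot[m] for m in cl.members if m in gene_to_monocot}
        cl.collinearity_supported = (
            len(d_ids) <= 1 and len(m_ids) <= 1 and bool(d_ids or m_ids)
        )
    return list(clusters)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class AncestryReport:
    depth_counts: dict[str, int]
    class_counts: dict[tuple[str, str], int]  # (depth, class) -> count
    paths: list[tuple[str, str, str, str]]  # gene, angiosperm, seed, ancient ids
    containment_violations: list[str]

    def counts_tuple(self) -> tuple[int, int, int]:
        return (
            self.depth_counts["ancient"],
            self.depth_counts["seed"],
            self.depth_counts["angiosperm"],
        )


def _check_disjoint(clusters: Sequence[LineageCluster], depth: str) -> None:
    seen: dict[str, str] = {}
    for cl in clusters:
        for g in cl.members:
            if g in seen and seen[g] != cl.cluster_id:
                raise ValidationError(
                    f"{depth} clusters {seen[g]} and {cl.cluster_id} overlap at {g}"
                )
            seen[g] = cl.cluster_id


def ancestry_report(
    ancient: Sequence[LineageCluster],
    seed: Sequence[LineageCluster],
    angiosperm: Sequence[LineageCluster],
) -> AncestryReport:
    """Counts per depth/class plus per-gene lineage paths by containment.

    An angiosperm cluster maps to the seed cluster whose clade contains it;
    a seed cluster maps to the ancient lineage whose attesting clade (basal
    cluster + sister) contains it. Containment failures are recorded as
    "unassigned" and reported, never silently dropped.
    """
    for depth, cls in (("ancient", ancient), ("seed", seed), ("angiosperm", angiosperm)):
        _check_disjoint(cls, depth)

    depth_counts = {
        "ancient": len(ancient),
        "seed": len(seed),
        "angiosperm": len(angiosperm),
    }
    class_counts: dict[tuple[str, str], int] = {}
    for depth, cls in (("ancient", ancient), ("seed", seed), ("angiosperm", angiosperm)):
        for cl in cls:
            key = (depth, cl.class_label or "unlabeled")
            class_counts[key] = class_counts.get(key, 0) + 1

    violations: list[str] = []

    def container(child_members: frozenset[str], parents: Sequence[LineageCluster]) -> str:
        hits = [p for p in parents if child_members <= p.scope]
        if len(hits) == 1:
            return hits[0].cluster_id
        partial = [
            p.cluster_id for p in parents if child_members & p.scope
        ]
        if partial:
            violations.append(
                f"cluster not nested: overlaps {partial} without containment"
            )
        return "unassigned"

    seed_parent = {cl.cluster_id: container(cl.members, seed) for cl in angiosperm}
    ancient_parent = {cl.cluster_id: container(cl.members, ancient) for cl in seed}

    paths: list[tuple[str, str, str, str]] = []
    for cl in angiosperm:
        sid = seed_parent[cl.cluster_id]
        aid = ancient_parent.get(sid, "unassigned")
        for gene in sorted(cl.members):
            paths.append((gene, cl.cluster_id, sid, aid))
    # genes in seed clusters but no angiosperm cluster (e.g. gymnosperm genes)
    in_ang = {g for cl in angiosperm for g in cl.members}
    for cl in seed:
        aid = ancient_parent[cl.cluster_id]
        for gene in sorted(cl.members - in_ang):
            paths.append((gene, "unassigned", cl.cluster_id, aid))
    paths.sort()
    return AncestryReport(depth_counts, class_counts, paths, violations)


def write_clusters(clusters: Iterable[LineageCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tdepth\tclass\tsupport\tcollinearity_supported\tgene_id\n"
        )
        for cl in clusters:
            sup = "" if cl.support is None else f"{cl.support:g}"
            col = "" if cl.collinearity_supported is None else str(
                cl.collinearity_supported
            ).lower()
            for gene in sorted(cl.members):
                fh.write(
                    f"{cl.cluster_id}\t{cl.depth}\t{cl.class_label or ''}\t"
                    f"{sup}\t{col}\t{gene}\n"
                )


def write_report(report: AncestryReport, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "summary_counts.tsv", "w") as fh:
        fh.write("depth\tclass\tcount\n")
        for depth in DEPTHS:
            fh.write(f"{depth}\t*\t{report.depth_counts[depth]}\n")
        for (depth, cls), n in sorted(report.class_counts.items()):
            fh.write(f"{depth}\t{cls}\t{n}\n")
    with open(directory / "lineage_paths.tsv", "w") as fh:
        fh.write("gene_id\tangiosperm_cluster\tseed_cluster\tancient_cluster\n")
        for row in report.paths:
            fh.write("\t".join(row) + "\n")
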