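"""Duplication-type classification from gene order, homology and synteny.

Each gene receives exactly one label by a strict priority cascade, the
scheme of MCScanX's duplicate_gene_classifier:

    wgd > tandem > proximal > dispersed > singleton

* wgd        — the gene appears in any collinear-block anchor;
* tandem     — a same-chromosome homology partner at rank distance 1
               (genome-wide adjacency, computed over *all* genes);
* proximal   — a same-chromosome partner at rank distance in
               (1, proximal_window), i.e. "spanning fewer than 20 genes"
               with the default window, read as an exclusive bound;
* dispersed  — any homology partner in the same genome;
* singleton  — none of the above.

Duplication is an intra-genome notion, so homology partners are only
considered when they belong to the same species; blocks passed in should be
intra-genome blocks when MCScanX semantics are wanted (the pipeline filters
them that way). Homology pairs are symmetrized internally: BLAST top-k
lists are asymmetric but duplication is a symmetric relation.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError
from .formats_io import CollinearBlock, GeneLocus, HomologyPair

DUPLICATION_LABELS = ("singleton", "dispersed", "proximal", "tandem", "wgd")


@dataclass(frozen=True)
class ClassifierConfig:
    proximal_window: int = 20  # exclusive bound on rank distance
    top_hits: int = 5  # expected truncation of the input pair lists

    def __post_init__(self) -> None:
        if self.proximal_window < 2:
            raise ConfigError("proximal_window must be >= 2")
        if self.top_hits < 1:
            raise ConfigError("top_hits must be >= 1")


@dataclass(frozen=True)
class GenePosition:
    species: str
    chromosome: str
    rank: int


@dataclass(frozen=True)
class DuplicationLabel:
    gene_id: str
    label: str


def assign_ranks(loci: Sequence[GeneLocus]) -> dict[str, GenePosition]:
    """Gene-order index: ranks 0..n-1 within each (species, chromosome).

    Sort key is (start, end, gene_id), so identical coordinates are
    permitted and broken deterministically.
    """
    groups: dict[tuple[str, str], list[GeneLocus]] = defaultdict(list)
    for g in loci:
        groups[(g.species, g.chromosome)].append(g)
    out: dict[str, GenePosition] = {}
    for (species, chromosome), members in groups.items():
        members.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(members):
            out[g.gene_id] = GenePosition(species, chromosome, rank)
    return out


def classify(
    genes: Iterable[str],
    pairs: Sequence[HomologyPair],
    blocks: Sequence[CollinearBlock],
    ranks: Mapping[str, GenePosition],
    cfg: ClassifierConfig | None = None,
) -> list[DuplicationLabel]:
    """Label every input gene by the priority cascade. Order-deterministic."""
    cfg = cfg or ClassifierConfig()
    genes = sorted(set(genes))

    partners: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        partners[p.query_id].add(p.subject_id)
        partners[p.subject_id].add(p.query_id)

    missing = sorted(
        g for g in set(partners) | set(genes) if g not in ranks
    )
    if missing:
        raise ValidationError(
            f"{len(missing)} gene(s) without rank assignment: {missing[:10]}"
        )

    anchored: set[str] = set()
    for b in blocks:
        for ga, gb in b.anchors:
            anchored.add(ga)
            anchored.add(gb)

    labels: list[DuplicationLabel] = []
    for g in genes:
        labels.append(DuplicationLabel(g, _label_one(g, partners, anchored, ranks, cfg)))
    return labels


def _label_one(
    gene: str,
    partners: Mapping[str, set[str]],
    anchored: set[str],
    ranks: Mapping[str, GenePosition],
    cfg: ClassifierConfig,
) -> str:
    if gene in anchored:
        return "wgd"
    pos = ranks[gene]
    min_dist: int | None = None
    has_genome_partner = False
    for other in partners.get(gene, ()):
        opos = ranks[other]
        if opos.species != pos.species:
            continue
        has_genome_partner = True
        if opos.chromosome != pos.chromosome:
            continue
        d = abs(opos.rank - pos.rank)
        if min_dist is None or d < min_dist:
            min_dist = d
    if min_dist == 1:
        return "tandem"
    if min_dist is not None and 1 < min_dist < cfg.proximal_window:
        return "proximal"
    if has_genome_partner:
        return "dispersed"
    return "singleton"


def duplication_summary(
    labels: Sequence[DuplicationLabel],
    family: Iterable[str],
    species_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-species proportions of each duplication type among family genes.

    Rows: species (sorted); columns: the five labels; each row sums to 1.
    Species with no family gene are omitted with a warning.
    """
    family = set(family)
    by_gene = {l.gene_id: l.label for l in labels}
    missing = sorted(family - set(by_gene))
    if missing:
        raise ValidationError(f"family genes without labels: {missing[:10]}")
    counts: dict[str, dict[str, int]] = defaultdict(lambda: dict.fromkeys(DUPLICATION_LABELS, 0))
    for g in family:
        sp = species_map.get(g)
        if sp is None:
            raise ValidationError(f"family gene {g!r} has no species mapping")
        counts[sp][by_gene[g]] += 1
    empty = sorted(set(species_map.values()) - set(counts))
    if empty:
        warnings.warn(f"species with no family genes omitted: {empty}")
    rows = {}
    for sp in sorted(counts):
        total = sum(counts[sp].values())
        rows[sp] = {lab: counts[sp][lab] / total for lab in DUPLICATION_LABELS}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(DUPLICATION_LABELS))
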