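"""Family-internal collinear pairs and their recursive merge into groups.

A collinear group is the transitive closure of family genes linked by
collinear anchor pairs — the connected components of the pair graph. One
group proxies one set of orthologs descended from a single ancestral gene.
Dicots and monocots are merged separately (clade scopes); a pair spanning
scopes signals mis-scoped input and is an error. Intra-genome pairs (from
self-comparison blocks) participate when present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ValidationError
from .formats_io import CollinearBlock


@dataclass(frozen=True)
class CollinearGroup:
    group_id: str
    members: frozenset[str]
    species_present: frozenset[str]
    clade_scope: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError(f"group {self.group_id}: fewer than 2 members")


def family_pairs(
    blocks: Sequence[CollinearBlock], family: Iterable[str]
) -> list[tuple[str, str]]:
    """Anchors with both genes in the family, deduplicated as unordered pairs.

    Returned in first-seen order with each pair sorted internally.
    """
    family = set(family)
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for b in blocks:
        for ga, gb in b.anchors:
            if ga in family and gb in family and ga != gb:
                pair = (ga, gb) if ga < gb else (gb, ga)
                if pair not in seen:
                    seen.add(pair)
                    out.append(pair)
    return out


def merge_groups(
    pairs: Sequence[tuple[str, str]],
    scope_map: Mapping[str, str],
    species_map: Mapping[str, str] | None = None,
) -> list[CollinearGroup]:
    """Connected components of the pair graph, as :class:`CollinearGroup` s.

    scope_map maps genes to a clade scope (dicot/monocot/other); every pair
    must lie within one scope. species_map, when given, fills
    species_present. Output is deterministic: groups sorted by smallest
    member id, ids G001, G002, ... Singleton vertices are never emitted.
    """
    graph = nx.Graph()
    for ga, gb in pairs:
        sa = scope_map.get(ga)
        sb = scope_map.get(gb)
        if sa is None or sb is None:
            missing = ga if sa is None else gb
            raise ValidationError(f"gene {missing!r} has no clade scope")
        if sa != sb:
            raise ValidationError(
                f"pair ({ga}, {gb}) spans clade scopes {sa!r} vs {sb!r}"
            )
        if ga != gb:
            graph.add_edge(ga, gb)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    groups: list[CollinearGroup] = []
    for i, comp in enumerate(components, start=1):
        members = frozenset(comp)
        species = frozenset(
            species_map[g] for g in comp if species_map and g in species_map
        ) if species_map else frozenset()
        groups.append(
            CollinearGroup(
                group_id=f"G{i:03d}",
                members=members,
                species_present=species,
                clade_scope=scope_map[comp[0]],
            )
        )
    return groups


def write_groups(groups: Sequence[CollinearGroup], path, species_map=None) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tgene_id\tspecies\tclade_scope\n")
        for g in groups:
            for gene in sorted(g.members):
                sp = species_map.get(gene, "") if species_map else ""
                fh.write(f"{g.group_id}\t{gene}\t{sp}\t{g.clade_scope}\n")


def read_groups(path, scope: str | None = None) -> list[CollinearGroup]:
    """Read a groups TSV written by :func:`write_groups`."""
    from .formats_io import _read_rows

    members: dict[str, set[str]] = {}
    species: dict[str, set[str]] = {}
    scopes: dict[str, str] = {}
    for _, row in _read_rows(path, ("group_id", "gene_id")):
        gid = row["group_id"]
        members.setdefault(gid, set()).add(row["gene_id"])
        if row.get("species"):
            species.setdefault(gid, set()).add(row["species"])
        if row.get("clade_scope"):
            scopes[gid] = row["clade_scope"]
    return [
        CollinearGroup(
            group_id=gid,
            members=frozenset(members[gid]),
            species_present=frozenset(species.get(gid, ())),
            clade_scope=scopes.get(gid, scope or "other"),
        )
        for gid in sorted(members)
    ]
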