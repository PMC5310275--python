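"""Synthetic gene-family evolution with full ground truth.

The generator emulates the evolutionary model the pipeline is built to
recover: a fixed number of *ancient* gene lineages present in early land
plants, stem duplications expanding them to the *seed-plant* and then the
*angiosperm* ancestor complement, and per-species duplication events
(WGD / tandem / proximal / dispersed) in angiosperm genomes. It emits every
input dialect the pipeline consumes — gene table, domain-hit table,
homology pairs, an MCScanX-style collinearity file, a Newick gene tree with
species and class maps, and protein FASTA with class-diagnostic motifs —
plus a :class:`SimTruth` with the known lineage ids, duplication labels,
and collinear groups.

Construction guarantees (at loss_probability 0):

* the gene tree encodes the true duplication/speciation history, so the
  three ancestry searches recover exactly (n_ancient, n_seed,
  n_angiosperm) lineages;
* every WGD-affected gene (and only those, among family genes) appears in
  an intra-genome collinear block; tandem copies sit at rank distance 1,
  proximal copies at a rank distance drawn from [2, 19], dispersed copies
  on a different chromosome far from any family gene — so the duplication
  classifier reproduces the truth labels;
* inter-species blocks within each clade link orthologous base genes, so
  collinear-group merging reproduces the truth groups.

Event placements reserve disjoint gene-order windows so events never
distort each other's rank gaps. Supports are emitted as 1.0 — the
simulated history is certain; noise is injected only via :func:`perturb`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ConfigError
from .formats_io import (
    AnnotatedGeneTree,
    CollinearBlock,
    DomainHit,
    GeneLocus,
    HomologyPair,
    SpeciesConfig,
    write_class_map,
    write_collinearity,
    write_domain_table,
    write_fasta,
    write_gene_table,
    write_newick_tree,
    write_pair_table,
    write_species_config,
)

DEFAULT_SPECIES_GROUPS: dict[str, str] = {
    "Ppa": "bryophyte",
    "Smo": "lycophyte",
    "Pab": "gymnosperm",
    "Aco": "dicot",
    "Ath": "dicot",
    "Egr": "dicot",
    "Ptr": "dicot",
    "Vvi": "dicot",
    "Osa": "monocot",
    "Sbi": "monocot",
    "Zma": "monocot",
}

CLASS_NAMES = ("IA-1", "IA-2", "IB", "IC1/ID", "IC2", "IE", "II")

# canonical stem-duplication layout for the default (7, 11, 18) depth counts:
# seed lineages per ancient lineage, and angiosperm lineages per seed lineage
_CANONICAL_SEED_ALLOC = {  # class -> number of seed lineages
    "IA-1": 1, "IA-2": 1, "IB": 2, "IC1/ID": 3, "IC2": 1, "IE": 1, "II": 2,
}
_CANONICAL_ANGIO_ALLOC = {  # class -> angiosperm lineages per seed lineage
    "IA-1": [1], "IA-2": [2], "IB": [2, 1], "IC1/ID": [2, 2, 1],
    "IC2": [2], "IE": [1], "II": [2, 2],
}

_PROFILE = "DUF260"
_PROFILE_LEN = 100
_AA = "ACDEFGHIKLMNPQRSTVWY"

EVENT_TYPES = ("wgd", "tandem", "proximal", "dispersed")


def default_events() -> dict[str, int]:
    """Per-angiosperm-species family duplication events.

    Chosen so each angiosperm carries ~34 family genes (18 ancestral plus
    16 event copies), the scale of a family substantially expanded by
    whole-genome and dispersed duplications.
    """
    return {"wgd": 6, "tandem": 3, "proximal": 2, "dispersed": 5}


@dataclass
class SimConfig:
    species_groups: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_GROUPS)
    )
    n_ancient: int = 7
    n_seed: int = 11
    n_angiosperm: int = 18
    events: dict[str, int] = field(default_factory=default_events)
    wgd_retention: float = 0.5
    background_genes_per_chromosome: int = 200
    n_chromosomes: int = 5
    loss_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_ancient <= self.n_seed <= self.n_angiosperm):
            raise ConfigError(
                "depth counts must satisfy 1 <= n_ancient <= n_seed <= n_angiosperm"
            )
        for k in self.events:
            if k not in EVENT_TYPES:
                raise ConfigError(f"unknown event type {k!r}")
            if self.events[k] < 0:
                raise ConfigError(f"negative event count for {k}")
        if sum(self.events.values()) > self.n_angiosperm:
            raise ConfigError(
                "more per-species events than ancestral family genes to act on"
            )
        if not (0 <= self.wgd_retention <= 1):
            raise ConfigError("wgd_retention outside [0, 1]")
        if not (0 <= self.loss_probability < 1):
            raise ConfigError("loss_probability outside [0, 1)")
        if self.background_genes_per_chromosome < 60 or self.n_chromosomes < 2:
            raise ConfigError("genome too small to place events safely")

    @property
    def species_config(self) -> SpeciesConfig:
        return SpeciesConfig(dict(self.species_groups))


def fixture_config(seed: int = 0) -> SimConfig:
    """The bare ancestry fixture: the canonical lineage topology with no
    per-species duplication events and no loss."""
    return SimConfig(events=dict.fromkeys(EVENT_TYPES, 0), seed=seed)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    species: str
    class_label: str
    ancient_id: int
    seed_id: int | None
    angio_id: int | None
    dup_label: str


@dataclass
class SimTruth:
    genes: dict[str, GeneTruth]
    depth_counts: tuple[int, int, int]
    groups: dict[str, list[frozenset[str]]]  # clade scope -> member sets

    @property
    def family(self) -> set[str]:
        return set(self.genes)

    def labels(self) -> dict[str, str]:
        return {g: t.dup_label for g, t in self.genes.items()}


@dataclass
class SimDataset:
    config: SimConfig
    species_config: SpeciesConfig
    loci: list[GeneLocus]
    hits: list[DomainHit]
    pairs: list[HomologyPair]
    blocks: list[CollinearBlock]
    newick: str
    class_map: dict[str, str]
    proteins: dict[str, str]

    def tree(self) -> AnnotatedGeneTree:
        agt = AnnotatedGeneTree.from_newick(self.newick)
        species = {g.gene_id: g.species for g in self.loci}
        return agt.annotate(species, self.class_map)

    def intra_blocks(self) -> list[CollinearBlock]:
        """Blocks from within-genome comparison (duplication-classifier input)."""
        return [b for b in self.blocks if b.species_a == b.species_b]

    def scope_map(self) -> dict[str, str]:
        return {
            g.gene_id: self.species_config.scope(g.species) for g in self.loci
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "hits": outdir / "hits.tsv",
            "pairs": outdir / "pairs.tsv",
            "blocks": outdir / "blocks.collinearity",
            "tree": outdir / "tree.nwk",
            "species": outdir / "species.tsv",
            "classes": outdir / "classes.tsv",
            "proteins": outdir / "proteins.fasta",
        }
        write_gene_table(self.loci, paths["genes"])
        write_domain_table(self.hits, paths["hits"])
        write_pair_table(self.pairs, paths["pairs"])
        write_collinearity(self.blocks, paths["blocks"])
        Path(paths["tree"]).write_text(self.newick)
        write_species_config(self.species_config, paths["species"])
        write_class_map(self.class_map, paths["classes"])
        write_fasta(self.proteins, paths["proteins"])
        return paths


def write_truth(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tspecies\tclass\tancient_id\tseed_id\tangio_id\tdup_label\n"
        )
        for g in sorted(truth.genes):
            t = truth.genes[g]
            fh.write(
                f"{t.gene_id}\t{t.species}\t{t.class_label}\t{t.ancient_id}\t"
                f"{'' if t.seed_id is None else t.seed_id}\t"
                f"{'' if t.angio_id is None else t.angio_id}\t{t.dup_label}\n"
            )


# ---------------------------------------------------------------------------
# lineage allocation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _AngioLineage:
    angio_id: int
    seed_id: int
    ancient_id: int
    class_label: str


def _split(n_children: int, n_parents: int) -> list[int]:
    base, extra = divmod(n_children, n_parents)
    return [base + 1 if i < extra else base for i in range(n_parents)]


def allocate_lineages(
    cfg: SimConfig,
) -> tuple[list[str], list[tuple[int, str]], list[_AngioLineage]]:
    """(ancient classes, seed lineages as (ancient_id, class), angiosperm lineages).

    The default (7, 11, 18) uses the canonical class layout: two ancient
    lineages in class IA (IA-1 and IA-2), one in each remaining class;
    seed lineages 1/1/2/3/1/1/2 across IA-1/IA-2/IB/IC1-ID/IC2/IE/II; and
    the matching angiosperm expansion. Other depth counts fall back to an
    even round-robin split with cyclic class labels.
    """
    canonical = (cfg.n_ancient, cfg.n_seed, cfg.n_angiosperm) == (7, 11, 18)
    if canonical:
        ancient_classes = list(CLASS_NAMES)
        seed_alloc = [_CANONICAL_SEED_ALLOC[c] for c in ancient_classes]
        angio_alloc_per_class = dict(_CANONICAL_ANGIO_ALLOC)
    else:
        ancient_classes = [
            CLASS_NAMES[i % len(CLASS_NAMES)] if cfg.n_ancient <= len(CLASS_NAMES)
            else f"C{i + 1}"
            for i in range(cfg.n_ancient)
        ]
        seed_alloc = _split(cfg.n_seed, cfg.n_ancient)
        angio_alloc_per_class = None

    seed_lineages: list[tuple[int, str]] = []
    for anc_id, count in enumerate(seed_alloc):
        for _ in range(count):
            seed_lineages.append((anc_id, ancient_classes[anc_id]))

    angio: list[_AngioLineage] = []
    if canonical:
        counters: dict[str, int] = {}
        for seed_id, (anc_id, cls) in enumerate(seed_lineages):
            k = counters.get(cls, 0)
            counters[cls] = k + 1
            n = angio_alloc_per_class[cls][k]
            for _ in range(n):
                angio.append(_AngioLineage(len(angio), seed_id, anc_id, cls))
    else:
        for seed_id, n in enumerate(_split(cfg.n_angiosperm, cfg.n_seed)):
            anc_id, cls = seed_lineages[seed_id]
            for _ in range(n):
                angio.append(_AngioLineage(len(angio), seed_id, anc_id, cls))
    return ancient_classes, seed_lineages, angio


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def simulate(cfg: SimConfig) -> tuple[SimDataset, SimTruth]:
    rng = random.Random(cfg.seed)
    spc = cfg.species_config
    basal_sp = sorted(spc.species_in("bryophyte", "lycophyte"))
    gym_sp = sorted(spc.species_in("gymnosperm"))
    dicot_sp = sorted(spc.species_in("dicot"))
    monocot_sp = sorted(spc.species_in("monocot"))
    angio_sp = dicot_sp + monocot_sp

    ancient_classes, seed_lineages, angio_lineages = allocate_lineages(cfg)

    # -- gene ids ------------------------------------------------------
    def basal_gene(sp: str, anc: int) -> str:
        return f"{sp}_A{anc:02d}"

    def gym_gene(sp: str, seed_id: int) -> str:
        return f"{sp}_S{seed_id:02d}"

    def base_gene(sp: str, angio_id: int) -> str:
        return f"{sp}_L{angio_id:02d}"

    truth_genes: dict[str, GeneTruth] = {}
    for sp in basal_sp:
        for anc, cls in enumerate(ancient_classes):
            g = basal_gene(sp, anc)
            truth_genes[g] = GeneTruth(g, sp, cls, anc, None, None, "singleton")
    for sp in gym_sp:
        for seed_id, (anc, cls) in enumerate(seed_lineages):
            g = gym_gene(sp, seed_id)
            truth_genes[g] = GeneTruth(g, sp, cls, anc, seed_id, None, "singleton")
    for sp in angio_sp:
        for lin in angio_lineages:
            g = base_gene(sp, lin.angio_id)
            truth_genes[g] = GeneTruth(
                g, sp, lin.class_label, lin.ancient_id, lin.seed_id,
                lin.angio_id, "singleton",
            )

    # -- ancestral angiosperm genome layout ---------------------------
    n_bg = cfg.background_genes_per_chromosome
    slot_positions: dict[int, list[tuple[int, int]]] = {
        c: [] for c in range(cfg.n_chromosomes)
    }  # chrom -> [(position, angio_id)]
    for lin in angio_lineages:
        for _ in range(10000):
            c = rng.randrange(cfg.n_chromosomes)
            pos = rng.randrange(10, n_bg - 10)
            if all(abs(pos - p) >= 30 for p, _ in slot_positions[c]):
                slot_positions[c].append((pos, lin.angio_id))
                break
        else:
            raise ConfigError("could not place family genes with safe spacing")
    # ancestral token lists: ("bg", chrom, j) and ("fam", angio_id)
    ancestral: list[list[tuple]] = []
    for c in range(cfg.n_chromosomes):
        row: list[tuple] = [("bg", c, j) for j in range(n_bg)]
        for pos, angio_id in sorted(slot_positions[c], reverse=True):
            row.insert(pos, ("fam", angio_id))
        ancestral.append(row)

    def token_id(sp: str, tok: tuple) -> str:
        if tok[0] == "bg":
            return f"{sp}bgc{tok[1]}g{tok[2]:03d}"
        return base_gene(sp, tok[1])

    # -- species genomes ----------------------------------------------
    genomes: dict[str, list[list[str]]] = {}
    copies_by_lineage: dict[tuple[str, int], list[str]] = {}
    wgd_blocks: list[CollinearBlock] = []
    family_copy_truth: list[GeneTruth] = []

    for sp in angio_sp:
        chroms = [[token_id(sp, t) for t in row] for row in ancestral]
        fam_pos: dict[int, tuple[int, int]] = {}  # angio_id -> (chrom, index)
        for c, row in enumerate(chroms):
            for i, gid in enumerate(row):
                if gid.startswith(f"{sp}_L"):
                    fam_pos[int(gid[-2:])] = (c, i)

        # choose event sources: distinct ancestral family genes
        order = sorted(cfg.events)
        n_events = sum(cfg.events.values())
        sources = rng.sample(sorted(fam_pos), n_events)
        assignments: list[tuple[str, int]] = []  # (event type, angio_id)
        k = 0
        for ev in order:
            for _ in range(cfg.events[ev]):
                assignments.append((ev, sources[k]))
                k += 1

        # family slots sit >= 30 ranks apart, so the small per-event windows
        # reserved below can never collide across different source genes
        reserved: dict[int, list[tuple[int, int]]] = {
            c: [] for c in range(cfg.n_chromosomes)
        }

        def reserve(c: int, lo: int, hi: int) -> bool:
            for rlo, rhi in reserved[c]:
                if lo <= rhi and rlo <= hi:
                    return False
            reserved[c].append((lo, hi))
            return True

        insertions: dict[int, list[tuple[int, str]]] = {
            c: [] for c in range(cfg.n_chromosomes)
        }
        appended: dict[int, list[str]] = {c: [] for c in range(cfg.n_chromosomes)}
        counters = {ev: 0 for ev in EVENT_TYPES}

        for ev, angio_id in assignments:
            c, i = fam_pos[angio_id]
            src = base_gene(sp, angio_id)
            t = truth_genes[src]
            counters[ev] += 1
            copy_id = f"{src}{ev[0]}{counters[ev]}"
            if ev == "tandem":
                if not reserve(c, i, i + 1):
                    raise ConfigError("event window collision")
                insertions[c].append((i + 1, copy_id))
            elif ev == "proximal":
                for _ in range(1000):
                    d = rng.randint(2, 19)
                    if reserve(c, i, i + d):
                        break
                else:
                    raise ConfigError("event window collision")
                insertions[c].append((i + d, copy_id))
            elif ev == "dispersed":
                for _ in range(10000):
                    c2 = rng.randrange(cfg.n_chromosomes)
                    if c2 == c:
                        continue
                    j = rng.randrange(5, len(chroms[c2]) - 5)
                    near_family = any(
                        abs(j - fi) < 25
                        for fc, fi in fam_pos.values()
                        if fc == c2
                    )
                    if near_family:
                        continue
                    if reserve(c2, j - 1, j + 1):
                        break
                else:
                    raise ConfigError("event window collision")
                insertions[c2].append((j, copy_id))
            else:  # wgd: duplicate a small window around the source gene
                if not reserve(c, i - 3, i + 3):
                    raise ConfigError("event window collision")
                c2 = rng.choice([x for x in range(cfg.n_chromosomes) if x != c])
                lo, hi = max(0, i - 2), min(len(chroms[c]) - 1, i + 2)
                anchors: list[tuple[str, str]] = []
                for idx in range(lo, hi + 1):
                    orig = chroms[c][idx]
                    if orig != src and rng.random() >= cfg.wgd_retention:
                        continue
                    dup = f"{orig}w{counters[ev]}" if orig != src else copy_id
                    appended[c2].append(dup)
                    anchors.append((orig, dup))
                wgd_blocks.append(
                    CollinearBlock(
                        block_id=f"{sp}wgd{counters[ev]}",
                        species_a=sp,
                        species_b=sp,
                        anchors=anchors,
                        score=100.0,
                        region_a=f"{sp}chr{c + 1}",
                        region_b=f"{sp}chr{c2 + 1}",
                    )
                )
            # truth for source and family copy
            truth_genes[src] = GeneTruth(
                src, sp, t.class_label, t.ancient_id, t.seed_id, t.angio_id, ev
            )
            family_copy_truth.append(
                GeneTruth(
                    copy_id, sp, t.class_label, t.ancient_id, t.seed_id,
                    t.angio_id, ev,
                )
            )
            copies_by_lineage.setdefault((sp, angio_id), []).append(copy_id)

        for c in range(cfg.n_chromosomes):
            for idx, gid in sorted(insertions[c], reverse=True):
                chroms[c].insert(idx, gid)
            chroms[c].extend(appended[c])
        genomes[sp] = chroms

    for t in family_copy_truth:
        truth_genes[t.gene_id] = t

    # gymnosperm / basal genomes: background plus family genes at random slots
    for sp in gym_sp + basal_sp:
        chroms = [
            [f"{sp}bgc{c}g{j:03d}" for j in range(n_bg)]
            for c in range(cfg.n_chromosomes)
        ]
        fam = sorted(g for g, t in truth_genes.items() if t.species == sp)
        for g in fam:
            c = rng.randrange(cfg.n_chromosomes)
            chroms[c].insert(rng.randrange(len(chroms[c])), g)
        genomes[sp] = chroms

    # -- gene loss -----------------------------------------------------
    lost: set[str] = set()
    if cfg.loss_probability > 0:
        for g in sorted(truth_genes):
            if rng.random() < cfg.loss_probability:
                lost.add(g)

    def alive(g: str) -> bool:
        return g not in lost

    # -- gene table ----------------------------------------------------
    family_ids = set(truth_genes)
    loci: list[GeneLocus] = []
    for sp in sorted(genomes):
        for c, row in enumerate(genomes[sp]):
            kept = [g for g in row if alive(g)]
            for i, gid in enumerate(kept):
                start = (i + 1) * 1000
                loci.append(
                    GeneLocus(
                        gene_id=gid,
                        species=sp,
                        chromosome=f"chr{c + 1}",
                        start=start,
                        end=start + 500,
                        strand="+" if rng.random() < 0.5 else "-",
                        locus_id=gid,
                        protein_length=160 if gid in family_ids else 300,
                    )
                )

    # -- homology pairs (top-k per query by simulated similarity) ------
    lineage_members: dict[int, dict[str, list[str]]] = {}
    for lin in angio_lineages:
        per_sp: dict[str, list[str]] = {}
        for sp in angio_sp:
            genes = [base_gene(sp, lin.angio_id)]
            genes += copies_by_lineage.get((sp, lin.angio_id), [])
            genes = [g for g in genes if alive(g)]
            if genes:
                per_sp[sp] = genes
        lineage_members[lin.angio_id] = per_sp

    top_k = 5
    pairs: list[HomologyPair] = []
    for lin in angio_lineages:
        per_sp = lineage_members[lin.angio_id]
        clade_of = {sp: spc.scope(sp) for sp in per_sp}
        all_genes = [(sp, g) for sp in sorted(per_sp) for g in per_sp[sp]]
        for qsp, q in all_genes:
            cands: list[tuple[float, str]] = []
            for ssp, s in all_genes:
                if s == q:
                    continue
                if ssp == qsp:
                    ev = 1e-180
                elif clade_of[ssp] == clade_of[qsp]:
                    ev = 1e-100
                else:
                    ev = 1e-40
                cands.append((ev, s))
            cands.sort()
            for ev, s in cands[:top_k]:
                pairs.append(HomologyPair(q, s, ev))

    # -- collinear blocks ---------------------------------------------
    blocks: list[CollinearBlock] = []
    for clade_species in (dicot_sp, monocot_sp):
        for ai in range(len(clade_species)):
            for bi in range(ai + 1, len(clade_species)):
                a, b = clade_species[ai], clade_species[bi]
                for c, row in enumerate(ancestral):
                    anchors = [
                        (token_id(a, t), token_id(b, t))
                        for t in row
                        if alive(token_id(a, t)) and alive(token_id(b, t))
                    ]
                    if not anchors:
                        continue
                    blocks.append(
                        CollinearBlock(
                            block_id=f"{a}{b}c{c + 1}",
                            species_a=a,
                            species_b=b,
                            anchors=anchors,
                            score=1000.0,
                            region_a=f"{a}chr{c + 1}",
                            region_b=f"{b}chr{c + 1}",
                        )
                    )
    for b in wgd_blocks:
        kept = [(x, y) for x, y in b.anchors if alive(x) and alive(y)]
        if kept:
            blocks.append(
                CollinearBlock(
                    block_id=b.block_id,
                    species_a=b.species_a,
                    species_b=b.species_b,
                    anchors=kept,
                    score=b.score,
                    region_a=b.region_a,
                    region_b=b.region_b,
                )
            )

    # -- gene tree ------------------------------------------------------
    newick = _build_tree(
        cfg, ancient_classes, seed_lineages, angio_lineages,
        basal_sp, gym_sp, dicot_sp, monocot_sp,
        copies_by_lineage, alive,
        basal_gene, gym_gene, base_gene,
    )

    # -- class map, proteins, domain hits ------------------------------
    class_map = {
        g: t.class_label for g, t in truth_genes.items() if alive(g)
    }
    proteins = _make_proteins(rng, class_map, truth_genes)
    hits = _make_hits(rng, sorted(class_map), loci, family_ids)

    # -- truth groups ----------------------------------------------------
    anchor_genes: set[str] = set()
    for b in blocks:
        for x, y in b.anchors:
            if x in family_ids and y in family_ids:
                anchor_genes.add(x)
                anchor_genes.add(y)
    groups: dict[str, list[frozenset[str]]] = {"dicot": [], "monocot": []}
    for scope, clade_species in (("dicot", dicot_sp), ("monocot", monocot_sp)):
        for lin in angio_lineages:
            members = set()
            for sp in clade_species:
                for g in lineage_members[lin.angio_id].get(sp, []):
                    if g in anchor_genes:
                        members.add(g)
            if len(members) >= 2:
                groups[scope].append(frozenset(members))

    truth = SimTruth(
        genes={g: t for g, t in truth_genes.items() if alive(g)},
        depth_counts=(cfg.n_ancient, cfg.n_seed, cfg.n_angiosperm),
        groups=groups,
    )
    dataset = SimDataset(
        config=cfg,
        species_config=spc,
        loci=loci,
        hits=hits,
        pairs=pairs,
        blocks=blocks,
        newick=newick,
        class_map=class_map,
        proteins=proteins,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------


def _ladder(subtrees: list[str]) -> str | None:
    subtrees = [s for s in subtrees if s]
    if not subtrees:
        return None
    cur = subtrees[0]
    for nxt in subtrees[1:]:
        cur = f"({cur},{nxt})1:0.1"
    return cur


def _leaf(gid: str) -> str:
    return f"{gid}:0.1"


def _build_tree(
    cfg, ancient_classes, seed_lineages, angio_lineages,
    basal_sp, gym_sp, dicot_sp, monocot_sp,
    copies_by_lineage, alive, basal_gene, gym_gene, base_gene,
) -> str:
    def species_subtree(sp: str, angio_id: int) -> str | None:
        genes = [base_gene(sp, angio_id)] + copies_by_lineage.get(
            (sp, angio_id), []
        )
        return _ladder([_leaf(g) for g in genes if alive(g)])

    def angio_subtree(lin) -> str | None:
        dic = _ladder(
            [s for sp in dicot_sp if (s := species_subtree(sp, lin.angio_id))]
        )
        mono = _ladder(
            [s for sp in monocot_sp if (s := species_subtree(sp, lin.angio_id))]
        )
        return _ladder([t for t in (dic, mono) if t])

    def seed_subtree(seed_id: int) -> str | None:
        gym = _ladder(
            [_leaf(gym_gene(sp, seed_id)) for sp in gym_sp
             if alive(gym_gene(sp, seed_id))]
        )
        ang = _ladder(
            [t for lin in angio_lineages if lin.seed_id == seed_id
             if (t := angio_subtree(lin))]
        )
        return _ladder([t for t in (gym, ang) if t])

    ancient_subtrees = []
    for anc in range(cfg.n_ancient):
        basal = _ladder(
            [_leaf(basal_gene(sp, anc)) for sp in basal_sp
             if alive(basal_gene(sp, anc))]
        )
        seeds = _ladder(
            [t for sid, (a, _) in enumerate(seed_lineages) if a == anc
             if (t := seed_subtree(sid))]
        )
        sub = _ladder([t for t in (basal, seeds) if t])
        if sub:
            ancient_subtrees.append(sub)
    root = _ladder(ancient_subtrees)
    if root is None:
        raise ConfigError("empty tree: every gene was lost")
    # strip the root's trailing support:length decoration
    if root.endswith(")1:0.1"):
        root = root[: -len("1:0.1")]
    return root + ";\n"


# ---------------------------------------------------------------------------
# proteins and domain hits
# ---------------------------------------------------------------------------

_CLASS_MOTIF = {
    "IA-1": "AAYIGP",  # diagnostic block downstream of the domain
    "IA-2": "SKYQ",    # diagnostic block immediately after the domain
    "II": "LDLSLNL",   # EAR-type LxLxL repression motif
}


def _make_proteins(
    rng: random.Random,
    class_map: Mapping[str, str],
    truth: Mapping[str, GeneTruth],
) -> dict[str, str]:
    classes = sorted(set(class_map.values()))
    domain_consensus = "".join(rng.choice(_AA) for _ in range(_PROFILE_LEN))
    class_consensus: dict[str, str] = {}
    for cls in classes:
        dom = list(domain_consensus)
        for pos in rng.sample(range(_PROFILE_LEN), 10):
            dom[pos] = rng.choice(_AA)
        tail = [rng.choice(_AA) for _ in range(60)]
        motif = _CLASS_MOTIF.get(cls)
        protected: set[int] = set()
        if motif:
            for i, ch in enumerate(motif):
                tail[2 + i] = ch
                protected.add(2 + i)
        class_consensus[cls] = "".join(dom) + "".join(tail)
    protected_tail = {
        cls: set(range(2, 2 + len(_CLASS_MOTIF.get(cls, ""))))
        for cls in classes
    }
    proteins: dict[str, str] = {}
    for gene in sorted(class_map):
        cls = class_map[gene]
        seq = list(class_consensus[cls])
        for i in range(len(seq)):
            if i >= _PROFILE_LEN and (i - _PROFILE_LEN) in protected_tail[cls]:
                continue
            if rng.random() < 0.02:
                seq[i] = rng.choice(_AA)
        proteins[gene] = "".join(seq)
    return proteins


def _make_hits(
    rng: random.Random,
    family: Sequence[str],
    loci: Sequence[GeneLocus],
    family_ids: set[str],
) -> list[DomainHit]:
    hits: list[DomainHit] = []
    for g in family:
        frm = rng.randint(1, 4)
        to = rng.randint(96, _PROFILE_LEN)
        hits.append(
            DomainHit(
                protein_id=g,
                profile_name=_PROFILE,
                profile_length=_PROFILE_LEN,
                hmm_from=frm,
                hmm_to=to,
                evalue=10 ** -rng.uniform(20, 60),
                score=round(rng.uniform(80, 200), 1),
            )
        )
    # decoy hits on background genes: each fails exactly one gate (or
    # targets another profile) so detection must reject them
    background = [g.gene_id for g in loci if g.gene_id not in family_ids]
    decoys = rng.sample(background, min(12, len(background)))
    for i, g in enumerate(decoys):
        kind = i % 3
        if kind == 0:  # coverage below threshold
            hits.append(DomainHit(g, _PROFILE, _PROFILE_LEN, 10, 70, 1e-20, 50.0))
        elif kind == 1:  # E-value above threshold
            hits.append(DomainHit(g, _PROFILE, _PROFILE_LEN, 1, 99, 1e-3, 20.0))
        else:  # different profile
            hits.append(DomainHit(g, "OtherDom", 80, 1, 80, 1e-30, 90.0))
    return hits


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

PERTURB_OPS = ("drop_gene", "shuffle_leaf_order", "downgrade_support")


def perturb(dataset: SimDataset, op: str, seed: int = 0) -> SimDataset:
    """Apply exactly one perturbation; returns a new dataset.

    drop_gene removes one random family gene from every file; the tree
    searches should degrade gracefully, never over-count.
    shuffle_leaf_order rotates children orders — a pure re-serialization
    that must leave every inference invariant.
    downgrade_support sets one random internal support to 0.5, below any
    recommended gate.
    """
    rng = random.Random(seed)
    if op == "drop_gene":
        gene = rng.choice(sorted(dataset.class_map))
        return remove_genes(dataset, {gene})
    if op == "shuffle_leaf_order":
        agt = dataset.tree()
        for node in agt.tree.preorder_node_iter():
            children = node.child_nodes()
            if len(children) > 1:
                rng.shuffle(children)
                node.set_child_nodes(children)
        new = _copy_dataset(dataset)
        new.newick = agt.to_newick()
        return new
    if op == "downgrade_support":
        agt = dataset.tree()
        internal = [
            n for n in agt.tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        node = rng.choice(internal)
        node.support = 0.5
        new = _copy_dataset(dataset)
        new.newick = agt.to_newick()
        return new
    raise ConfigError(f"unknown perturbation {op!r}")


def _copy_dataset(dataset: SimDataset) -> SimDataset:
    return SimDataset(
        config=dataset.config,
        species_config=dataset.species_config,
        loci=list(dataset.loci),
        hits=list(dataset.hits),
        pairs=list(dataset.pairs),
        blocks=list(dataset.blocks),
        newick=dataset.newick,
        class_map=dict(dataset.class_map),
        proteins=dict(dataset.proteins),
    )


def remove_genes(dataset: SimDataset, genes: set[str]) -> SimDataset:
    new = _copy_dataset(dataset)
    new.loci = [g for g in dataset.loci if g.gene_id not in genes]
    new.hits = [h for h in dataset.hits if h.protein_id not in genes]
    new.pairs = [
        p for p in dataset.pairs
        if p.query_id not in genes and p.subject_id not in genes
    ]
    new.blocks = []
    for b in dataset.blocks:
        kept = [
            (x, y) for x, y in b.anchors if x not in genes and y not in genes
        ]
        if kept:
            new.blocks.append(
                CollinearBlock(
                    b.block_id, b.species_a, b.species_b, kept, b.score,
                    b.region_a, b.region_b,
                )
            )
    new.class_map = {
        g: c for g, c in dataset.class_map.items() if g not in genes
    }
    new.proteins = {
        g: s for g, s in dataset.proteins.items() if g not in genes
    }
    agt = dataset.tree()
    agt.tree.prune_taxa_with_labels(sorted(genes), suppress_unifurcations=True)
    for node in agt.tree:
        if not hasattr(node, "support"):
            node.support = None
    new.newick = agt.to_newick()
    return new
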