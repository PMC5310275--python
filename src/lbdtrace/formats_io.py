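"""Readers and writers for the external formats the pipeline touches.

Dialects
--------
Gene table
    8-column TSV with a header row naming the fields of :class:`GeneLocus`
    (``species, gene_id, chromosome, start, end, strand, locus_id,
    protein_length``). Coordinates are 1-based inclusive (GFF convention);
    gene order ("rank") is always derived from coordinates, never stored.

Domain table
    7-column TSV with header ``protein_id, profile_name, profile_length,
    hmm_from, hmm_to, evalue, score`` — a documented projection of the
    HMMER3 per-domain tabular output onto the fields the detection rule
    needs. Converting a native ``--domtblout`` file amounts to selecting
    columns 1 (target name), 4 (query name), 6 (qlen), 16 (hmm from),
    17 (hmm to), 13 (i-Evalue) and 14 (score).

Collinearity
    The MCScanX ``.collinearity`` dialect: ``## Alignment N: ...`` block
    headers followed by anchor lines ``N-i: geneA geneB evalue``. Lines
    starting with ``#`` that are not block headers are comments.

Trees
    Newick. Internal node labels, when present, are support values.
    Supports in (1, 100] are treated as percentages and divided by 100;
    values in [0, 1] are fractions; anything outside [0, 100] is an error.
    A missing label is recorded as missing support, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .errors import ConfigError, ParseError, ValidationError

STRANDS = frozenset({"+", "-"})

SPECIES_GROUPS = ("bryophyte", "lycophyte", "gymnosperm", "dicot", "monocot")

GENE_TABLE_COLUMNS = (
    "species",
    "gene_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "locus_id",
    "protein_length",
)

DOMAIN_TABLE_COLUMNS = (
    "protein_id",
    "profile_name",
    "profile_length",
    "hmm_from",
    "hmm_to",
    "evalue",
    "score",
)

PAIR_TABLE_COLUMNS = ("query_id", "subject_id", "evalue")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    """One gene model: genomic placement plus isoform/locus identity.

    Alternative isoforms of one locus share ``locus_id`` (and species);
    ``gene_id`` is unique within a dataset.
    """

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    locus_id: str
    protein_length: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"{self.gene_id}: coordinates are 1-based")
        if self.strand not in STRANDS:
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.protein_length <= 0:
            raise ValidationError(f"{self.gene_id}: non-positive protein length")


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM match, in profile (HMM) coordinates."""

    protein_id: str
    profile_name: str
    profile_length: int
    hmm_from: int
    hmm_to: int
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if not (1 <= self.hmm_from <= self.hmm_to <= self.profile_length):
            raise ValidationError(
                f"{self.protein_id}: hit coordinates "
                f"[{self.hmm_from}, {self.hmm_to}] outside profile of length "
                f"{self.profile_length}"
            )
        if self.evalue < 0:
            raise ValidationError(f"{self.protein_id}: negative E-value")


@dataclass(frozen=True)
class HomologyPair:
    """A BLAST-style homologous gene pair (post isoform collapse)."""

    query_id: str
    subject_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValidationError(f"self-pair {self.query_id}")
        if self.evalue < 0:
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: negative E-value"
            )


@dataclass
class CollinearBlock:
    """An ordered run of anchored gene pairs between two genomic regions."""

    block_id: str
    species_a: str | None
    species_b: str | None
    anchors: list[tuple[str, str]]
    score: float | None = None
    region_a: str | None = None
    region_b: str | None = None

    def __post_init__(self) -> None:
        if len(self.anchors) < 1:
            raise ValidationError(f"block {self.block_id}: no anchors")


@dataclass(frozen=True)
class SpeciesConfig:
    """Maps species codes to major plant groups.

    Groups drive every taxon-aware step: bryophyte/lycophyte species are
    the basal land plants, gymnosperm + dicot + monocot are seed plants,
    dicot and monocot define the collinearity clade scopes.
    """

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        for code, group in self.groups.items():
            if group not in SPECIES_GROUPS:
                raise ConfigError(f"species {code}: unknown group {group!r}")

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.groups)

    def species_in(self, *groups: str) -> frozenset[str]:
        for g in groups:
            if g not in SPECIES_GROUPS:
                raise ConfigError(f"unknown species group {g!r}")
        return frozenset(s for s, g in self.groups.items() if g in groups)

    def scope(self, code: str) -> str:
        """Collinearity clade scope of a species: dicot, monocot or other."""
        group = self.groups.get(code)
        if group is None:
            raise ConfigError(f"unknown species {code!r}")
        return group if group in ("dicot", "monocot") else "other"


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------


def _read_rows(path: str | Path, columns: Sequence[str]) -> Iterable[tuple[int, dict]]:
    """Yield (line_number, row dict) for a headered TSV, validating the header."""
    path = Path(path)
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in columns if c not in header]
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: header missing columns {missing}"
                    )
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            yield lineno, dict(zip(header, fields))
        if header is None and path.stat().st_size > 0:
            # whitespace-only file: treat as empty
            return


def _to_int(value: str, what: str, path: Path, lineno: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad integer for {what}: {value!r}") from exc


def _to_float(value: str, what: str, path: Path, lineno: int) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad number for {what}: {value!r}") from exc


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------


def read_gene_table(path: str | Path) -> list[GeneLocus]:
    """Read a gene-position table; validates invariants and gene_id uniqueness."""
    path = Path(path)
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path, GENE_TABLE_COLUMNS):
        try:
            locus = GeneLocus(
                gene_id=row["gene_id"],
                species=row["species"],
                chromosome=row["chromosome"],
                start=_to_int(row["start"], "start", path, lineno),
                end=_to_int(row["end"], "end", path, lineno),
                strand=row["strand"],
                locus_id=row["locus_id"],
                protein_length=_to_int(
                    row["protein_length"], "protein_length", path, lineno
                ),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        if locus.gene_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate gene_id {locus.gene_id}")
        seen.add(locus.gene_id)
        loci.append(locus)
    return loci


def write_gene_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in loci:
            fh.write(
                f"{g.species}\t{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t"
                f"{g.strand}\t{g.locus_id}\t{g.protein_length}\n"
            )


# ---------------------------------------------------------------------------
# domain table
# ---------------------------------------------------------------------------


def read_domain_table(path: str | Path) -> list[DomainHit]:
    """Read domain hits; returned unsorted and unfiltered."""
    path = Path(path)
    hits: list[DomainHit] = []
    for lineno, row in _read_rows(path, DOMAIN_TABLE_COLUMNS):
        try:
            hit = DomainHit(
                protein_id=row["protein_id"],
                profile_name=row["profile_name"],
                profile_length=_to_int(
                    row["profile_length"], "profile_length", path, lineno
                ),
                hmm_from=_to_int(row["hmm_from"], "hmm_from", path, lineno),
                hmm_to=_to_int(row["hmm_to"], "hmm_to", path, lineno),
                evalue=_to_float(row["evalue"], "evalue", path, lineno),
                score=_to_float(row["score"], "score", path, lineno),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DOMAIN_TABLE_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.profile_name}\t{h.profile_length}\t"
                f"{h.hmm_from}\t{h.hmm_to}\t{h.evalue:g}\t{h.score:g}\n"
            )


# ---------------------------------------------------------------------------
# homology pairs
# ---------------------------------------------------------------------------


def read_pair_table(path: str | Path) -> list[HomologyPair]:
    path = Path(path)
    pairs: list[HomologyPair] = []
    for lineno, row in _read_rows(path, PAIR_TABLE_COLUMNS):
        try:
            pairs.append(
                HomologyPair(
                    query_id=row["query_id"],
                    subject_id=row["subject_id"],
                    evalue=_to_float(row["evalue"], "evalue", path, lineno),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return pairs


def write_pair_table(pairs: Iterable[HomologyPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_TABLE_COLUMNS) + "\n")
        for p in pairs:
            fh.write(f"{p.query_id}\t{p.subject_id}\t{p.evalue:g}\n")


# ---------------------------------------------------------------------------
# collinearity (MCScanX dialect)
# ---------------------------------------------------------------------------


def read_collinearity(
    path: str | Path, loci: Sequence[GeneLocus] | None = None
) -> list[CollinearBlock]:
    """Parse an MCScanX-style ``.collinearity`` file.

    When ``loci`` is supplied, every anchor gene is cross-checked against
    the gene table (unknown gene -> :class:`ValidationError`) and the
    block's species pair is filled in from the first anchor.
    """
    path = Path(path)
    by_id = {g.gene_id: g for g in loci} if loci is not None else None
    blocks: list[CollinearBlock] = []
    current: CollinearBlock | None = None

    def flush() -> None:
        nonlocal current
        if current is not None:
            if not current.anchors:
                raise ParseError(
                    f"{path}: block {current.block_id} has no anchor lines"
                )
            blocks.append(current)
            current = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("## Alignment"):
                flush()
                # "## Alignment 0: score=500.0 e_value=1e-20 N=5 chrA&chrB plus"
                head = line[len("## Alignment"):].strip()
                block_id, _, rest = head.partition(":")
                score = None
                region_a = region_b = None
                for token in rest.split():
                    if token.startswith("score="):
                        try:
                            score = float(token[len("score="):])
                        except ValueError as exc:
                            raise ParseError(
                                f"{path}:{lineno}: bad score in {token!r}"
                            ) from exc
                    elif "&" in token:
                        region_a, _, region_b = token.partition("&")
                current = CollinearBlock(
                    block_id=block_id.strip(),
                    species_a=None,
                    species_b=None,
                    anchors=[("_pending_", "_pending_")],
                    score=score,
                    region_a=region_a,
                    region_b=region_b,
                )
                current.anchors.clear()
                continue
            if line.startswith("#"):
                continue
            # anchor line: "N-i: geneA geneB evalue"
            if current is None:
                raise ParseError(
                    f"{path}:{lineno}: anchor line outside any '## Alignment' block"
                )
            body = line.split(":", 1)
            if len(body) != 2:
                raise ParseError(f"{path}:{lineno}: malformed anchor line {line!r}")
            fields = body[1].split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: malformed anchor line {line!r}")
            gene_a, gene_b = fields[0], fields[1]
            if by_id is not None:
                for g in (gene_a, gene_b):
                    if g not in by_id:
                        raise ValidationError(
                            f"{path}:{lineno}: anchor gene {g!r} absent from gene table"
                        )
                if current.species_a is None:
                    current.species_a = by_id[gene_a].species
                    current.species_b = by_id[gene_b].species
            current.anchors.append((gene_a, gene_b))
    flush()
    return blocks


def write_collinearity(blocks: Iterable[CollinearBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("############### lbdtrace collinearity ###############\n")
        for b in blocks:
            score = f"score={b.score:g} " if b.score is not None else ""
            region = ""
            if b.region_a and b.region_b:
                region = f" {b.region_a}&{b.region_b} plus"
            fh.write(f"## Alignment {b.block_id}: {score}N={len(b.anchors)}{region}\n")
            for i, (ga, gb) in enumerate(b.anchors):
                fh.write(f"{b.block_id}-{i:>3}:\t{ga}\t{gb}\t0\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def normalize_support(value: float) -> float:
    """Map a raw support label to [0, 1].

    Values in (1, 100] are percentages; values in [0, 1] are fractions;
    anything else is an error. Idempotent on already-normalized values.
    """
    if math.isnan(value) or value < 0 or value > 100:
        raise ValidationError(f"support value {value!r} outside [0, 100]")
    return value / 100.0 if value > 1 else value


class AnnotatedGeneTree:
    """A rooted gene tree plus per-leaf species / class annotations.

    Wraps a :class:`dendropy.Tree`. Leaf taxon labels are gene ids.
    Internal-node supports live on ``node.support`` (float in [0, 1] or
    ``None`` for missing) after :func:`read_newick_tree`.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        species: Mapping[str, str] | None = None,
        class_labels: Mapping[str, str] | None = None,
    ) -> None:
        self.tree = tree
        self.species = dict(species or {})
        self.class_labels = dict(class_labels or {})
        for node in tree:
            if not hasattr(node, "support"):
                node.support = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "AnnotatedGeneTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                rooting="force-rooted",
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise ParseError(f"bad Newick: {exc}") from exc
        agt = cls(tree)
        for node in tree:
            node.support = None
            if node.is_leaf():
                continue
            if node.label is not None and node.label != "":
                try:
                    raw = float(node.label)
                except ValueError as exc:
                    raise ParseError(
                        f"internal node label {node.label!r} is not a numeric support"
                    ) from exc
                node.support = normalize_support(raw)
        return agt

    def annotate(
        self,
        species: Mapping[str, str],
        class_labels: Mapping[str, str] | None = None,
    ) -> "AnnotatedGeneTree":
        self.species = dict(species)
        if class_labels is not None:
            self.class_labels = dict(class_labels)
        return self

    def clone(self) -> "AnnotatedGeneTree":
        cloned = dendropy.Tree(self.tree)  # deep structural copy
        # dendropy's copy constructor does not carry ad-hoc attributes
        for src, dst in zip(
            self.tree.preorder_node_iter(), cloned.preorder_node_iter()
        ):
            dst.support = getattr(src, "support", None)
        return AnnotatedGeneTree(cloned, self.species, self.class_labels)

    # -- queries -------------------------------------------------------

    def leaf_gene_ids(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node_genes(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def node_species(self, node: dendropy.Node) -> frozenset[str]:
        out = set()
        for leaf in node.leaf_iter():
            sp = self.species.get(leaf.taxon.label)
            if sp is None:
                raise ValidationError(
                    f"leaf {leaf.taxon.label!r} has no species annotation"
                )
            out.add(sp)
        return frozenset(out)

    # -- serialization -------------------------------------------------

    def to_newick(self) -> str:
        for node in self.tree:
            if not node.is_leaf():
                s = getattr(node, "support", None)
                node.label = None if s is None else _format_support(s)
        out = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return out.strip() + ("\n" if not out.endswith("\n") else "")

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())


def _format_support(s: float) -> str:
    txt = f"{s:.6f}".rstrip("0").rstrip(".")
    return txt if txt else "0"


def read_newick_tree(path: str | Path) -> AnnotatedGeneTree:
    """Read a Newick tree; supports normalized to [0, 1], absent -> missing."""
    return AnnotatedGeneTree.from_newick(Path(path).read_text())


def write_newick_tree(tree: AnnotatedGeneTree, path: str | Path) -> None:
    tree.write(path)


# ---------------------------------------------------------------------------
# species config / gene class maps
# ---------------------------------------------------------------------------


def read_species_config(path: str | Path) -> SpeciesConfig:
    """Read a 2-column TSV (species, group) into a :class:`SpeciesConfig`."""
    path = Path(path)
    groups: dict[str, str] = {}
    for lineno, row in _read_rows(path, ("species", "group")):
        code = row["species"]
        if code in groups:
            raise ValidationError(f"{path}:{lineno}: duplicate species {code}")
        groups[code] = row["group"]
    return SpeciesConfig(groups)


def write_species_config(cfg: SpeciesConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tgroup\n")
        for code in sorted(cfg.groups):
            fh.write(f"{code}\t{cfg.groups[code]}\n")


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (gene_id, class) mapping genes to subfamily labels."""
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, row in _read_rows(path, ("gene_id", "class")):
        if row["gene_id"] in out:
            raise ValidationError(f"{path}:{lineno}: duplicate gene {row['gene_id']}")
        out[row["gene_id"]] = row["class"]
    return out


def write_class_map(classes: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\n")
        for gene in sorted(classes):
            fh.write(f"{gene}\t{classes[gene]}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
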