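"""End-to-end orchestration: detect -> classify -> groups -> ancestry -> report.

A single config drives the run; every stage is also callable on its own
from intermediates. The manifest records the package version, all
parameters, input checksums and per-stage record counts, so identical
config + inputs give byte-identical outputs and manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .ancestry_inference import (
    ancestry_report,
    collinearity_support,
    find_ancient_lineages,
    find_angiosperm_ancestors,
    find_seed_ancestors,
    write_clusters,
    write_report,
)
from .collinearity_grouping import family_pairs, merge_groups, write_groups
from .duplication_classifier import (
    ClassifierConfig,
    assign_ranks,
    classify,
    duplication_summary,
)
from .errors import ConfigError
from .family_detection import DetectionConfig, collapse_isoforms, domain_coverage, filter_candidates
from .formats_io import (
    read_class_map,
    read_collinearity,
    read_domain_table,
    read_gene_table,
    read_newick_tree,
    read_pair_table,
    read_species_config,
)

log = logging.getLogger("lbdtrace")


@dataclass
class RunConfig:
    genes: Path
    hits: Path
    pairs: Path
    blocks: Path
    tree: Path
    species: Path
    classes: Path | None
    outdir: Path
    max_evalue: float = 1e-5
    min_coverage: float = 0.80
    profile_name: str = "DUF260"
    proximal_window: int = 20
    min_support: float | None = None
    dicot_min: int | None = None
    monocot_min: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        base = Path(path).parent
        kwargs: dict[str, Any] = {}
        for key in ("genes", "hits", "pairs", "blocks", "tree", "species"):
            if key not in raw:
                raise ConfigError(f"{path}: missing required path {key!r}")
            kwargs[key] = (base / raw[key]).resolve()
        kwargs["classes"] = (
            (base / raw["classes"]).resolve() if raw.get("classes") else None
        )
        kwargs["outdir"] = (base / raw.get("outdir", "lbdtrace_out")).resolve()
        for key in (
            "max_evalue", "min_coverage", "profile_name", "proximal_window",
            "min_support", "dicot_min", "monocot_min",
        ):
            if key in raw and raw[key] is not None:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def validate_inputs(self) -> None:
        for key in ("genes", "hits", "pairs", "blocks", "tree", "species"):
            p = getattr(self, key)
            if not Path(p).is_file():
                raise ConfigError(f"input file for stage {key!r} not found: {p}")
        if self.classes is not None and not Path(self.classes).is_file():
            raise ConfigError(f"classes file not found: {self.classes}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    cfg.validate_inputs()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "parameters": {
            "max_evalue": cfg.max_evalue,
            "min_coverage": cfg.min_coverage,
            "profile_name": cfg.profile_name,
            "proximal_window": cfg.proximal_window,
            "min_support": cfg.min_support,
            "dicot_min": cfg.dicot_min,
            "monocot_min": cfg.monocot_min,
        },
        "inputs": {
            key: {"path": str(getattr(cfg, key)), "sha256": _sha256(getattr(cfg, key))}
            for key in ("genes", "hits", "pairs", "blocks", "tree", "species")
            if getattr(cfg, key) is not None
        },
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        return t0

    def done(name, t0, **counts):
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            **counts,
        }
        log.info("stage %s: %s", name, counts)

    try:
        t0 = stage("detect")
        loci = read_gene_table(cfg.genes)
        hits = read_domain_table(cfg.hits)
        species_cfg = read_species_config(cfg.species)
        det = DetectionConfig(cfg.max_evalue, cfg.min_coverage, cfg.profile_name)
        candidates = filter_candidates(hits, det)
        family = collapse_isoforms(candidates, loci)
        by_id = {g.gene_id: g for g in loci}
        best = {}
        for h in hits:
            if h.protein_id in family and h.profile_name == det.profile_name:
                cur = best.get(h.protein_id)
                if cur is None or h.evalue < cur.evalue:
                    best[h.protein_id] = h
        with open(outdir / "members.tsv", "w") as fh:
            fh.write("gene_id\tspecies\tbest_coverage\tbest_evalue\n")
            for g in sorted(family):
                h = best[g]
                fh.write(
                    f"{g}\t{by_id[g].species}\t{domain_coverage(h):.4f}\t"
                    f"{h.evalue:g}\n"
                )
        done("detect", t0, candidates=len(candidates), family=len(family))

        t0 = stage("classify")
        pairs = read_pair_table(cfg.pairs)
        blocks = read_collinearity(cfg.blocks, loci)
        intra = [b for b in blocks if b.species_a == b.species_b]
        ranks = assign_ranks(loci)
        labels = classify(
            (g.gene_id for g in loci), pairs, intra, ranks,
            ClassifierConfig(proximal_window=cfg.proximal_window),
        )
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("gene_id\tlabel\n")
            for l in labels:
                fh.write(f"{l.gene_id}\t{l.label}\n")
        species_map = {g.gene_id: g.species for g in loci}
        summary = duplication_summary(labels, family, species_map)
        summary.to_csv(outdir / "duplication_summary.tsv", sep="\t")
        label_counts: dict[str, int] = {}
        fam_labels = {l.gene_id: l.label for l in labels if l.gene_id in family}
        for lab in fam_labels.values():
            label_counts[lab] = label_counts.get(lab, 0) + 1
        done("classify", t0, genes=len(labels), **label_counts)

        t0 = stage("groups")
        fpairs = family_pairs(blocks, family)
        scope_map = {g.gene_id: species_cfg.scope(g.species) for g in loci}
        groups_by_scope = {}
        for scope in ("dicot", "monocot"):
            scoped = [p for p in fpairs if scope_map[p[0]] == scope]
            groups = merge_groups(scoped, scope_map, species_map)
            groups_by_scope[scope] = groups
            write_groups(groups, outdir / f"groups_{scope}.tsv", species_map)
        done(
            "groups", t0, family_pairs=len(fpairs),
            dicot_groups=len(groups_by_scope["dicot"]),
            monocot_groups=len(groups_by_scope["monocot"]),
        )

        t0 = stage("ancestry")
        agt = read_newick_tree(cfg.tree)
        class_map = read_class_map(cfg.classes) if cfg.classes else {}
        agt.annotate(species_map, class_map)
        ancient = find_ancient_lineages(agt, species_cfg, cfg.min_support)
        seed = find_seed_ancestors(agt, species_cfg, cfg.min_support)
        angio = find_angiosperm_ancestors(
            agt, species_cfg, cfg.min_support, cfg.dicot_min, cfg.monocot_min
        )
        collinearity_support(
            angio, groups_by_scope["dicot"], groups_by_scope["monocot"]
        )
        report = ancestry_report(ancient, seed, angio)
        write_clusters([*ancient, *seed, *angio], outdir / "clusters.tsv")
        write_report(report, outdir)
        done(
            "ancestry", t0,
            ancient=len(ancient), seed=len(seed), angiosperm=len(angio),
            collinearity_supported=sum(
                1 for c in angio if c.collinearity_supported
            ),
        )
        manifest["depth_counts"] = report.counts_tuple()
    except Exception:
        # partial outputs from a failed run are not trustworthy
        (outdir / "STALE").write_text(
            "run aborted; outputs beyond the last manifest stage are stale\n"
        )
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
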