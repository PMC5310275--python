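"""Family-membership detection from profile-HMM domain hits.

A protein belongs to the family iff at least one of its hits to the family
profile simultaneously passes the E-value gate and covers at least the
configured fraction of the profile model. Coverage is measured in profile
(HMM) coordinates — the rule is about how much of the *domain model* is
matched, not how much of the target sequence. Alternative isoforms are then
collapsed to one representative gene per locus (longest protein wins, ties
to the lexicographically smallest gene id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, ValidationError
from .formats_io import DomainHit, GeneLocus


@dataclass(frozen=True)
class DetectionConfig:
    """Gates of the detection rule.

    max_evalue: per-domain E-value ceiling (inclusive). Default 1e-5, the
        operational reading of the profile's gathering threshold.
    min_coverage: minimum fraction of profile columns matched (inclusive).
        Default 0.80.
    profile_name: the family-defining profile. Default "DUF260", the
        LOB/AS2 domain.
    """

    max_evalue: float = 1e-5
    min_coverage: float = 0.80
    profile_name: str = "DUF260"

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= 1):
            raise ConfigError(f"min_coverage {self.min_coverage} outside (0, 1]")
        if self.max_evalue <= 0:
            raise ConfigError(f"max_evalue {self.max_evalue} must be positive")


def domain_coverage(hit: DomainHit) -> float:
    """Fraction of profile columns spanned by the hit, in (0, 1]."""
    return (hit.hmm_to - hit.hmm_from + 1) / hit.profile_length


def hit_passes(hit: DomainHit, cfg: DetectionConfig) -> bool:
    """Both gates, evaluated on one hit; boundary values pass."""
    return (
        hit.profile_name == cfg.profile_name
        and hit.evalue <= cfg.max_evalue
        and domain_coverage(hit) >= cfg.min_coverage
    )


def filter_candidates(
    hits: Iterable[DomainHit], cfg: DetectionConfig | None = None
) -> set[str]:
    """Proteins with >=1 single hit passing both gates for the family profile."""
    cfg = cfg or DetectionConfig()
    return {h.protein_id for h in hits if hit_passes(h, cfg)}


def collapse_isoforms(
    members: Iterable[str], loci: Sequence[GeneLocus] | Mapping[str, GeneLocus]
) -> set[str]:
    """One representative gene per locus among the member proteins.

    Representative = longest protein_length; ties broken by the
    lexicographically smallest gene_id.
    """
    if isinstance(loci, Mapping):
        by_id = dict(loci)
    else:
        by_id = {g.gene_id: g for g in loci}
    members = set(members)
    missing = sorted(m for m in members if m not in by_id)
    if missing:
        raise ValidationError(
            f"{len(missing)} member(s) without a locus mapping: {missing[:10]}"
        )
    best: dict[tuple[str, str], GeneLocus] = {}
    for m in sorted(members):
        g = by_id[m]
        key = (g.species, g.locus_id)
        cur = best.get(key)
        if cur is None or (g.protein_length, _neg(g.gene_id)) > (
            cur.protein_length,
            _neg(cur.gene_id),
        ):
            best[key] = g
    return {g.gene_id for g in best.values()}


class _neg:
    """Inverts string ordering so 'larger tuple wins' keeps the smaller id."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_neg") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_neg") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg) and self.s == other.s


def detect_family(
    hits: Iterable[DomainHit],
    loci: Sequence[GeneLocus],
    cfg: DetectionConfig | None = None,
) -> set[str]:
    """filter_candidates followed by collapse_isoforms."""
    cfg = cfg or DetectionConfig()
    return collapse_isoforms(filter_candidates(hits, cfg), loci)
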