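# Methods

## The model

A gene family in land plants is treated as a set of *lineages*: ancestral
genes whose descendants form clades in the gene tree and runs of collinear
orthologs in extant genomes. Three evolutionary depths are distinguished —
early land plants (before the bryophyte/lycophyte vs seed-plant split),
the seed-plant ancestor, and the angiosperm (dicot + monocot) ancestor.
Lineage counts at the three depths are inferred purely from tree topology
and species annotations; divergence dating, reconciliation cost models and
tree inference itself are out of scope (trees, domain hits, homology pairs
and collinear blocks are inputs produced by standard external tools).

## Family detection

A protein is a family member iff **one single hit** to the family profile
passes both gates: per-domain E-value ≤ `max_evalue` (default 1e-5, the
operational reading of the curated gathering threshold) and profile
coverage `(hmm_to − hmm_from + 1) / profile_length` ≥ `min_coverage`
(default 0.80). Coverage is measured in profile (HMM) coordinates because
the criterion is about how much of the *domain model* is matched. A hit is
the unit of evidence: one hit passing the E-value gate and another passing
the coverage gate do not combine. The per-domain (not full-sequence)
E-value is used; both thresholds are configurable and boundary values
pass. Alternative isoforms are collapsed to one representative per locus:
longest protein, ties to the lexicographically smallest gene id.

## Duplication typing

Gene order ("rank") is computed per (species, chromosome) by sorting on
(start, end, gene_id); it is always derived, never stored. Each gene gets
exactly one label by strict priority:

1. **wgd** — the gene appears in any collinear-block anchor;
2. **tandem** — a same-chromosome homology partner at rank distance 1
   (genome-wide adjacency over *all* genes, not family-only);
3. **proximal** — a same-chromosome partner at distance in (1, 20); the
   "fewer than 20 genes" window is an exclusive bound (19 qualifies);
4. **dispersed** — any homology partner in the same genome;
5. **singleton** — none of the above.

Two deliberate choices: homology pairs are symmetrized before
classification (BLAST top-k lists are asymmetric, duplication is not), and
only *same-genome* partners count — duplication is an intra-genome notion,
matching the per-genome self-comparison that produces the input pairs. For
the same reason the pipeline feeds the classifier only intra-genome blocks
(`species_a == species_b`), while collinearity grouping sees all blocks.
Genes in both tandem and proximal configurations with different partners
resolve by the cascade order (tandem wins).

## Collinear groups

Family-internal anchor pairs (both genes family members, deduplicated as
unordered pairs) are merged into groups as the connected components of the
pair graph — the only closure consistent with recursive/iterative merging
of collinear genes. Dicots and monocots are merged separately (their
scopes come from the species config, not hard-coded species lists); a pair
spanning scopes is an error signalling mis-scoped input. Intra-genome
pairs participate when present. Components of size ≥ 2 are emitted, sorted
by smallest member id. Deeper merging across the dicot/monocot split is
intentionally not attempted: genome rearrangement erases the blocks that
would justify it.

## Ancestral lineage inference

All searches run on a rooted tree (`root_tree` supports outgroup and
midpoint rooting) whose leaves map to species, with an optional gene →
subfamily class map used only to label the resulting clusters (majority
class, ties lexicographic).

A *taxon requirement* is a list of clauses; a clause holds on a clade when
at least `min_species` distinct species from its species set occur among
the clade's leaves. `minimal_complete_clades` returns, by a single
post-order pass, the clades satisfying every clause with no qualifying
strict descendant; such clades are provably pairwise disjoint.

* **Seed depth**: clauses = {≥ 1 gymnosperm species} plus one clause per
  analyzed angiosperm species. Whether the "all analyzed species"
  criterion should also demand bryophytes/lycophytes is ambiguous in the
  underlying analysis; this implementation requires gymnosperm + all
  angiosperms, and the clause set is configurable.
* **Angiosperm depth**: clauses = {≥ `dicot_min` dicot species} and
  {≥ `monocot_min` monocot species}, defaults "all of each". Clauses are
  presence-only, so non-angiosperm leaves inside a clade are transparent:
  they neither satisfy nor block a clause. Strict exclusion is deliberately
  not imposed — with stem duplications, gymnosperm orthologs interleave
  inside angiosperm clades and exclusion would undercount.
* **Ancient depth**: "neighboring" is formalized as a sister-clade test —
  a maximal clade whose leaves are exclusively bryophyte/lycophyte attests
  an ancient lineage iff its sister clade contains ≥ 1 gene of every
  analyzed seed-plant species (clause set configurable). This is the only
  topology-checkable reading of "neighbors with all seed plants"; users
  should be aware it is a formalization choice.

`min_support` defaults to `None` (pure topology); 0.95 is recommended when
supports are SH-aLRT values, mirroring the >94 % verification practice.
The gate applies at the qualifying node only; a support-less node directly
above leaves passes (cherry labels are routinely absent). Supports in
(1, 100] are read as percentages, [0, 1] as fractions, anything else is an
error; missing is recorded as missing, never zero. Multifurcations are
used as-is, never arbitrarily resolved.

An angiosperm cluster is **collinearity-supported** iff all of its dicot
members that occur in any dicot group occur in one single group, likewise
for monocots, and at least one member is grouped at all — so a cluster
with no grouped member is flagged unsupported (the signature of a lineage
whose blocks were obscured by massive duplication).

The report nests clusters by clade containment (angiosperm → seed → the
ancient lineage whose attesting clade, basal cluster plus sister, contains
it); containment failures are reported as "unassigned", never dropped.

## Branch-model LRT

`2·(ℓ₁ − ℓ₀)` is compared to the upper tail of χ²(df). The alternative
must nest the null to tolerance 1e-6; a worse alternative likelihood
signals a failed upstream optimization and is an error, while differences
within the tolerance clamp the statistic to 0. `df` is an explicit
argument (1 for one extra ω); a warning is emitted when it disagrees with
the omega counts of the fits. p is never rounded internally; presentation
rounds to 4 significant decimals. Restart strategies for the ω optimizer
are the concern of the upstream ML program, not of this module. The codeml
reader scrapes `lnL` and one-ratio (`omega (dN/dS) = …`) or branch-model
(`w (dN/dS) for branches: …`) lines from main result files.

## Sequence profiles

Column information content is IC = log₂20 − H with gaps excluded from the
frequency denominator and no small-sample correction (that correction is
presentation-only in logo renderers; omitting it keeps the math exact and
deterministic). An all-gap column has IC 0 and gap fraction 1. Note that
appending a duplicate of a *single* sequence can move IC in either
direction (it shifts frequencies toward that sequence's residues);
duplicating the entire alignment leaves IC unchanged, and the tests assert
the latter. Motif matching is case-insensitive, `x` is the only wildcard,
and overlapping matches are all reported, 1-based.

## The synthetic-data generator

`simulate(SimConfig)` emulates the study design: 11 species (bryophyte
Ppa, lycophyte Smo, gymnosperm Pab, dicots Aco/Ath/Egr/Ptr/Vvi, monocots
Osa/Sbi/Zma), 7 ancient lineages expanding to 11 seed-plant and 18
angiosperm lineages through the canonical per-class layout (class IA split
into IA-1/IA-2 ancient lineages; seed clusters 3/2/2/2/1/1 across
IC1-ID/IA/IB/II/IC2/IE), then per-angiosperm-species duplication events.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| depth counts | 7 / 11 / 18 | the reconstructed lineage complement |
| events per angiosperm species | 6 wgd, 3 tandem, 2 proximal, 5 dispersed | ~34 family genes per angiosperm, the reported scale of expansion |
| wgd_retention | 0.5 | typical post-WGD retention of block neighbors |
| background genes | 5 chromosomes × 200 | enough gene-order room for safe event placement |
| loss_probability | 0 | losses are a perturbation, not the base condition |
| supports | 1.0 everywhere | the simulated history is certain; noise lives in `perturb` |

Placement guarantees make truth labels exact: family genes sit ≥ 30 ranks
apart; each event reserves a disjoint gene-order window (tandem offset 1,
proximal offset uniform on [2, 19], dispersed on another chromosome ≥ 25
ranks from any family gene, WGD duplicating a ±2 window whose anchors form
an intra-genome block), so no event distorts another's rank gap. Homology
pairs are all within-lineage pairs truncated to the top 5 per query by
simulated similarity (copies most similar, then within-clade orthologs).
Inter-species blocks within each clade anchor the shared ancestral gene
order, so group merging recovers one group per lineage per clade plus
their WGD copies. Proteins are sampled from per-class consensus sequences
(2 % per-site substitution) with protected class motifs (AAYIGP in IA-1,
SKYQ in IA-2, an LxLxL repeat in class II); no realistic substitution
model is claimed. Domain hits give every family protein a high-coverage,
low-E-value hit plus background decoys that each fail exactly one gate.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: topological error and long-branch attraction in
the gene tree, fractionation bias after WGD, fragmented assemblies and
annotation noise, E-value distributions of real HMM searches, and synteny
decay between clades. Recovery results on simulated data certify the
algorithms, not the robustness of the criteria to real phylogenetic noise
(the `perturb` harness — gene drop, leaf-order shuffle, support
downgrade — probes the first-order effects).

With `loss_probability` > 0 each family gene is removed independently from
every emitted file; inferred depth counts then never exceed the simulated
truth (monotone degradation), which the tests assert at loss 0.2.

## Problem sizes used in the checks

The packaged checks run the fixture tree (169 leaves), 1,000+ random
oracle instances (trees ≤ 40 leaves, pair graphs ≤ 100 vertices, genomes
≤ 200 genes), and 100 simulated datasets of ~11,400 genes / ~300 family
members each — sizes chosen to exercise every code path at the scale of
the real 11-genome analysis's family (431 genes) while keeping the full
suite under a minute.

## Known limitations

* The ancient-depth "sister coverage" criterion inspects one node's
  sister; a single misplaced basal leaf can split or hide an ancient
  lineage. Use `min_support` and the configurable sister requirement to
  probe sensitivity.
* Collinearity support treats groups as hard assignments; partially
  overlapping groups (possible with promiscuous anchors) count as
  unsupported rather than fractionally supported.
* The codeml reader targets the two line formats above; exotic output
  layouts need manual extraction (the LRT itself only needs two numbers).
* MCScanX `.collinearity` parsing covers the block-header + anchor-line
  dialect; per-anchor E-values are not retained. Native HMMER
  `--domtblout` files are not parsed directly — project the seven needed
  columns into the documented TSV first.
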