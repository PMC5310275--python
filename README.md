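# lbdtrace

Reconstructing the ancestry of a plant gene family from domain hits,
genome collinearity and a species-annotated gene tree.

Plant transcription-factor families such as the Lateral Organ Boundaries
Domain (LBD/AS2) family descend from a handful of genes in early land
plants, expanded by stem duplications before the seed-plant and angiosperm
radiations and by whole-genome / tandem / proximal / dispersed duplications
within individual angiosperm genomes. `lbdtrace` implements the full desk
side of that analysis for comparative genomicists:

* **Family detection** from profile-HMM domain hits: a protein is a family
  member iff a single hit to the family profile (default DUF260, the LOB
  domain) passes both gates — per-domain E-value ≤ 10⁻⁵ *and* coverage of
  ≥ 80 % of the profile columns — followed by collapsing alternative
  isoforms to one representative per locus.
* **Duplication typing** per gene with the MCScanX-style priority cascade
  `wgd > tandem > proximal > dispersed > singleton` (tandem = homolog at
  gene-order distance 1; proximal = distance < 20; wgd = anchored in a
  collinear block).
* **Collinear ortholog groups**: family-internal anchor pairs are
  recursively merged — the transitive closure, i.e. connected components
  of the pair graph — separately for dicots and monocots.
* **Ancestral lineage inference** at three depths from a rooted gene tree
  whose leaves carry species labels:
  * *ancient* — maximal bryophyte/lycophyte-only clades whose sister
    contains genes of every analyzed seed-plant species;
  * *seed plant* — minimal clades with ≥ 1 gymnosperm gene plus ≥ 1 gene
    from every analyzed angiosperm species;
  * *angiosperm* — minimal clades spanning all analyzed dicot and monocot
    species (clause minima configurable), cross-checked against the
    collinear groups.

  Minimal qualifying clades are pairwise disjoint, so their count is the
  inferred number of ancestral genes at that depth.
* **Branch-model LRT**: 2·(ℓ₁ − ℓ₀) against χ²(df) for a two-ratio vs
  one-ratio ω = dN/dS comparison (log-likelihoods supplied, e.g. scraped
  from codeml output files).
* **Sequence profiles**: per-column information content
  IC = log₂20 − H of class alignments, and motif scanning with `x`
  wildcards (SKYQ, AAYIGP, LxLxL).
* **Synthetic data**: a genome-evolution simulator that emits every input
  dialect above with known ground truth, so the whole pipeline is testable
  end to end without downloading genomes.

## Worked example

Simulate a dataset (11 species: one bryophyte, one lycophyte, one
gymnosperm, five dicots, three monocots; 7 → 11 → 18 ancestral lineages;
per-angiosperm duplication events) and run the whole pipeline:

```sh
lbdtrace simulate --seed 42 --out data
lbdtrace run --config run.yaml     # paths to the files under data/
```

The log reports each stage:

```
stage classify: {'genes': 11391, 'tandem': 48, 'dispersed': 80, 'singleton': 41, 'proximal': 32, 'wgd': 96}
stage groups: {'family_pairs': 282, 'dicot_groups': 18, 'monocot_groups': 18}
stage ancestry: {'ancient': 7, 'seed': 11, 'angiosperm': 18, 'collinearity_supported': 18}
depth counts: (7, 11, 18)
```

Reading: of the 297 family genes, 96 are WGD-derived, 48 tandem, 32
proximal, 80 dispersed and 41 unduplicated; the 282 family-internal
collinear anchor pairs merge into 18 dicot and 18 monocot ortholog groups;
and the tree yields 7 ancient lineages, 11 seed-plant ancestors and 18
angiosperm ancestors — exactly the simulated truth, with all 18 angiosperm
clusters supported by collinearity. Outputs land in `out/`
(`members.tsv`, `labels.tsv`, `groups_*.tsv`, `clusters.tsv`,
`lineage_paths.tsv`, `summary_counts.tsv`, `manifest.json`).

The LRT subcommand works directly from log-likelihoods:

```sh
$ lbdtrace lrt --null-lnl -8133.64 --alt-lnl -8129.48 --df 1
2*delta_lnL = 8.3200, df = 1, p = 0.003921
```

i.e. the two-ratio branch model fits significantly better (p ≈ 0.0039).

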