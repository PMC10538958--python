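# On-disk formats

All tables are UTF-8 TSV with `.` decimals. A missing value is written as
an empty cell and parsed from an empty cell or `NA`. Writers are
byte-stable: fixed row/column order, 6 significant digits for scores and
abundances (`%.6g`), scientific notation for p/q values (`%.6e`).

## Reporter intensity tables (`proteome_<set>.tsv`)

One file per TMT set. Columns: `feature`, then `<set>_<channel>` for each
of the ten reporter channels (126, 127N, ... 131). Values are raw reporter
intensities; channel 126 is the pooled-control reference.

## Design sidecar (`design.tsv`)

Columns: `sample`, `group`, `plex`, `channel`. One row per proteome
sample; the reference channel carries no sample and has no row.

## Abundance matrices (`write_matrix`)

Columns: `feature`, then one column per sample id. Group and plex
metadata live in a sidecar design TSV (`sample`, `group`[, `plex`]).

## Phosphosite table (`phospho.tsv`)

Columns: `id`, `protein`, `position` (1-based), `residue` (S/T/Y),
`window` (13-mer flanking sequence, `_`-padded at protein ends,
phosphoacceptor at the center), `localization_prob`, then one log2
intensity column per sample. Empty cell = not quantified.

## Annotation collections (GMT)

One term per line: `term<TAB>description<TAB>member1<TAB>member2...`.
Duplicate members collapse; duplicate term ids are an error.

## Interaction networks (SIF)

One edge per line: `source<TAB>relation<TAB>target` with nodes in
lexicographic order and lines sorted. Node attributes are written to a
companion `<name>.sif.attrs.tsv` (`node`, then one column per attribute).

## Kinase motifs (`kinase_motifs.tsv`)

One motif per line: kinase name, then `offset:residues` constraints,
e.g. `PKA<TAB>-3:R<TAB>-2:R<TAB>0:ST`. Offset 0 (required) lists the
allowed phosphoacceptor residues. `#` starts a comment line.

## Ground truth (`ground_truth.tsv`)

Columns: `kind`, `entity`, `context`, `value`. Kinds:
`differential_feature` (entity=feature, context=group, value=log2 effect),
`enriched_term`, `perturbation_event` (entity=protein, context=sample),
`planted_cluster` (context=semicolon-joined members), `motif_cluster`,
`target_mrna_protein_corr`.

## Result tables

- `proteome_differential.tsv` / `phospho_differential.tsv`: `feature`,
  then per non-control group `log2fc_<g>`, `p_<g>`, `padj_<g>`, `sig_<g>`.
- `enrich_fisher.tsv`, `enrich_1d_<g>.tsv`, `enrich_2d_<g>.tsv`: `term`,
  `mode`, `size`, `score`, `score_x`, `score_y`, `overlap`, `p`, `q`,
  `significant`; 2-D runs also emit `enrich_2d_<g>_scatter.tsv`
  (`term`, `score_x`, `score_y`, `q`).
- `kinase_enrichment.tsv`: `cluster`, `kinase`, `cluster_size`,
  `motif_matches`, `overlap`, `p`, `q`, `significant`.
- `coreg_edges.tsv`: `protein_a`, `protein_b`, `rho`, `p`, `q`, `sign`.
- `coreg_events.tsv`: `sample`, `protein_a`, `protein_b`, `distance`,
  `grubbs_G`, `grubbs_p`.
- `consensus_perturbed.tsv`: `group`, `protein`, `k`, `n`, `K`, `N`, `p`,
  `consensus`.
- `network_clusters.tsv`: `cluster`, `size`, `cohesiveness`, `p`,
  `members`, `regimen_counts`.

## Run manifest and log

Each stage writes `manifest_<stage>.json` (config hash, seed, event
records with row/filter counts) — fully deterministic — and appends
timestamped lines to `logs/<stage>.log` (the only non-reproducible file
in an output tree).
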