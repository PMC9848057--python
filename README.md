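# arrayscan

Quantitative toolkit for tandem gene-family homogenization analysis and
tissue-specificity expression screening, built around five stages:

- **Expression atlas** — classify genes into `not_detected` /
  `tissue_enriched` / `group_enriched` / `other` from a TPM matrix
  (5-fold rule, per-gene Z ≥ 1 group rule, TPM < 1 detection floor), and a
  differential screen (Welch's t on log2(TPM+1), Benjamini–Hochberg,
  fold change > 2 ∧ adjusted P < 0.05 ∧ anchor-tissue enrichment).
- **Residue composition** — per-gene glycine/tyrosine/GC proportions
  (X excluded from both sides of residue fractions), a tyrosine ≥ 5% ×
  skin-enrichment candidate screen, and per-group summaries with one-way
  ANOVA.
- **Tandem arrays** — affine-gap Needleman–Wunsch protein alignment with
  deterministic traceback, neighbor identity (1 − p-distance over gap-free
  columns), tail-to-head orientation, identical-CDS clades, an NG86-style
  Ks/Ka estimator (pathway-averaged counts, Jukes–Cantor correction), and
  molecular-clock dating `T = Ks / (2·mu)` with `mu = 2e-9` per site per
  year by default.
- **CNE decay** — merged-interval alignment coverage per conserved
  noncoding element with strict decayed (< 50%) / intact (> 90%) cuts, a
  desk-scale Smith–Waterman hit generator, and cross-species contrasts.
- **Synthetic data** — forward-time tandem-array evolution (duplication,
  Jukes–Cantor point mutation, optional nonallelic gene-conversion tract
  copying, two-species split), planted-structure expression matrices, and
  CNE decay scenarios — every generator seeded and byte-reproducible.

## CLI

All analyses are exposed through a single `arrayscan` entry point:

```sh
arrayscan classify --matrix expr.tsv --replicates map.tsv --fold 5 --detect 1 --z 1 --out classes.tsv
arrayscan de --matrix expr.tsv --replicates map.tsv --a dorsal --b abdominal \
             --classes classes.tsv --fold 2 --alpha 0.05 --out de.tsv
arrayscan composition --cds cds.fa --protein prot.fa --classes classes.tsv \
             --tyr-cutoff 0.05 --out comp.tsv
arrayscan array-stats --cds cds.fa --loci loci.gff3 --family family.txt --out report.json
arrayscan ks --cds cds.fa --pairs pairs.tsv --mu 2e-9 --out ks.tsv
arrayscan cne --cnes cnes.fa --hits hits.paf --decay-cut 0.5 --intact-cut 0.9 --out cne.tsv
arrayscan simulate array --seed 42 --out-dir sim/
arrayscan run --config config.yaml
```

`map.tsv` is a two-column headerless sample→tissue table. Loci may be GFF3
(1-based inclusive, `gene` lines with `ID=`) or 6-column BED; hit tables may
be BLAST outfmt-6-like or minimal PAF. Internally everything is 0-based
half-open.

`arrayscan run` executes expression → composition → array stats → Ks → CNE
from a YAML config (`PipelineConfig` fields; see
`PipelineConfig.to_yaml`), writes TSV/JSON artifacts plus a `manifest.json`
with the config hash, and is byte-deterministic for a fixed config.

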