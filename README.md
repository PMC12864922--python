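# tdploc

Analysis toolkit for measuring how the RNA-binding protein TDP-43 limits
mRNA accumulation in neurites, built around three assays performed on one
pool of reporter sequences:

- **Tiling MPRA** — 260-nt oligos tiled every 6 nt across 3′ UTRs (with
  260-nt flank extension and 20-nt PCR handles) measure which discrete
  sequences make a reporter's localization TDP-43-sensitive. For every
  motif-bearing tile a companion oligo with base-complemented motifs
  (GUGUG→CACAC, UGUGU→ACACA, GUAUG→CAUAC) tests necessity.
- **RBNS** — in vitro binding of the same pool to purified TDP-43 yields a
  relative affinity per oligo, R = (frequency in bound pool)/(frequency in
  input pool).
- **SLAM-seq** — pulse-chase 4SU labeling read out as T>C conversions gives
  each oligo a stability ratio, rate(t=12 h)/rate(t=0 h), and a genotype
  effect Δstability = log2(ratio_KO/ratio_WT).

The central localization statistic is the **Localization Ratio**

    LR = log2( rel. abundance in neurite fraction / rel. abundance in soma fraction )

and its knockout-minus-wild-type difference **ΔLR**; positive ΔLR means an
RNA becomes more neurite-enriched when TDP-43 is lost. Supporting modules
cover UMI-aware amplicon quantification (adapter trimming, seeded
near-exact assignment to the oligo dictionary, unique-UMI counting),
windowed RNA base-pair probability profiles (80-nt windows sliding by
10 nt over each 260-mer), 5-mer enrichment between UTR sets (Fisher exact
+ BH FDR), CLIP peak overlap/read-density contrasts, and Wilcoxon
rank-sum group comparisons.

Every raw input the pipeline consumes can be produced by the seeded
synthetic-data generator (`tdploc.synthdata`), which plants known ΔLR
effects, affinities, half-lives, motif positions and structural contexts
and records them in a truth table, so every estimator can be tested for
parameter recovery.

## Worked example

```python
from tdploc import validation

validation.motif_recovery(seed=1)
# (['GTGTG', 'TGTGT', 'GTATG'], 3)
```

A simulated fractionation experiment (40 target UTRs with three planted
motifs each, 200 background genes) is analyzed blind: genes are ranked by
measured ΔLR, and 5-mer enrichment between the increased and unchanged
UTR sets puts exactly the three canonical TDP-43 motifs on top.

```python
import numpy as np
np.mean(validation.delta_lr_recovery(range(1, 11)))   # 3.953  (planted: 4.0)
validation.slam_ratio_recovery(seed=3)["stability_ratio_wt"]
# 0.514  (planted 12-h half-life, 12-h chase: expected 0.5)
validation.structure_classification(seed=2)["accuracy"]  # 1.0
```

The full pipeline chains simulate → design → quantify → localize → fold →
rbns → slam → stats:

```
tdploc run-all --seed 1 --outdir out/
```

It finishes in a few minutes on one CPU and prints a summary whose
headline contrasts mirror the biology planted by the generator — oligos
that contain an occupied (CLIP-supported) motif show the largest ΔLR
(median effect ≈ +4.0 log2 vs motif-free oligos, rank-sum p ≈ 1e-81 at
this scale), the highest affinity (R effect ≈ +3.1) and the largest
stabilization on TDP-43 loss (Δstability effect ≈ +0.88 ≈ log2 of the
planted half-life doubling), mutant companions lose all three effects,
and ranking motifs by base-pair probability puts the effect in the
single-stranded bottom 20%. Per-stage tables (counts, LR tables, R
values, conversion rates, structure scores, the per-oligo master join
and the contrast suite) are written under `out/results/`.

Individual stages are also exposed as subcommands (`simulate`, `design`,
`quantify`, `localize`, `fold`, `rbns`, `slam`) operating on plain
FASTA/FASTQ/BED/TSV files; see `tdploc --help`.

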