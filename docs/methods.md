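# Methods

## Statistical model and pipeline

The package quantifies TDP-43-dependent mRNA accumulation in neurites at
two resolutions. At the gene level, subcellular fractionation RNA-seq
counts (soma vs neurite, wild-type vs knockout, replicated) are turned
into Localization Ratios LR = log2(rel_neurite / rel_soma), where the
relative abundance of feature *f* in sample *s* is
(count + pc) / Σ_f (count + pc) with pseudocount pc = 0.5 (finite LR at
zero counts without dominating moderate counts). ΔLR = mean LR(KO) −
mean LR(WT) is tested per feature with a two-sided Welch t across
replicate LRs and Benjamini–Hochberg FDR across features. This
total-count normalization is deliberately simple and self-contained; it
is not size-factor robust, so when a non-negligible count share changes,
ΔLR estimates of unaffected features shift by −log2 of the library
composition change. The synthetic study keeps affected genes a small
share of each library (see below), which bounds this bias at ≈0.1 log2
units. With a single replicate per genotype ΔLR is reported with NA
statistics.

At the oligo level, the same LR/ΔLR machinery runs on unique-UMI counts
from the tiling MPRA. Reporter pools are a closed dictionary, so read
assignment is seeded near-exact matching rather than general alignment:
after 5′ adapter removal (Hamming distance ≤ 2 to the known adapter) and
UMI extraction (first 8 nt of the reverse read), the forward remainder
must match an oligo's 5′ end and the reverse remainder the reverse
complement of its 3′ end, each within 2 mismatches; candidates come from
exact lookup of read thirds (pigeonhole), the unique minimal-distance
oligo wins, and ties — including reads equidistant between a wild-type
oligo and its motif-mutant companion — are left unassigned. Indels are
not modeled (amplicon reads of known origin). N counts as a mismatch in
assignment and as a literal symbol in UMIs; deduplication is exact
string identity per (oligo, sample), with no 1-mismatch UMI clustering.

SLAM-seq samples use a conversion-aware variant of the same matcher:
T>C on the forward strand (A>G on the reverse) is expected chemistry, so
it is invisible to seeding and costs nothing in verification. Without
this, heavily labeled reads fail the 2-mismatch budget and the labeled
fraction at late chase times is underestimated (measured ratio 0.37
instead of 0.5 in a half-life-12 h simulation). Conversion rates are
pooled n_TC/n_T per oligo (no per-read mixture modeling), reference-T
positions below base quality Q20 are skipped when qualities are present,
non-T-reference mismatches are tallied as diagnostics only, and the
stability ratio rate(t=12)/rate(t=0) is NA below 200 covered T positions
or at zero t=0 rate. Optional background subtraction (a no-4SU control
rate) is off by default.

RBNS enrichment is R = (bound frequency)/(input frequency), per
(concentration, replicate) bound sample against its own replicate's
input, with oligos under 10 input reads NA'd (ratio variance explodes at
small denominators) and the unweighted mean across bound samples as the
per-oligo summary. Concordance across concentrations is Spearman
correlation of log R with average-linkage clustering on 1 − ρ.

Group comparisons throughout are two-sided Wilcoxon rank-sum tests:
exact when min(n₁, n₂) ≤ 25 and the pooled sample is tie-free, else the
normal approximation with continuity correction. 5-mer enrichment
between UTR sets uses per-UTR presence/absence in a 2×2 Fisher exact
test with BH FDR over all 1024 5-mers and a pseudocounted log2
enrichment of presence fractions; the output ranks by enrichment.
Interval overlap uses ≥1 nt in 0-based half-open coordinates everywhere,
so a motif exactly abutting a CLIP peak is *not* inside it.

## RNA structure model

Motif accessibility is profiled with a McCaskill-style partition
function over nested structures: 80-nt windows sliding 10 nt across each
260-mer; per window, P_paired(i) = Σ_j P(i, j); positions covered by
several windows take the arithmetic mean (position-count independent).
The energy model is additive per pair — GC −3 kT, AU −2 kT, GU −1 kT,
minimum hairpin loop 3 nt, no stacking or dangles — plus one **loop-
closing penalty of 8 kT** paid by every pair whose immediately enclosed
positions are not themselves paired (hairpin, internal-loop or multiloop
closure alike). The penalty is essential, not cosmetic: with per-pair
energies alone, an isolated pair is pure gain, so in an 80-nt window
essentially every base with a single available partner is predicted
paired and accessible and stem-embedded motifs are indistinguishable
(both ≈0.5–1.0). One Turner-magnitude closing cost restores helix
cooperativity; with it, designed accessible motifs profile at ≈0.1–0.2
and designed 12-bp stems at ≈0.9. The model is small enough that an
exhaustive structure-enumeration oracle (shipped with the test suite)
is exact, and the backend matches it to <1e-9 on sequences ≤12 nt.
The backend sits behind a minimal contract (symmetric non-negative
matrix, row sums ≤ 1), so a thermodynamic backend can be dropped in;
none is bundled. Motif scores are the mean (not sum) over the 5 motif
positions, comparable across motif counts; the top/bottom 20% structure
split ranks stably on (score, id) with ⌈qN⌉ members per set.

## Synthetic data: what it emulates, and what it does not

All raw inputs are generated from a single seed (one `SeedSequence`
fanned out per stage; identical seeds give byte-identical outputs).
Defaults define the study conditions:

- **UTR set** — 6 target and 10 background UTRs of 300 nt, three planted
  canonical motifs per target (cycling GUGUG/UGUGU/GUAUG so all three
  types occur). Half the targets are "occupied": their motifs sit in
  accessible context — a strongly A-rich, C-free stretch (A 0.90 /
  G 0.04 / U 0.06) extending 75 nt on each side, i.e. the full width any
  covering 80-nt window can see, because with narrower protection chance
  CAC/CACAC complements in flanking sequence base-pair the motif and
  structural classification degrades. The other targets carry their
  motifs mid-arm in designed perfect hairpins (12-bp stems, 4-nt loop).
  Background UTRs are plain random sequence; chance motif occurrences
  are left in place and recorded. A `motif_context="neutral"` mode
  plants motifs in unmodified random sequence instead — used by the
  motif-discovery study, where the engineered A-rich scaffold would
  itself be the strongest sequence signal (AAAAA-type 5-mers outrank the
  motifs), an artifact no real UTR set has.
- **Effect wiring** — only intact occupied motifs carry effects:
  ΔLR +4 log2, affinity 1 + 3 per occupied motif, half-life 6 h (WT) vs
  12 h (KO). Motifs without occupancy (stem-embedded or chance) get a
  modest ΔLR of +0.5 and affinity increment 0.3; mutant companions get
  nothing. This mirrors the observed biology: occupancy, not motif
  presence, predicts function.
- **Fractionation counts** — negative binomial (dispersion 0.1) with
  genotype-independent soma means and KO neurite means scaled by
  2^ΔLR; per-sample library-size factors ~lognormal(0, 0.15). 200
  unaffected filler genes pad the transcriptome and target genes are
  expressed at 5% of background, keeping affected RNA a small share of
  each library as in real data (and keeping the total-count
  normalization's composition bias ≈0.1 log2).
- **Reads** — forward mate = 45-nt adapter + 130-nt variable-region
  prefix; reverse mate = 35-nt adapter + 8-nt UMI + reverse-complement
  130-nt suffix; substitution errors at 0.002/base; UMIs uniform over
  4^8 with no collision correction (collisions negligible at ~40
  reads/oligo and bounded explicitly in tests); uniform high base
  qualities. Depth 100,000 pairs/sample, multinomial in the planted
  abundances (depth conserved exactly). MPRA: 2 compartments × 2
  genotypes × 3 replicates. RBNS: duplicates at 500/50/5 nM; bound-pool
  weights ∝ affinity^γ(c) with γ rising log-linearly in concentration
  (0.5 → 1.0), a monotone stand-in for concentration-dependent dynamic
  range. SLAM: labeled fraction 2^(−t/half-life) at chase times 0 and
  12 h, T>C at 0.05/T on labeled and 0.001/T on unlabeled molecules.
- **CLIP** — one merged peak per occupied-motif cluster (±20 nt); read
  intervals Poisson at 100 reads/kb outside peaks and 3.5× that inside.

Not emulated: realistic quality-score models, PCR duplicate families,
indels, splice structure, isoform mixtures, batch effects, or any
real-library noise calibration — passing recovery tests shows the
estimators are correct under the stated models, not that the models
capture every property of real libraries.

## Scale, determinism and numerical choices

Problem sizes are desk-scale by design: the default end-to-end run
(~2,400 oligos, 32 sequencing samples of 100k pairs, 216 genes)
completes in a few minutes on one CPU, and the recovery studies use
focused simulations (e.g. 8 oligos at ~2,000 reads each for half-life
recovery, 3 oligos at 20,000 reads for affinity order). The rolling ΔLR
profile uses a centered 5-tile window shrinking at the ends. Localization
direction groups in the end-to-end run are labeled by effect size with
nominal p (|ΔLR| > 1, p < 0.05): with triplicates and ~200 genes,
BH-corrected calls (still reported per feature) have no power, and the
labels feed descriptive sequence analyses rather than inference.
Degenerate inputs are defined rather than accidental: all-zero samples
raise naming the sample, identical replicate vectors give p = 1,
single-replicate designs report estimates with NA statistics, all-tied
structure scores split by id order, and every discarded read is
attributable in the processing logs (total = assigned + unassigned +
rejected, exactly).

## Known limitations

Total-count normalization is not robust to large composition shifts;
the energy model ignores stacking, so its probabilities are
ordinally, not thermodynamically, meaningful; conversion-rate ratios
assume pure exponential decay and a two-timepoint design; the matcher
tolerates substitutions only; and the Wilcoxon exact branch is skipped
whenever ties exist, even tiny samples.
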