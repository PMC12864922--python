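"""Synthetic raw data with the statistical structure the pipeline assumes.

Every raw input the analysis consumes can be generated here from a seeded
generator: 3' UTR sets with planted GU-repeat motifs in accessible or
stem-paired contexts, paired-end MPRA/RBNS/SLAM amplicon reads (adapter +
variable region, adapter + 8-nt UMI + reverse-complement suffix),
negative-binomial fractionation count matrices with neurite-specific
knockout effects, and CLIP peak/read intervals piled over occupied
motifs. A TruthTable records every planted parameter (ΔLR, affinity,
half-lives, motif positions, occupancy, structural context) so that
downstream estimates can be checked against ground truth.

Ground-truth effect wiring mirrors the biology being emulated: only
motifs in accessible (single-stranded, A-rich) context are "occupied" by
TDP-43; occupied motifs carry the large localization effect, high in
vitro affinity and genotype-dependent stability, while motifs buried in
designed hairpin stems, chance background motifs and mutated companions
carry little or none.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import design
from .config import FWD_ADAPTER, REV_ADAPTER, PipelineConfig, SimConfig
from .io import FastqWriter, revcomp, write_bed, write_fasta, write_tsv

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: accessible-context composition: strongly A-rich, C-free so planted
#: motifs have no strong pairing partner nearby (A, C, G, T)
_ACCESSIBLE_P = (0.90, 0.0, 0.04, 0.06)
_STEM_LOOP = "AAAA"


def _rand_seq(rng: np.random.Generator, n: int, p: Sequence[float] | None = None) -> str:
    if n <= 0:
        return ""
    idx = rng.choice(4, size=n, p=p) if p is not None else rng.integers(0, 4, size=n)
    return _BASES[idx].tobytes().decode()


@dataclass
class UtrSet:
    records: List[design.UtrRecord]
    metadata: pd.DataFrame
    truth: pd.DataFrame


def _motif_string(hits: Sequence[Tuple[str, int, int]]) -> str:
    return ";".join(f"{m}@{s}-{e}" for m, s, e in hits)


def gen_utr_set(cfg: SimConfig, rng: np.random.Generator | None = None) -> UtrSet:
    """Target + background UTRs with planted motifs and ground truth.

    Occupied targets host their motifs inside wide A-rich accessible
    blocks; unoccupied targets host them in the arms of designed perfect
    hairpin stems. Background UTRs are plain random sequence; chance
    motif occurrences are left in place and recorded with occupied=False.
    """
    cfg.require_valid()
    rng = rng or np.random.default_rng(cfg.seed)
    k = cfg.motifs_per_target
    ss_block = 2 * cfg.ss_protect_nt + 5 * k + cfg.ss_spacer_nt * max(0, k - 1)
    stem_unit = 2 * cfg.stem_arm_nt + len(_STEM_LOOP)
    stem_block = stem_unit * k + 12 * max(0, k - 1)
    if cfg.motif_context == "designed" and k > 0 and max(ss_block, stem_block) > cfg.utr_length:
        raise ValueError(
            f"utr_length={cfg.utr_length} too short for {k} planted motifs "
            f"(needs >= {max(ss_block, stem_block)} nt)"
        )

    n_occupied = int(round(cfg.frac_occupied * cfg.n_target_utrs))
    records, meta_rows, truth_rows = [], [], []

    def _add(gene: str, seq: str, is_target: bool, occupied: bool, context: str,
             hits: List[Tuple[str, int, int]], extra: dict):
        rec = design.UtrRecord(
            gene_id=gene,
            transcript_id=f"{gene}.1",
            sequence=seq,
            upstream_flank=_rand_seq(rng, design.FLANK_LEN),
            downstream_flank=_rand_seq(rng, design.FLANK_LEN),
        )
        records.append(rec)
        meta_rows.append(
            {
                "gene_id": gene,
                "transcript_id": rec.transcript_id,
                "tags": "",
                "polya_conserved": True,
                "length": rec.length,
                "interval_start": 0,
                "interval_end": rec.length,
                "upstream_flank": rec.upstream_flank,
                "downstream_flank": rec.downstream_flank,
            }
        )
        truth_rows.append(
            {
                "gene_id": gene,
                "is_target": is_target,
                "occupied": occupied,
                "structural_context": context,
                "motif_positions": _motif_string(hits),
                **extra,
            }
        )

    for t in range(cfg.n_target_utrs):
        gene = f"target{t:03d}"
        occupied = t < n_occupied
        motifs = [design.MOTIFS[i % len(design.MOTIFS)] for i in range(k)]
        if cfg.motif_context == "neutral":
            # motifs dropped into plain random sequence: the right emulation
            # for composition-sensitive sequence studies, where an engineered
            # A-rich or hairpin scaffold would itself be an enriched signal
            seq = _rand_seq(rng, cfg.utr_length)
            hits = []
            stride = cfg.utr_length // max(k, 1)
            if k and stride < 10:
                raise ValueError(
                    f"utr_length={cfg.utr_length} too short for {k} planted motifs"
                )
            for i, motif in enumerate(motifs):
                pos = i * stride + int(rng.integers(0, stride - 5))
                seq = seq[:pos] + motif + seq[pos + 5:]
                hits.append((motif, pos, pos + 5))
            context = "neutral"
            delta = cfg.delta_lr_occupied if occupied else 0.0
            aff = 1.0 + (cfg.affinity_scale if occupied else cfg.affinity_motif_only) * k
            hl_ko = cfg.halflife_ko_h if occupied else cfg.halflife_wt_h
            _add(gene, seq, True, occupied, context, hits,
                 {"planted_delta_lr": delta, "planted_affinity": aff,
                  "planted_halflife_wt": cfg.halflife_wt_h,
                  "planted_halflife_ko": hl_ko})
            continue
        if occupied:
            parts = [_rand_seq(rng, cfg.ss_protect_nt, _ACCESSIBLE_P)]
            hits = []
            pos = cfg.ss_protect_nt
            for i, motif in enumerate(motifs):
                if i:
                    parts.append(_rand_seq(rng, cfg.ss_spacer_nt, _ACCESSIBLE_P))
                    pos += cfg.ss_spacer_nt
                parts.append(motif)
                hits.append((motif, pos, pos + 5))
                pos += 5
            parts.append(_rand_seq(rng, cfg.ss_protect_nt, _ACCESSIBLE_P))
            block = "".join(parts)
        else:
            parts, hits = [], []
            pos = 0
            for i, motif in enumerate(motifs):
                if i:
                    spacer = _rand_seq(rng, 12)
                    parts.append(spacer)
                    pos += len(spacer)
                arm = _rand_seq(rng, cfg.stem_arm_nt - 5 - 3) + motif + _rand_seq(rng, 3)
                unit = arm + _STEM_LOOP + revcomp(arm)
                parts.append(unit)
                hits.append((motif, pos + cfg.stem_arm_nt - 8, pos + cfg.stem_arm_nt - 3))
                pos += len(unit)
            block = "".join(parts)
        lead = int(rng.integers(0, cfg.utr_length - len(block) + 1))
        seq = _rand_seq(rng, lead) + block + _rand_seq(rng, cfg.utr_length - len(block) - lead)
        hits = [(m, s + lead, e + lead) for m, s, e in hits]
        context = "single_stranded" if occupied else "paired"
        delta = cfg.delta_lr_occupied if occupied else 0.0
        aff = 1.0 + (cfg.affinity_scale if occupied else cfg.affinity_motif_only) * k
        hl_ko = cfg.halflife_ko_h if occupied else cfg.halflife_wt_h
        _add(gene, seq, True, occupied, context, hits,
             {"planted_delta_lr": delta, "planted_affinity": aff,
              "planted_halflife_wt": cfg.halflife_wt_h, "planted_halflife_ko": hl_ko})

    for b in range(cfg.n_background_utrs):
        gene = f"bg{b:03d}"
        seq = _rand_seq(rng, cfg.utr_length)
        hits = [(m, s, e) for m, s, e in design.find_motifs(seq)]
        _add(gene, seq, False, False, "none", hits,
             {"planted_delta_lr": 0.0, "planted_affinity": 1.0,
              "planted_halflife_wt": cfg.halflife_wt_h,
              "planted_halflife_ko": cfg.halflife_wt_h})

    return UtrSet(records, pd.DataFrame(meta_rows), pd.DataFrame(truth_rows))


def truth_motif_intervals(truth: pd.DataFrame) -> Dict[str, List[Tuple[int, int, bool]]]:
    """Per-gene planted/recorded motif intervals with occupancy flags."""
    out: Dict[str, List[Tuple[int, int, bool]]] = {}
    for row in truth.itertuples(index=False):
        occ = bool(row.occupied)
        out[row.gene_id] = [
            (s, e, occ) for _m, s, e in design.hits_from_str(row.motif_positions)
        ]
    return out


def annotate_pool_truth(
    pool: Sequence[design.OligoRecord], truth: pd.DataFrame, cfg: SimConfig
) -> pd.DataFrame:
    """Per-oligo planted parameters derived from the gene-level truth.

    An oligo is *regulated* when it is non-mutant and fully contains at
    least one occupied planted motif; regulated oligos carry the large
    localization effect, high affinity and the knockout stability shift.
    """
    intervals = truth_motif_intervals(truth)
    rows = []
    for rec in pool:
        occ = 0
        if not rec.is_mutant:
            for s, e, is_occ in intervals.get(rec.gene_id, []):
                if is_occ and s >= rec.start and e <= rec.start + len(rec.variable_seq):
                    occ += 1
        n_motifs = 0 if rec.is_mutant else len(rec.motif_hits)
        other = max(0, n_motifs - occ)
        if rec.is_mutant:
            delta, aff = 0.0, 1.0
        elif occ:
            delta = cfg.delta_lr_occupied
            aff = 1.0 + cfg.affinity_scale * occ + cfg.affinity_motif_only * other
        elif n_motifs:
            delta = cfg.delta_lr_motif_only
            aff = 1.0 + cfg.affinity_motif_only * other
        else:
            delta, aff = 0.0, 1.0
        rows.append(
            {
                "oligo_id": rec.oligo_id,
                "gene_id": rec.gene_id,
                "is_mutant": rec.is_mutant,
                "n_motifs": len(rec.motif_hits),
                "n_occupied": occ,
                "planted_delta_lr": delta,
                "planted_affinity": aff,
                "planted_halflife_wt": cfg.halflife_wt_h,
                "planted_halflife_ko": cfg.halflife_ko_h if occ else cfg.halflife_wt_h,
            }
        )
    return pd.DataFrame(rows).set_index("oligo_id")


# ---------------------------------------------------------------------------
# fractionation counts
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def gen_fractionation_counts(
    cfg: SimConfig, truth: pd.DataFrame, rng: np.random.Generator | None = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x (compartment x genotype x replicate) negative-binomial counts.

    Soma expectations are genotype-independent; the knockout neurite
    expectation is the wild-type one times 2^planted ΔLR. Filler genes pad
    the transcriptome so affected genes stay a small share of each library,
    as in real data. Library sizes vary per sample.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    genes = list(truth["gene_id"]) + [f"filler{i:04d}" for i in range(cfg.n_filler_genes)]
    is_target = np.concatenate(
        [truth["is_target"].to_numpy(bool), np.zeros(cfg.n_filler_genes, bool)]
    )
    delta = np.concatenate(
        [truth["planted_delta_lr"].to_numpy(float), np.zeros(cfg.n_filler_genes)]
    )
    base = cfg.fractionation_base_mean * np.exp(rng.normal(0.0, 0.2, len(genes)))
    base[is_target] *= cfg.target_expr_factor

    counts, samples = {}, []
    for genotype in ("WT", "KO"):
        for compartment in ("soma", "neurite"):
            for rep in range(1, cfg.replicates + 1):
                name = f"frac_{compartment}_{genotype}_rep{rep}"
                lib = np.exp(rng.normal(0.0, 0.15))
                mean = base * lib
                if genotype == "KO" and compartment == "neurite":
                    mean = mean * np.exp2(delta)
                counts[name] = _nb_draw(rng, mean, cfg.fractionation_dispersion)
                samples.append(
                    {"sample": name, "assay": "fractionation",
                     "compartment": compartment, "genotype": genotype,
                     "replicate": rep}
                )
    table = pd.DataFrame(counts, index=pd.Index(genes, name="feature_id"))
    return table, pd.DataFrame(samples)


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=min(k, len(seq)), replace=False):
        old = out[pos]
        choices = [b for b in "ACGT" if b != old]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def _emit_sample(
    fq1: str,
    fq2: str,
    pool_vars: Dict[str, str],
    read_counts: Dict[str, int],
    cfg: SimConfig,
    rng: np.random.Generator,
    sample: str,
    per_read_variable: Callable[[str, str, np.random.Generator], str] | None = None,
) -> int:
    """Write one paired FASTQ sample.

    fwd read = FWD_ADAPTER + variable-region prefix; rev read =
    REV_ADAPTER + UMI + reverse complement of the variable-region suffix.
    `per_read_variable(oligo_id, var, rng)` lets callers mutate each
    molecule (SLAM T>C conversions) before the reads are cut from it.
    """
    n = 0
    rl = cfg.read_len
    with FastqWriter(fq1) as w1, FastqWriter(fq2) as w2:
        for oligo_id, count in read_counts.items():
            if count <= 0:
                continue
            var0 = pool_vars[oligo_id]
            static = per_read_variable is None
            fwd_t = FWD_ADAPTER + var0[:rl]
            rc_suffix = revcomp(var0[-rl:])
            for _ in range(count):
                if static:
                    fwd, suf = fwd_t, rc_suffix
                else:
                    var = per_read_variable(oligo_id, var0, rng)
                    fwd = FWD_ADAPTER + var[:rl]
                    suf = revcomp(var[-rl:])
                umi = _rand_seq(rng, cfg.umi_length)
                fwd = _apply_errors(fwd, rng, cfg.seq_error_rate)
                rev = _apply_errors(REV_ADAPTER + umi + suf, rng, cfg.seq_error_rate)
                # read names carry source provenance (simulator ground truth)
                name = f"{sample}|{oligo_id}|{n}"
                w1.write(name, fwd)
                w2.write(name, rev)
                n += 1
    return n


def _multinomial_counts(
    rng: np.random.Generator, depth: int, ids: Sequence[str], weights: np.ndarray
) -> Dict[str, int]:
    total = weights.sum()
    if total <= 0:
        raise ValueError("abundance weights must have positive total")
    draws = rng.multinomial(depth, weights / total)
    return dict(zip(ids, draws))


def mpra_abundances(
    pool_truth: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Expected per-oligo relative abundance per MPRA sample.

    Soma is genotype-independent; knockout neurite abundance is wild-type
    times 2^planted ΔLR (regulated oligos only).
    """
    ids = pool_truth.index.to_numpy()
    base = np.exp(rng.normal(0.0, 0.25, len(ids)))
    delta = pool_truth["planted_delta_lr"].to_numpy(float)
    cols, samples = {}, []
    for genotype in ("WT", "KO"):
        for compartment in ("soma", "neurite"):
            for rep in range(1, cfg.replicates + 1):
                name = f"mpra_{compartment}_{genotype}_rep{rep}"
                w = base * np.exp2(delta) if (genotype == "KO" and compartment == "neurite") else base
                cols[name] = w / w.sum()
                samples.append(
                    {"sample": name, "assay": "mpra", "compartment": compartment,
                     "genotype": genotype, "replicate": rep}
                )
    return pd.DataFrame(cols, index=pd.Index(ids, name="oligo_id")), pd.DataFrame(samples)


def gen_mpra_reads(
    pool: Sequence[design.OligoRecord],
    abundances: pd.DataFrame,
    cfg: SimConfig,
    outdir: str,
    rng: np.random.Generator | None = None,
    samples_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Paired FASTQ per MPRA sample from an abundance table; returns sample sheet."""
    if not pool:
        raise ValueError("empty oligo pool")
    rng = rng or np.random.default_rng(cfg.seed + 2)
    os.makedirs(outdir, exist_ok=True)
    pool_vars = {r.oligo_id: r.variable_seq for r in pool}
    rows = []
    for sample in abundances.columns:
        weights = abundances[sample].to_numpy(float)
        counts = _multinomial_counts(rng, cfg.read_depth, abundances.index, weights)
        fq1 = os.path.join(outdir, f"{sample}_R1.fastq")
        fq2 = os.path.join(outdir, f"{sample}_R2.fastq")
        _emit_sample(fq1, fq2, pool_vars, counts, cfg, rng, sample)
        rows.append({"sample": sample, "fastq1": fq1, "fastq2": fq2})
    sheet = pd.DataFrame(rows)
    if samples_meta is not None:
        sheet = sheet.merge(samples_meta, on="sample")
    return sheet


def _rbns_gamma(conc: float, concentrations: Sequence[float]) -> float:
    lo, hi = min(concentrations), max(concentrations)
    if hi == lo:
        return 1.0
    return 0.5 + 0.5 * (np.log(conc) - np.log(lo)) / (np.log(hi) - np.log(lo))


def gen_rbns_reads(
    pool: Sequence[design.OligoRecord],
    pool_truth: pd.DataFrame,
    cfg: SimConfig,
    outdir: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Input + per-concentration bound FASTQ pairs for each RBNS replicate.

    The input pool is uniform; each bound pool is sampled with weight
    input_freq x affinity^gamma(c), gamma increasing with protein
    concentration so the enrichment dynamic range is concentration-
    monotone.
    """
    if not pool:
        raise ValueError("empty oligo pool")
    aff = pool_truth["planted_affinity"].to_numpy(float)
    if (aff < 0).any():
        raise ValueError("planted affinities must be >= 0")
    rng = rng or np.random.default_rng(cfg.seed + 3)
    os.makedirs(outdir, exist_ok=True)
    pool_vars = {r.oligo_id: r.variable_seq for r in pool}
    ids = pool_truth.index
    uniform = np.ones(len(ids))
    rows = []
    for rep in range(1, cfg.rbns_replicates + 1):
        name = f"rbns_input_rep{rep}"
        counts = _multinomial_counts(rng, cfg.read_depth, ids, uniform)
        fq1 = os.path.join(outdir, f"{name}_R1.fastq")
        fq2 = os.path.join(outdir, f"{name}_R2.fastq")
        _emit_sample(fq1, fq2, pool_vars, counts, cfg, rng, name)
        rows.append({"sample": name, "fastq1": fq1, "fastq2": fq2, "assay": "rbns",
                     "role": "input", "concentration": np.nan, "replicate": rep})
        for conc in cfg.concentrations_nM:
            gamma = _rbns_gamma(conc, cfg.concentrations_nM)
            name = f"rbns_bound_{conc:g}nM_rep{rep}"
            counts = _multinomial_counts(rng, cfg.read_depth, ids, uniform * aff ** gamma)
            fq1 = os.path.join(outdir, f"{name}_R1.fastq")
            fq2 = os.path.join(outdir, f"{name}_R2.fastq")
            _emit_sample(fq1, fq2, pool_vars, counts, cfg, rng, name)
            rows.append({"sample": name, "fastq1": fq1, "fastq2": fq2, "assay": "rbns",
                         "role": "bound", "concentration": conc, "replicate": rep})
    return pd.DataFrame(rows)


def gen_slam_reads(
    pool: Sequence[design.OligoRecord],
    pool_truth: pd.DataFrame,
    cfg: SimConfig,
    outdir: str,
    rng: np.random.Generator | None = None,
    labeled: bool = True,
) -> pd.DataFrame:
    """Pulse-chase SLAM reads per genotype x timepoint x replicate.

    At chase time t the labeled fraction of an oligo's molecules is
    2^(-t / half-life); T positions convert to C at the labeled rate on
    labeled molecules and at the background rate otherwise. `labeled=False`
    emulates the no-4SU control (background conversions only).
    """
    if not pool:
        raise ValueError("empty oligo pool")
    rng = rng or np.random.default_rng(cfg.seed + 4)
    os.makedirs(outdir, exist_ok=True)
    pool_vars = {r.oligo_id: r.variable_seq for r in pool}
    t_positions = {
        oid: np.array([i for i, c in enumerate(var) if c == "T"], dtype=np.int64)
        for oid, var in pool_vars.items()
    }
    halflife = {
        "WT": pool_truth["planted_halflife_wt"].to_dict(),
        "KO": pool_truth["planted_halflife_ko"].to_dict(),
    }
    ids = pool_truth.index
    uniform = np.ones(len(ids))
    rows = []
    for genotype in ("WT", "KO"):
        for t in cfg.timepoints_h:
            for rep in range(1, cfg.replicates + 1):
                name = f"slam_{genotype}_t{t:g}_rep{rep}"

                def convert(oid: str, var: str, r: np.random.Generator, _t=t, _g=genotype) -> str:
                    hl = halflife[_g][oid]
                    frac = 2.0 ** (-_t / hl) if np.isfinite(hl) else 1.0
                    is_lab = labeled and (r.random() < frac)
                    rate = cfg.conversion_rate_labeled if is_lab else cfg.background_conversion_rate
                    tpos = t_positions[oid]
                    if rate <= 0 or len(tpos) == 0:
                        return var
                    k = r.binomial(len(tpos), rate)
                    if k == 0:
                        return var
                    out = list(var)
                    for pos in r.choice(tpos, size=k, replace=False):
                        out[pos] = "C"
                    return "".join(out)

                counts = _multinomial_counts(rng, cfg.read_depth, ids, uniform)
                fq1 = os.path.join(outdir, f"{name}_R1.fastq")
                fq2 = os.path.join(outdir, f"{name}_R2.fastq")
                _emit_sample(fq1, fq2, pool_vars, counts, cfg, rng, name,
                             per_read_variable=convert)
                rows.append({"sample": name, "fastq1": fq1, "fastq2": fq2,
                             "assay": "slam", "genotype": genotype,
                             "timepoint": t, "replicate": rep})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CLIP features
# ---------------------------------------------------------------------------

def gen_clip_features(
    truth: pd.DataFrame,
    cfg: SimConfig,
    utr_lengths: Dict[str, int],
    rng: np.random.Generator | None = None,
    peak_pad: int = 20,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """CLIP peaks (one merged interval per occupied-motif cluster) + reads.

    Read intervals are Poisson with rate clip_read_rate_kb outside peaks
    and clip_fold times that inside, so every occupied motif sits inside
    exactly one peak and peak read density exceeds background by the
    configured fold in expectation.
    """
    rng = rng or np.random.default_rng(cfg.seed + 5)
    peak_rows, read_rows = [], []
    intervals = truth_motif_intervals(truth)
    for gene, length in utr_lengths.items():
        occ = [(s, e) for s, e, o in intervals.get(gene, []) if o]
        padded = [(max(0, s - peak_pad), min(length, e + peak_pad)) for s, e in occ]
        merged: List[List[int]] = []
        for s, e in sorted(padded):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for i, (s, e) in enumerate(merged):
            peak_rows.append({"chrom": gene, "start": s, "end": e,
                              "name": f"{gene}_peak{i}", "score": ".", "strand": "+"})
        # reads
        peak_bp = sum(e - s for s, e in merged)
        regions = []
        cursor = 0
        for s, e in merged:
            if s > cursor:
                regions.append((cursor, s, False))
            regions.append((s, e, True))
            cursor = e
        if cursor < length:
            regions.append((cursor, length, False))
        serial = 0
        for s, e, inside in regions:
            rate = cfg.clip_read_rate_kb * (cfg.clip_fold if inside else 1.0)
            n = rng.poisson(rate * (e - s) / 1000.0)
            for _ in range(n):
                start = int(rng.integers(s, e))
                end = min(length, start + cfg.clip_read_len)
                if end <= start:
                    continue
                read_rows.append({"chrom": gene, "start": start, "end": end,
                                  "name": f"{gene}_read{serial}", "score": ".",
                                  "strand": "+"})
                serial += 1
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    return (pd.DataFrame(peak_rows, columns=cols),
            pd.DataFrame(read_rows, columns=cols))


# ---------------------------------------------------------------------------
# one-call simulation of every pipeline input
# ---------------------------------------------------------------------------

def simulate_all(pipcfg: PipelineConfig, outdir: str) -> Dict[str, str]:
    """Generate every raw input under `outdir` and return an artifact map."""
    cfg = pipcfg.sim.require_valid()
    os.makedirs(outdir, exist_ok=True)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(cfg.seed).spawn(7)]
    utr_rng, frac_rng, mpra_rng, rbns_rng, slam_rng, clip_rng, _ = streams

    utrs = gen_utr_set(cfg, utr_rng)
    paths = {"outdir": outdir}
    paths["utr_fasta"] = os.path.join(outdir, "utrs.fasta")
    write_fasta(paths["utr_fasta"], ((r.gene_id, r.sequence) for r in utrs.records))
    paths["utr_metadata"] = os.path.join(outdir, "utr_metadata.tsv")
    write_tsv(paths["utr_metadata"], utrs.metadata)
    paths["truth"] = os.path.join(outdir, "truth.tsv")
    write_tsv(paths["truth"], utrs.truth)

    kept, _rejected = design.filter_utrs(utrs.records, pipcfg.max_utr_len)
    metas = [design.merge_meta_utr([r]) for r in kept]
    pool = design.assemble_pool(metas, tile_len=pipcfg.tile_len,
                                step=pipcfg.tile_step, flank=pipcfg.flank)
    paths["pool_fasta"] = os.path.join(outdir, "pool.fasta")
    paths["pool_manifest"] = os.path.join(outdir, "pool_manifest.tsv")
    design.write_pool(pool, paths["pool_fasta"], paths["pool_manifest"])

    pool_truth = annotate_pool_truth(pool, utrs.truth, cfg)
    paths["pool_truth"] = os.path.join(outdir, "pool_truth.tsv")
    write_tsv(paths["pool_truth"], pool_truth, index=True)

    counts, frac_samples = gen_fractionation_counts(cfg, utrs.truth, frac_rng)
    paths["fractionation_counts"] = os.path.join(outdir, "fractionation_counts.tsv")
    write_tsv(paths["fractionation_counts"], counts, index=True)
    paths["fractionation_samples"] = os.path.join(outdir, "fractionation_samples.tsv")
    write_tsv(paths["fractionation_samples"], frac_samples)

    def _relativize(sheet: pd.DataFrame) -> pd.DataFrame:
        out = sheet.copy()
        for col in ("fastq1", "fastq2"):
            out[col] = [os.path.relpath(p, outdir) for p in out[col]]
        return out

    ab, mpra_samples = mpra_abundances(pool_truth, cfg, mpra_rng)
    sheet = gen_mpra_reads(pool, ab, cfg, os.path.join(outdir, "mpra"), mpra_rng,
                           mpra_samples)
    paths["mpra_samples"] = os.path.join(outdir, "mpra_samples.tsv")
    write_tsv(paths["mpra_samples"], _relativize(sheet))

    sheet = gen_rbns_reads(pool, pool_truth, cfg, os.path.join(outdir, "rbns"), rbns_rng)
    paths["rbns_samples"] = os.path.join(outdir, "rbns_samples.tsv")
    write_tsv(paths["rbns_samples"], _relativize(sheet))

    sheet = gen_slam_reads(pool, pool_truth, cfg, os.path.join(outdir, "slam"), slam_rng)
    paths["slam_samples"] = os.path.join(outdir, "slam_samples.tsv")
    write_tsv(paths["slam_samples"], _relativize(sheet))

    lengths = {r.gene_id: r.length for r in utrs.records}
    peaks, reads = gen_clip_features(utrs.truth, cfg, lengths, clip_rng)
    paths["clip_peaks"] = os.path.join(outdir, "clip_peaks.bed")
    write_bed(paths["clip_peaks"], peaks)
    paths["clip_reads"] = os.path.join(outdir, "clip_reads.bed")
    write_bed(paths["clip_reads"], reads)

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump({k: os.path.relpath(v, outdir) for k, v in paths.items()
                   if k != "outdir"}, fh, indent=2)
    return paths
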