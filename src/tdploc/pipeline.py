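"""End-to-end orchestration: simulate -> design -> quantify -> localize ->
fold -> rbns -> slam -> stats, writing every stage's tables plus a
summary of the headline contrasts into one output directory."""

from __future__ import annotations

import json
import os
import time
from typing import Dict

import numpy as np
import pandas as pd

from . import comparative_stats as cstats
from . import design, localization, rbns, slam, structure, synthdata
from .config import PipelineConfig
from .io import read_bed, read_samplesheet, read_tsv, write_tsv
from .read_processing import quantify


def quantify_mpra(sheet: pd.DataFrame, pool, read_len: int, umi_len: int = 8):
    variable = {r.oligo_id: r.variable_seq for r in pool}
    return quantify(sheet, variable, read_len, umi_len=umi_len)


def oligo_delta_lr(counts: pd.DataFrame, sheet: pd.DataFrame,
                   pseudocount: float = 0.5) -> pd.DataFrame:
    return localization.gene_delta_lr(counts, sheet, pseudocount)


def rbns_r_table(counts: pd.DataFrame, sheet: pd.DataFrame,
                 min_input: int = rbns.DEFAULT_MIN_INPUT) -> pd.DataFrame:
    """R per bound sample, each normalized to its own replicate's input."""
    r_cols = {}
    for rep, grp in sheet.groupby("replicate"):
        inputs = grp[grp["role"] == "input"]["sample"]
        if len(inputs) != 1:
            raise ValueError(f"replicate {rep}: need exactly one input sample")
        input_counts = counts[inputs.iloc[0]]
        bound = grp[grp["role"] == "bound"]["sample"]
        r = rbns.compute_r(counts[list(bound)], input_counts, min_input)
        for col in r:
            r_cols[col] = r[col]
    return pd.DataFrame(r_cols)


def slam_tables(sheet: pd.DataFrame, pool, read_len: int, umi_len: int,
                min_T: int, background_rate: float = 0.0):
    """Quantify SLAM samples and derive conversion/stability tables."""
    variable = {r.oligo_id: r.variable_seq for r in pool}
    counters: Dict[str, slam.ConversionCounter] = {}

    def factory(sample: str):
        counters[sample] = slam.ConversionCounter(variable, read_len)
        return counters[sample]

    counts, log = quantify(sheet, variable, read_len, umi_len=umi_len,
                           on_assigned_factory=factory, conversion_aware=True)
    conv = pd.concat([c.table(s) for s, c in counters.items()], ignore_index=True)
    rates = slam.conversion_rates(conv, min_T)
    ratios = slam.stability_ratio(rates, sheet, min_T, background_rate)
    delta = slam.delta_stability(ratios)
    return counts, log, conv, rates, ratios, delta


def run_all(cfg: PipelineConfig, outdir: str) -> Dict:
    """Run the whole pipeline at the configured scale; returns the summary."""
    t_start = time.time()
    os.makedirs(outdir, exist_ok=True)
    raw = os.path.join(outdir, "raw")
    res = os.path.join(outdir, "results")
    os.makedirs(res, exist_ok=True)
    paths = synthdata.simulate_all(cfg, raw)
    pool = design.load_pool(paths["pool_fasta"], paths["pool_manifest"])
    manifest = read_tsv(paths["pool_manifest"], keep_default_na=False)
    truth = read_tsv(paths["truth"])
    rl, ul = cfg.sim.read_len, cfg.sim.umi_length

    # --- gene-level localization from fractionation counts -----------------
    frac_counts = read_tsv(paths["fractionation_counts"], index_col=0)
    frac_samples = read_tsv(paths["fractionation_samples"])
    gene_lr = localization.gene_delta_lr(frac_counts, frac_samples, cfg.pseudocount)
    write_tsv(os.path.join(res, "gene_delta_lr.tsv"), gene_lr, index=True)

    # --- MPRA ---------------------------------------------------------------
    mpra_sheet = read_samplesheet(paths["mpra_samples"])
    mpra_counts, mpra_log = quantify_mpra(mpra_sheet, pool, rl, ul)
    write_tsv(os.path.join(res, "mpra_counts.tsv"), mpra_counts, index=True)
    write_tsv(os.path.join(res, "mpra_processing_log.tsv"), mpra_log)
    oligo_lr = oligo_delta_lr(mpra_counts, mpra_sheet, cfg.pseudocount)
    write_tsv(os.path.join(res, "oligo_delta_lr.tsv"), oligo_lr, index=True)

    # positional rolling profiles for wild-type tiles of target genes
    prof_rows = []
    wt = manifest[~manifest["is_mutant"].astype(bool)]
    for gene, grp in wt.groupby("gene_id"):
        dlr = oligo_lr["delta_lr"].reindex(grp["oligo_id"])
        prof = localization.rolling_profile(
            dlr.to_numpy(), grp["start"].to_numpy(), cfg.rolling_window
        )
        prof.insert(0, "gene_id", gene)
        prof_rows.append(prof)
    profiles = pd.concat(prof_rows, ignore_index=True)
    write_tsv(os.path.join(res, "delta_lr_profiles.tsv"), profiles)

    # --- structure -----------------------------------------------------------
    backend = structure.BasePairBackend()
    scores = structure.score_pool([r for r in pool if r.motif_hits and not r.is_mutant],
                                  backend, cfg.fold_window, cfg.fold_slide)
    write_tsv(os.path.join(res, "motif_structure_scores.tsv"), scores)

    # --- RBNS ----------------------------------------------------------------
    rbns_sheet = read_samplesheet(paths["rbns_samples"])
    rbns_counts, rbns_log = quantify_mpra(rbns_sheet, pool, rl, ul)
    write_tsv(os.path.join(res, "rbns_counts.tsv"), rbns_counts, index=True)
    write_tsv(os.path.join(res, "rbns_processing_log.tsv"), rbns_log)
    r_table = rbns_r_table(rbns_counts, rbns_sheet, cfg.min_input)
    mean_r = rbns.summarize_r(r_table)
    write_tsv(os.path.join(res, "rbns_r_values.tsv"),
              r_table.assign(mean_r=mean_r), index=True)
    rho, order = rbns.concentration_concordance(r_table)
    write_tsv(os.path.join(res, "rbns_concordance.tsv"), rho, index=True)
    motif_counts = manifest.set_index("oligo_id")["n_motifs"]
    r_bins, r_rho, r_p = rbns.r_by_motif_count(mean_r, motif_counts)
    write_tsv(os.path.join(res, "rbns_by_motif_count.tsv"), r_bins)

    # --- SLAM ----------------------------------------------------------------
    slam_sheet = read_samplesheet(paths["slam_samples"])
    bg = cfg.sim.background_conversion_rate if cfg.background_subtract else 0.0
    _counts, slam_log, conv, _rates, ratios, dstab = slam_tables(
        slam_sheet, pool, rl, ul, cfg.min_T, bg
    )
    write_tsv(os.path.join(res, "slam_conversions.tsv"), conv)
    write_tsv(os.path.join(res, "slam_processing_log.tsv"), slam_log)
    write_tsv(os.path.join(res, "slam_stability_ratios.tsv"), ratios)
    write_tsv(os.path.join(res, "slam_delta_stability.tsv"), dstab, index=True)

    # --- integrative statistics ---------------------------------------------
    peaks = read_bed(paths["clip_peaks"]) if os.path.getsize(paths["clip_peaks"]) else \
        pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    reads = read_bed(paths["clip_reads"]) if os.path.getsize(paths["clip_reads"]) else \
        pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])

    # localization-defined gene groups (measured, not truth); group labels
    # use effect size with nominal p -- at triplicate scale BH-adjusted
    # calls are reported in the LrTable but are too conservative to label
    # groups for the sequence analyses
    sig = (gene_lr["p_value"] < 0.05) & gene_lr["p_value"].notna()
    direction = pd.Series("unchanged", index=gene_lr.index)
    direction[sig & (gene_lr["delta_lr"] > 1)] = "increased"
    direction[sig & (gene_lr["delta_lr"] < -1)] = "decreased"
    utr_seqs = {r.gene_id: r.sequence
                for r in design.load_utrs(paths["utr_fasta"], paths["utr_metadata"])}
    increased = [g for g in direction.index if direction[g] == "increased" and g in utr_seqs]
    unchanged = [g for g in utr_seqs if direction.get(g, "unchanged") == "unchanged"]
    summary_kmer = None
    if increased and unchanged:
        kmers = cstats.kmer_enrichment([utr_seqs[g] for g in increased],
                                       [utr_seqs[g] for g in unchanged])
        write_tsv(os.path.join(res, "kmer_enrichment.tsv"), kmers)
        summary_kmer = kmers.head(5)[["kmer", "log2_enrichment", "p"]].to_dict("records")

    utr_iv = pd.DataFrame({"chrom": list(utr_seqs), "start": 0,
                           "end": [len(s) for s in utr_seqs.values()]})
    groups = {g: direction.get(g, "unchanged") for g in utr_seqs}
    clip_utr, clip_summary = cstats.clip_overlap_stats(
        utr_iv, peaks, reads, groups, control_group="unchanged"
    )
    write_tsv(os.path.join(res, "clip_overlap_per_utr.tsv"), clip_utr)
    write_tsv(os.path.join(res, "clip_overlap_summary.tsv"), clip_summary)

    master = cstats.build_master(
        manifest, peaks,
        delta_lr=oligo_lr["delta_lr"],
        mean_r=mean_r,
        delta_stab=dstab["delta_stability"],
        motif_pair_prob=scores.set_index("oligo_id")["motif_pair_prob"]
        if len(scores) else None,
    )
    write_tsv(os.path.join(res, "oligo_master.tsv"), master, index=True)
    contrasts = cstats.headline_contrasts(master)
    write_tsv(os.path.join(res, "headline_contrasts.tsv"), contrasts)

    target_mask = truth.set_index("gene_id")["planted_delta_lr"] > 0
    recovered = gene_lr.loc[target_mask.index[target_mask], "delta_lr"].mean()
    summary = {
        "seed": cfg.seed,
        "n_oligos": len(pool),
        "n_genes": int(len(frac_counts)),
        "elapsed_s": round(time.time() - t_start, 1),
        "gene_delta_lr_mean_targets": None if np.isnan(recovered) else float(recovered),
        "rbns_motif_trend_rho": r_rho,
        "rbns_motif_trend_p": r_p,
        "top_kmers": summary_kmer,
        "headline_contrasts": contrasts.to_dict("records"),
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
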