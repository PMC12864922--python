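"""Parameter-recovery studies: does the pipeline recover what was planted?

Each function runs a focused simulation through the real analysis path
and returns the recovered quantity, so the package's headline claims
(design constants, motif recovery, ΔLR/half-life/affinity recovery,
structure-based motif classification) can be checked end to end from a
single seed.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import design, localization, rbns, synthdata
from . import comparative_stats as cstats
from .config import SimConfig
from .pipeline import rbns_r_table, slam_tables
from .read_processing import quantify
from .structure import BasePairBackend, motif_pair_prob, positional_profile


def _random_pool(rng: np.random.Generator, n: int, length: int = 260) -> List[design.OligoRecord]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        design.OligoRecord(f"o{i}", "g", 0,
                           bases[rng.integers(0, 4, length)].tobytes().decode())
        for i in range(n)
    ]


def measure_design_constants(seed: int = 0) -> Dict[str, float]:
    """Observable design constants, measured from generated artifacts."""
    cfg = SimConfig(seed=seed, n_target_utrs=1, n_background_utrs=1, read_depth=50)
    utrs = synthdata.gen_utr_set(cfg)
    pool = design.assemble_pool([design.merge_meta_utr([r]) for r in utrs.records])
    var_lens = {len(r.variable_seq) for r in pool}
    full_lens = {len(r.full_seq) for r in pool}
    starts = sorted({r.start for r in pool})
    steps = {b - a for a, b in zip(starts, starts[1:])}
    # UMI length straight off a generated reverse read
    import tempfile

    truth = synthdata.annotate_pool_truth(pool, utrs.truth, cfg)
    with tempfile.TemporaryDirectory() as tmp:
        ab = pd.DataFrame({"s": np.ones(len(pool)) / len(pool)},
                          index=[r.oligo_id for r in pool])
        sheet = synthdata.gen_mpra_reads(pool, ab, cfg, tmp,
                                         np.random.default_rng(seed))
        from .config import REV_ADAPTER
        from .io import read_fastq_pairs

        _n, _f, _q, rev, _q2 = next(read_fastq_pairs(sheet["fastq1"][0],
                                                     sheet["fastq2"][0]))
        umi_len = len(rev) - len(REV_ADAPTER) - cfg.read_len

    # fold window layout measured by counting backend invocations
    calls: List[int] = []
    be = BasePairBackend()

    class _Recorder:
        def pair_probabilities(self, seq):
            calls.append(len(seq))
            return be.pair_probabilities(seq)

    positional_profile(pool[0].variable_seq, window=80, slide=10,
                       backend=_Recorder())
    assert len(set(calls)) == 1
    n_windows = len(calls)
    slide = (len(pool[0].variable_seq) - calls[0]) // (n_windows - 1)
    return {
        "tile_length_nt": var_lens.pop() if len(var_lens) == 1 else float("nan"),
        "tile_step_nt": steps.pop() if len(steps) == 1 else float("nan"),
        "handle_length_nt": (full_lens.pop() - 260) // 2 if len(full_lens) == 1 else float("nan"),
        "umi_length_nt": umi_len,
        "fold_window_nt": calls[0],
        "fold_slide_nt": slide,
        "n_fold_windows": n_windows,
    }


def motif_recovery(seed: int = 0) -> Tuple[List[str], int]:
    """Localization-driven 5-mer discovery at motif-discovery scale.

    Simulates a fractionation experiment over 40 occupied targets and 200
    background genes, labels genes by measured ΔLR, and runs the k-mer
    enrichment between the increased and unchanged 3' UTR sets. Returns
    the top-3 enriched 5-mers and how many are canonical TDP-43 motifs.
    """
    cfg = SimConfig(seed=seed, n_target_utrs=40, n_background_utrs=200,
                    frac_occupied=1.0, motif_context="neutral")
    utrs = synthdata.gen_utr_set(cfg)
    counts, samples = synthdata.gen_fractionation_counts(cfg, utrs.truth)
    lr = localization.gene_delta_lr(counts, samples)
    seqs = {r.gene_id: r.sequence for r in utrs.records}
    inc = [g for g in seqs
           if lr.loc[g, "delta_lr"] > 1 and lr.loc[g, "p_value"] < 0.05]
    unchanged = [g for g in seqs if g not in set(inc)]
    table = cstats.kmer_enrichment([seqs[g] for g in inc],
                                   [seqs[g] for g in unchanged])
    top3 = list(table.head(3)["kmer"])
    return top3, sum(k in design.MOTIFS for k in top3)


def delta_lr_recovery(seeds: Sequence[int]) -> List[float]:
    """Mean recovered ΔLR over the occupied-target genes, one value per seed."""
    out = []
    for seed in seeds:
        cfg = SimConfig(seed=seed)
        utrs = synthdata.gen_utr_set(cfg)
        counts, samples = synthdata.gen_fractionation_counts(cfg, utrs.truth)
        lr = localization.gene_delta_lr(counts, samples)
        occ = utrs.truth.loc[utrs.truth["planted_delta_lr"] > 0, "gene_id"]
        out.append(float(lr.loc[occ, "delta_lr"].mean()))
    return out


def slam_ratio_recovery(seed: int, halflife_h: float = 12.0,
                        n_oligos: int = 8, depth: int = 16_000) -> Dict[str, float]:
    """Recovered t12/t0 stability ratio for a planted half-life.

    The knockout is planted at twice the wild-type half-life, so the
    function also reports the recovered Δstability against its expected
    value log2(2^(-t/2h) / 2^(-t/h))."""
    import tempfile

    rng = np.random.default_rng(seed)
    pool = _random_pool(rng, n_oligos)
    truth = pd.DataFrame(
        {"planted_halflife_wt": halflife_h, "planted_halflife_ko": 2 * halflife_h},
        index=pd.Index([r.oligo_id for r in pool], name="oligo_id"),
    )
    cfg = SimConfig(seed=seed, read_depth=depth, replicates=1)
    with tempfile.TemporaryDirectory() as tmp:
        sheet = synthdata.gen_slam_reads(pool, truth, cfg, tmp,
                                         np.random.default_rng(seed))
        _c, _log, _conv, _rates, ratios, delta = slam_tables(
            sheet, pool, cfg.read_len, cfg.umi_length, min_T=200
        )
    wt = ratios[ratios["genotype"] == "WT"]["stability_ratio"].mean()
    t = cfg.timepoints_h[1]
    expected_delta = float(np.log2(2 ** (-t / (2 * halflife_h))) - np.log2(2 ** (-t / halflife_h)))
    return {
        "stability_ratio_wt": float(wt),
        "expected_ratio": float(2 ** (-t / halflife_h)),
        "delta_stability": float(delta["delta_stability"].mean()),
        "expected_delta": expected_delta,
    }


def affinity_rank_recovery(seeds: Sequence[int],
                           affinities: Sequence[float] = (1.0, 2.0, 4.0),
                           depth: int = 20_000) -> int:
    """Number of seeds in which mean R reproduces the planted affinity order."""
    import tempfile

    correct = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        pool = _random_pool(rng, len(affinities))
        ids = [r.oligo_id for r in pool]
        truth = pd.DataFrame(
            {"planted_affinity": list(affinities),
             "planted_halflife_wt": 6.0, "planted_halflife_ko": 6.0},
            index=pd.Index(ids, name="oligo_id"),
        )
        cfg = SimConfig(seed=seed, read_depth=depth, rbns_replicates=1,
                        concentrations_nM=(500.0,))
        with tempfile.TemporaryDirectory() as tmp:
            sheet = synthdata.gen_rbns_reads(pool, truth, cfg, tmp,
                                             np.random.default_rng(seed))
            counts, _ = quantify(sheet, {r.oligo_id: r.variable_seq for r in pool},
                                 cfg.read_len)
            mean_r = rbns.summarize_r(rbns_r_table(counts, sheet))
        want = [ids[i] for i in np.argsort(affinities)]
        correct += list(mean_r.reindex(ids).sort_values().index) == want
    return correct


def clip_density_fold(seed: int = 0, read_rate_kb: float = 500.0) -> Dict[str, float]:
    """Measured CLIP read density (reads/kb) inside vs outside peaks.

    Generates the default UTR set plus CLIP features at a dense read rate
    and recomputes the in/out density ratio from the emitted intervals."""
    cfg = SimConfig(seed=seed, clip_read_rate_kb=read_rate_kb)
    utrs = synthdata.gen_utr_set(cfg)
    lengths = {r.gene_id: r.length for r in utrs.records}
    peaks, reads = synthdata.gen_clip_features(
        utrs.truth, cfg, lengths, np.random.default_rng(seed)
    )
    peak_by = {c: g[["start", "end"]].to_numpy() for c, g in peaks.groupby("chrom")}
    n_in = 0
    for row in reads.itertuples(index=False):
        pk = peak_by.get(row.chrom)
        if pk is not None and ((pk[:, 0] < row.end) & (pk[:, 1] > row.start)).any():
            n_in += 1
    peak_bp = int((peaks["end"] - peaks["start"]).sum())
    total_bp = sum(lengths.values())
    dens_in = n_in / (peak_bp / 1000.0)
    dens_out = (len(reads) - n_in) / ((total_bp - peak_bp) / 1000.0)
    return {"density_fold": dens_in / dens_out, "n_reads": len(reads)}


def structure_classification(seed: int = 0) -> Dict[str, float]:
    """Accuracy of accessible-vs-stem motif classification by pairing score.

    Uses pool tiles whose planted motif context (A-rich accessible block
    or full hairpin) lies entirely inside the variable region, scores the
    planted motif intervals from the positional profile, and classifies
    at pairing probability 0.5."""
    cfg = SimConfig(seed=seed)
    utrs = synthdata.gen_utr_set(cfg)
    pool = design.assemble_pool([design.merge_meta_utr([r]) for r in utrs.records])
    context = utrs.truth.set_index("gene_id")["structural_context"]
    intervals = synthdata.truth_motif_intervals(utrs.truth)
    backend = BasePairBackend()
    n_ok = n_tot = 0
    scores = {"single_stranded": [], "paired": []}
    for rec in pool:
        if rec.is_mutant or context.get(rec.gene_id, "none") == "none":
            continue
        ctx = context[rec.gene_id]
        margin = cfg.ss_protect_nt if ctx == "single_stranded" else 30
        local = []
        for s, e, _occ in intervals.get(rec.gene_id, []):
            if s >= rec.start and e <= rec.start + len(rec.variable_seq):
                if s - rec.start >= margin and rec.start + 260 - e >= margin:
                    local.append((s - rec.start, e - rec.start))
                else:
                    local = []
                    break
        if not local:
            continue
        prof = positional_profile(rec.variable_seq, backend=backend)
        mean, _ = motif_pair_prob(prof, local)
        scores[ctx].append(mean)
        predicted = "paired" if mean > 0.5 else "single_stranded"
        n_ok += predicted == ctx
        n_tot += 1
    return {
        "accuracy": n_ok / n_tot if n_tot else float("nan"),
        "n_classified": n_tot,
        "mean_score_single_stranded": float(np.mean(scores["single_stranded"])),
        "mean_score_paired": float(np.mean(scores["paired"])),
    }
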