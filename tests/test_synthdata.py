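"""Synthetic-data generator: determinism, planted structure, read formats."""

import os

import numpy as np
import pandas as pd
import pytest

from tdploc import design, synthdata
from tdploc.config import SimConfig
from tdploc.design import find_motifs, hits_from_str
from tdploc.io import read_fastq_pairs, revcomp


def test_no_targets_gives_background_only():
    cfg = SimConfig(seed=1, n_target_utrs=0, n_background_utrs=5)
    utrs = synthdata.gen_utr_set(cfg)
    assert len(utrs.records) == 5
    assert not utrs.truth["is_target"].any()
    assert (utrs.truth["planted_delta_lr"] == 0).all()


def test_planted_motifs_found_by_independent_scan():
    cfg = SimConfig(seed=3, n_target_utrs=6, n_background_utrs=2)
    utrs = synthdata.gen_utr_set(cfg)
    for rec, row in zip(utrs.records, utrs.truth.itertuples(index=False)):
        hits = hits_from_str(row.motif_positions)
        if row.is_target:
            assert len(hits) >= cfg.motifs_per_target
        scan = {(m, s, e) for m, s, e in find_motifs(rec.sequence)}
        for m, s, e in hits:
            assert rec.sequence[s:e] == m
            assert (m, s, e) in scan


def test_too_short_utr_raises_sizing_error():
    with pytest.raises(ValueError, match="too short"):
        synthdata.gen_utr_set(SimConfig(seed=0, utr_length=120))


def test_same_seed_byte_identical_outputs(tmp_path):
    from tdploc.config import PipelineConfig

    cfg = PipelineConfig(seed=11)
    cfg.sim.read_depth = 300
    cfg.sim.n_target_utrs, cfg.sim.n_background_utrs = 2, 2
    a = synthdata.simulate_all(cfg, str(tmp_path / "a"))
    b = synthdata.simulate_all(cfg, str(tmp_path / "b"))
    for key in a:
        if key == "outdir":
            continue
        with open(a[key], "rb") as fa, open(b[key], "rb") as fb:
            assert fa.read() == fb.read(), key


@pytest.fixture(scope="module")
def mini_pool():
    cfg = SimConfig(seed=5, n_target_utrs=2, n_background_utrs=1)
    utrs = synthdata.gen_utr_set(cfg)
    kept, _ = design.filter_utrs(utrs.records)
    pool = design.assemble_pool([design.merge_meta_utr([r]) for r in kept])
    truth = synthdata.annotate_pool_truth(pool, utrs.truth, cfg)
    return cfg, utrs, pool, truth


def test_mpra_reads_zero_depth_and_exact_reconstruction(tmp_path, mini_pool):
    cfg, _utrs, pool, truth = mini_pool
    cfg = SimConfig(**{**cfg.__dict__, "read_depth": 0})
    rng = np.random.default_rng(0)
    ab, meta = synthdata.mpra_abundances(truth, cfg, rng)
    sheet = synthdata.gen_mpra_reads(pool, ab[ab.columns[:1]], cfg, str(tmp_path), rng)
    assert os.path.getsize(sheet["fastq1"][0]) == 0

    cfg = SimConfig(**{**cfg.__dict__, "read_depth": 500, "seq_error_rate": 0.0})
    sheet = synthdata.gen_mpra_reads(pool, ab[ab.columns[:1]], cfg,
                                     str(tmp_path / "clean"), np.random.default_rng(1))
    by_id = {r.oligo_id: r.variable_seq for r in pool}
    n = 0
    for name, fwd, q1, rev, q2 in read_fastq_pairs(sheet["fastq1"][0], sheet["fastq2"][0]):
        src = name.split("|")[1]
        var = by_id[src]
        assert fwd == synthdata.FWD_ADAPTER + var[: cfg.read_len]
        assert rev[len(synthdata.REV_ADAPTER) + cfg.umi_length:] == revcomp(var[-cfg.read_len:])
        assert len(q1) == len(fwd) and len(q2) == len(rev)
        n += 1
    assert n == 500  # multinomial counts conserve requested depth exactly


def test_mpra_equal_abundances_split_within_binomial_bound(tmp_path, mini_pool):
    cfg, _utrs, pool, _truth = mini_pool
    cfg = SimConfig(**{**cfg.__dict__, "read_depth": 10_000, "seq_error_rate": 0.0})
    two = pool[:2]
    ab = pd.DataFrame({"s": [0.5, 0.5]}, index=[r.oligo_id for r in two])
    sheet = synthdata.gen_mpra_reads(two, ab, cfg, str(tmp_path), np.random.default_rng(2))
    counts = {}
    for name, *_ in read_fastq_pairs(sheet["fastq1"][0], sheet["fastq2"][0]):
        src = name.split("|")[1]
        counts[src] = counts.get(src, 0) + 1
    assert sum(counts.values()) == 10_000
    for v in counts.values():
        assert abs(v - 5000) <= 3 * 50  # binomial sigma = 50


def test_rbns_file_layout_matches_design(tmp_path, mini_pool):
    """Three bound samples (500/50/5 nM) plus one input per replicate."""
    cfg, _utrs, pool, truth = mini_pool
    cfg = SimConfig(**{**cfg.__dict__, "read_depth": 50})
    sheet = synthdata.gen_rbns_reads(pool, truth, cfg, str(tmp_path))
    for rep, grp in sheet.groupby("replicate"):
        assert (grp["role"] == "input").sum() == 1
        bound = grp[grp["role"] == "bound"]
        assert sorted(bound["concentration"]) == [5.0, 50.0, 500.0]
    assert sheet["fastq1"].map(os.path.exists).all()


def test_slam_conversion_free_when_rates_zero(tmp_path, mini_pool):
    cfg, _utrs, pool, truth = mini_pool
    cfg = SimConfig(**{**cfg.__dict__, "read_depth": 200, "seq_error_rate": 0.0,
                       "conversion_rate_labeled": 0.0,
                       "background_conversion_rate": 0.0, "replicates": 1})
    sheet = synthdata.gen_slam_reads(pool, truth, cfg, str(tmp_path))
    by_id = {r.oligo_id: r.variable_seq for r in pool}
    for fq1, fq2 in zip(sheet["fastq1"], sheet["fastq2"]):
        for name, fwd, _q1, rev, _q2 in read_fastq_pairs(fq1, fq2):
            var = by_id[name.split("|")[1]]
            assert fwd == synthdata.FWD_ADAPTER + var[: cfg.read_len]


def test_slam_infinite_halflife_keeps_conversion_rate_flat(tmp_path, mini_pool):
    """half-life -> infinity: the t=12 conversion rate equals the t=0 rate
    within binomial error (stability ratio ~ 1)."""
    cfg, _utrs, pool, truth = mini_pool
    pool = pool[:3]
    truth = truth.loc[[r.oligo_id for r in pool]].copy()
    truth["planted_halflife_wt"] = np.inf
    truth["planted_halflife_ko"] = np.inf
    cfg = SimConfig(**{**cfg.__dict__, "read_depth": 3000, "seq_error_rate": 0.0,
                       "replicates": 1})
    sheet = synthdata.gen_slam_reads(pool, truth, cfg, str(tmp_path))
    by_id = {r.oligo_id: r.variable_seq for r in pool}
    rates = {}
    for row in sheet[sheet["genotype"] == "WT"].itertuples(index=False):
        tc = t_tot = 0
        for name, fwd, _q1, rev, _q2 in read_fastq_pairs(row.fastq1, row.fastq2):
            var = by_id[name.split("|")[1]]
            ref = var[: cfg.read_len]
            for a, b in zip(ref, fwd[len(synthdata.FWD_ADAPTER):]):
                if a == "T":
                    t_tot += 1
                    tc += b == "C"
        rates[row.timepoint] = tc / t_tot
    assert rates[0.0] > 0.02
    se = np.sqrt(rates[0.0] / 50_000)
    assert abs(rates[12.0] - rates[0.0]) < 4 * se + 0.004


def test_clip_features_cover_occupied_motifs(mini_pool):
    cfg, utrs, _pool, _truth = mini_pool
    lengths = {r.gene_id: r.length for r in utrs.records}
    peaks, reads = synthdata.gen_clip_features(utrs.truth, cfg, lengths,
                                               np.random.default_rng(0))
    iv = synthdata.truth_motif_intervals(utrs.truth)
    for gene, motifs in iv.items():
        pk = peaks[peaks["chrom"] == gene]
        for s, e, occ in motifs:
            if occ:
                inside = ((pk["start"] <= s) & (pk["end"] >= e)).sum()
                assert inside == 1  # exactly one (merged) peak contains it
    assert (peaks["start"] < peaks["end"]).all()
    # density contrast: reads/kb inside peaks well above outside
    total_peak = peaks.eval("end - start").sum()
    total_len = sum(lengths.values())
    n_in = 0
    for row in reads.itertuples(index=False):
        pk = peaks[peaks["chrom"] == row.chrom]
        n_in += bool(((pk["start"] < row.end) & (pk["end"] > row.start)).any())
    dens_in = n_in / max(total_peak, 1)
    dens_out = (len(reads) - n_in) / max(total_len - total_peak, 1)
    assert dens_in > 2.0 * dens_out


def test_clip_no_occupied_motifs_gives_empty_peaks():
    cfg = SimConfig(seed=2, n_target_utrs=4, n_background_utrs=0, frac_occupied=0.0)
    utrs = synthdata.gen_utr_set(cfg)
    lengths = {r.gene_id: r.length for r in utrs.records}
    peaks, _reads = synthdata.gen_clip_features(utrs.truth, cfg, lengths,
                                                np.random.default_rng(0))
    assert len(peaks) == 0


def test_fractionation_null_has_no_systematic_delta():
    cfg = SimConfig(seed=9, n_target_utrs=4, n_background_utrs=4,
                    delta_lr_occupied=0.0, delta_lr_motif_only=0.0)
    utrs = synthdata.gen_utr_set(cfg)
    counts, samples = synthdata.gen_fractionation_counts(cfg, utrs.truth)
    from tdploc.localization import gene_delta_lr

    res = gene_delta_lr(counts, samples)
    mean = res["delta_lr"].mean()
    se = res["delta_lr"].std() / np.sqrt(len(res))
    assert abs(mean) < 3 * se + 0.02
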