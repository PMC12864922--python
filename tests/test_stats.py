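"""Integrative statistics vs independent oracles; class assignment; joins."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import helpers
from tdploc import comparative_stats as cs


def test_fisher_matches_hypergeometric_oracle():
    """scipy's two-sided Fisher p equals direct hypergeometric summation to
    1e-12 on 100 random 2x2 tables."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        table = rng.integers(0, 40, size=(2, 2))
        p_scipy = sps.fisher_exact(table, alternative="two-sided")[1]
        p_oracle = helpers.fisher_two_sided(table)
        assert abs(p_scipy - p_oracle) < 1e-12


def test_wilcoxon_exact_matches_enumeration():
    """Exact branch equals full enumeration of rank assignments (n <= 8)."""
    rng = np.random.default_rng(1)
    assert cs.wilcoxon_ranksum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
    for _ in range(20):
        n1, n2 = rng.integers(2, 9, 2)
        pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
        x, y = pooled[:n1], pooled[n1:]
        assert cs.wilcoxon_ranksum(x, y) == pytest.approx(
            helpers.wilcoxon_exact_two_sided(x, y), abs=1e-12
        )


def test_wilcoxon_identical_groups_and_branch_agreement():
    assert cs.wilcoxon_ranksum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=1e-9)
    # exact vs normal-approximation branches agree near the size cutoff
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 25)
    y = rng.normal(0.3, 1, 25)
    p_exact = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
    p_pkg = cs.wilcoxon_ranksum(x, y)  # untied floats -> exact branch
    p_asym = sps.mannwhitneyu(x, y, method="asymptotic",
                              alternative="two-sided").pvalue
    assert p_pkg == pytest.approx(p_exact, abs=1e-12)
    assert abs(p_exact - p_asym) < 0.02


def test_kmer_enrichment_null_and_planted():
    seqs = ["ACGTACGTACGTAAACCCGGGTTT" * 3 for _ in range(5)]
    table = cs.kmer_enrichment(seqs, list(seqs))
    assert np.allclose(table["log2_enrichment"], 0.0)
    assert np.allclose(table["p"], 1.0)

    rng = np.random.default_rng(3)
    rand = lambda: "".join(rng.choice(list("ACGT"), 150))
    targets = [rand()[:70] + "GTGTG" + rand()[:75] for _ in range(12)]
    bg = [rand() for _ in range(60)]
    table = cs.kmer_enrichment(targets, bg)
    row = table.set_index("kmer").loc["GTGTG"]
    assert row["log2_enrichment"] > 0
    # Fisher p equals the oracle on the same 2x2 table
    oracle = helpers.fisher_two_sided(
        [[row["n_target_with"], row["n_target_without"]],
         [row["n_bg_with"], row["n_bg_without"]]]
    )
    assert row["p"] == pytest.approx(oracle, abs=1e-12)
    with pytest.raises(ValueError):
        cs.kmer_enrichment(targets, bg, k=0)


def test_clip_overlap_arithmetic():
    utrs = pd.DataFrame({"chrom": ["g1", "g2"], "start": 0, "end": [1000, 500]})
    peaks = pd.DataFrame({"chrom": ["g1"], "start": [100], "end": [150],
                          "name": "p", "score": ".", "strand": "+"})
    reads = pd.DataFrame({"chrom": ["g1"] * 10, "start": range(0, 1000, 100),
                          "end": range(30, 1030, 100), "name": "r",
                          "score": ".", "strand": "+"})
    per_utr, summary = cs.clip_overlap_stats(
        utrs, peaks, reads, {"g1": "increased", "g2": "unchanged"},
        control_group="unchanged",
    )
    g1 = per_utr.set_index("gene_id").loc["g1"]
    assert g1["has_peak"] and g1["read_density_kb"] == pytest.approx(10.0)
    assert not per_utr.set_index("gene_id").loc["g2", "has_peak"]
    empty_utr, _ = cs.clip_overlap_stats(utrs, peaks.iloc[:0], reads, {})
    assert not empty_utr["has_peak"].any()


def test_motif_class_boundaries():
    manifest = pd.DataFrame({
        "oligo_id": ["a", "b", "c", "d"],
        "gene_id": "g",
        "start": [0, 0, 0, 0],
        "is_mutant": [False, False, False, True],
        "motif_hits": ["", "GTGTG@10-15", "GTGTG@100-105", "GTGTG@10-15"],
    })
    # peak [15, 40): motif [10,15) is adjacent (0-nt overlap) -> no clip
    peaks = pd.DataFrame({"chrom": ["g"], "start": [15], "end": [40],
                          "name": "p", "score": ".", "strand": "+"})
    classes = cs.motif_class_assign(manifest, peaks)
    assert classes["a"] == "no_motif"
    assert classes["b"] == "motif_no_clip"
    assert classes["d"] == "mutant"
    peaks2 = pd.DataFrame({"chrom": ["g"], "start": [99], "end": [120],
                           "name": "p", "score": ".", "strand": "+"})
    classes = cs.motif_class_assign(manifest, peaks2)
    assert classes["c"] == "motif_clip"


def test_motifcount_stability_correlation():
    counts = pd.Series(np.repeat(np.arange(8), 70))
    rng = np.random.default_rng(4)
    flat = pd.Series(np.ones(len(counts)))
    _m, rho, _p = cs.motifcount_stability_correlation(counts, flat)
    assert rho == 0.0
    noisy = pd.Series(counts + rng.normal(0, 0.1, len(counts)))
    medians, rho, p = cs.motifcount_stability_correlation(counts, noisy)
    assert rho > 0.9 and p < 1e-6
    assert list(medians["bin"]) == ["0", "1", "2", "3", "4+"]
    assert cs.count_motifs("TGTGTGT") == 3  # overlap counting


def test_build_master_disjoint_ids_warns():
    manifest = pd.DataFrame({
        "oligo_id": ["a"], "gene_id": "g", "start": [0],
        "is_mutant": [False], "companion_id": [""], "n_motifs": [0],
        "motif_hits": [""],
    })
    peaks = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    with pytest.warns(UserWarning, match="empty"):
        master = cs.build_master(manifest, peaks,
                                 delta_lr=pd.Series({"zzz": 1.0}))
    assert np.isnan(master.loc["a", "delta_lr"])


def test_class_partition_is_exhaustive(small_pool):
    _cfg, pool, _truth = small_pool
    from tdploc.design import pool_manifest

    manifest = pool_manifest(pool)
    peaks = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    classes = cs.motif_class_assign(manifest, peaks)
    wild = manifest[~manifest["is_mutant"]]
    assert set(classes[wild["oligo_id"]]) <= set(cs.MOTIF_CLASSES)
    assert (classes[manifest[manifest["is_mutant"]]["oligo_id"]] == "mutant").all()
    has_motif = wild.set_index("oligo_id")["n_motifs"] > 0
    assert ((classes[wild["oligo_id"]] == "no_motif") == ~has_motif).all()
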