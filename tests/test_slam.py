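"""T>C conversion counting and pulse-chase stability ratios."""

import numpy as np
import pandas as pd
import pytest

from tdploc.slam import (ConversionCounter, conversion_rates, delta_stability,
                         stability_ratio)

REF = {"o1": "ACGT" * 65}  # 260 nt, 65 reference T positions


def _pair_for(var, read_len=130):
    return var[:read_len], var[-read_len:]


def test_conversion_counting_arithmetic():
    counter = ConversionCounter(REF, read_len=130)
    fwd, suf = _pair_for(REF["o1"])
    counter("o1", fwd, suf)  # perfect read: T positions covered, none converted
    assert counter.n_tc["o1"] == 0
    assert counter.n_t["o1"] == 65
    # convert 3 T positions on the forward mate
    mutated = list(fwd)
    for pos in (3, 7, 11):
        assert mutated[pos] == "T"
        mutated[pos] = "C"
    counter2 = ConversionCounter(REF, read_len=130)
    counter2("o1", "".join(mutated), suf)
    assert counter2.n_tc["o1"] == 3 and counter2.n_t["o1"] == 65
    # a non-T mismatch is a diagnostic, not a conversion
    other = "G" + fwd[1:]
    counter3 = ConversionCounter(REF, read_len=130)
    counter3("o1", other, suf)
    assert counter3.n_tc["o1"] == 0
    assert counter3.other_mismatch["o1"] == 1


def test_low_quality_t_positions_skipped():
    counter = ConversionCounter(REF, read_len=130)
    fwd, suf = _pair_for(REF["o1"])
    lowq = "!" * 130  # phred 0 everywhere
    counter("o1", fwd, suf, fwd_qual=lowq, suffix_qual=None)
    assert counter.n_t["o1"] == 33  # only the reverse mate's T positions


def _rates_df(rows):
    return pd.DataFrame(rows, columns=["oligo_id", "sample", "n_TC", "n_T",
                                       "other_mismatch"])


def test_stability_ratio_cases():
    samples = pd.DataFrame({
        "sample": ["wt0", "wt12", "ko0", "ko12"],
        "genotype": ["WT", "WT", "KO", "KO"],
        "timepoint": [0.0, 12.0, 0.0, 12.0],
    })
    conv = _rates_df([
        ("a", "wt0", 100, 10_000, 0), ("a", "wt12", 50, 10_000, 0),
        ("a", "ko0", 100, 10_000, 0), ("a", "ko12", 100, 10_000, 0),
        ("b", "wt0", 100, 10_000, 0), ("b", "wt12", 100, 10_000, 0),
        ("b", "ko0", 100, 10_000, 0), ("b", "ko12", 100, 10_000, 0),
        ("low", "wt0", 1, 50, 0), ("low", "wt12", 1, 50, 0),
        ("low", "ko0", 1, 50, 0), ("low", "ko12", 1, 50, 0),
    ])
    ratios = stability_ratio(conv, samples, min_T=200)
    wide = ratios.set_index(["oligo_id", "genotype"])["stability_ratio"]
    assert wide[("a", "WT")] == pytest.approx(0.5)   # 0.005 / 0.01
    assert wide[("a", "KO")] == pytest.approx(1.0)   # stable limit
    assert np.isnan(wide[("low", "WT")])             # below coverage floor
    delta = delta_stability(ratios)
    assert delta.loc["a", "delta_stability"] == pytest.approx(1.0)
    assert delta.loc["b", "delta_stability"] == pytest.approx(0.0)
    assert np.isnan(delta.loc["low", "delta_stability"])


def test_delta_requires_both_genotypes():
    samples = pd.DataFrame({"sample": ["wt0", "wt12"], "genotype": ["WT", "WT"],
                            "timepoint": [0.0, 12.0]})
    conv = _rates_df([("a", "wt0", 10, 1000, 0), ("a", "wt12", 5, 1000, 0)])
    ratios = stability_ratio(conv, samples)
    with pytest.raises(ValueError, match="KO"):
        delta_stability(ratios)


def _slam_sim(tmp_path, cfg, pool, truth, labeled=True):
    from tdploc import synthdata
    from tdploc.pipeline import slam_tables

    sheet = synthdata.gen_slam_reads(pool, truth, cfg, str(tmp_path),
                                     np.random.default_rng(cfg.seed), labeled=labeled)
    return slam_tables(sheet, pool, cfg.read_len, cfg.umi_length, min_T=200,
                       background_rate=0.0)


@pytest.fixture(scope="module")
def slam_pool():
    from tdploc.design import OligoRecord

    rng = np.random.default_rng(5)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    pool = [OligoRecord(f"o{i}", "g", 0,
                        bases[rng.integers(0, 4, 260)].tobytes().decode())
            for i in range(8)]
    return pool


def test_halflife_recovery_and_genotype_shift(tmp_path, slam_pool):
    """Planted 12 h half-life -> t12/t0 conversion ratio ~ 0.5; doubling the
    knockout half-life gives a positive log2 stability shift."""
    from tdploc.config import SimConfig

    truth = pd.DataFrame(
        {"planted_halflife_wt": 12.0, "planted_halflife_ko": 24.0},
        index=pd.Index([r.oligo_id for r in slam_pool], name="oligo_id"),
    )
    cfg = SimConfig(seed=6, read_depth=16_000, replicates=1)
    _c, _log, _conv, _rates, ratios, delta = _slam_sim(tmp_path, cfg, slam_pool, truth)
    wt = ratios[ratios["genotype"] == "WT"]["stability_ratio"]
    assert wt.mean() == pytest.approx(0.5, abs=0.06)
    assert (delta["delta_stability"] > 0).all()
    assert delta["delta_stability"].mean() == pytest.approx(
        np.log2((2 ** (-12 / 24)) / 0.5), abs=0.25
    )


def test_no_label_control_flat_ratios(tmp_path, slam_pool):
    """Without 4SU both timepoints sit at background and ratios are ~1."""
    from tdploc.config import SimConfig

    truth = pd.DataFrame(
        {"planted_halflife_wt": 6.0, "planted_halflife_ko": 6.0},
        index=pd.Index([r.oligo_id for r in slam_pool], name="oligo_id"),
    )
    cfg = SimConfig(seed=8, read_depth=16_000, replicates=1,
                    background_conversion_rate=0.004, seq_error_rate=0.0)
    _c, _log, conv, _rates, ratios, _delta = _slam_sim(
        tmp_path, cfg, slam_pool, truth, labeled=False
    )
    pooled = conv.groupby("sample")[["n_TC", "n_T"]].sum()
    rate = pooled["n_TC"] / pooled["n_T"]
    assert np.allclose(rate, 0.004, atol=0.001)
    assert ratios["stability_ratio"].mean() == pytest.approx(1.0, abs=0.1)
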