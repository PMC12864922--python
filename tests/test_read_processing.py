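"""Adapter trimming, UMI extraction, seeded assignment and UMI dedup."""

import numpy as np
import pandas as pd
import pytest

from tdploc import synthdata
from tdploc.config import FWD_ADAPTER, REV_ADAPTER, SimConfig
from tdploc.io import read_fastq_pairs, revcomp
from tdploc.read_processing import (PoolIndex, ProcessResult, count_umis,
                                    extract_umi, process_sample, quantify,
                                    trim_adapter, trim_adapters)


def test_trim_exact_and_mismatch_threshold():
    assert trim_adapter(FWD_ADAPTER + "ACGT", FWD_ADAPTER) == "ACGT"
    two_off = "TT" + FWD_ADAPTER[2:] + "ACGT"
    assert trim_adapter(two_off, FWD_ADAPTER) == "ACGT"
    three_off = "TTT" + FWD_ADAPTER[3:] + "ACGT"
    assert trim_adapter(three_off, FWD_ADAPTER) is None
    assert trim_adapter("ACG", FWD_ADAPTER) is None  # shorter than adapter
    # pair rejected if either mate fails
    assert trim_adapters(three_off, REV_ADAPTER + "A" * 20) is None


def test_extract_umi_variants():
    assert extract_umi("ACGTACGTNNNTTT") == ("ACGTACGT", "NNNTTT")
    assert extract_umi("ACGTACGTAA", umi_len=0) == ("", "ACGTACGTAA")
    umi, _rem = extract_umi("ACGTNCGTAAAA")
    assert umi == "ACGTNCGT"  # N kept as a literal symbol
    assert extract_umi("ACGTACGT") is None  # nothing left after the UMI


@pytest.fixture(scope="module")
def toy_index():
    rng = np.random.default_rng(0)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    vars_ = {}
    for i in range(20):
        vars_[f"oligo{i}"] = bases[rng.integers(0, 4, 260)].tobytes().decode()
    # a wild-type / mutant-companion style pair differing at 5 positions
    wt = vars_["oligo0"]
    mut = wt[:100] + "CACAC" + wt[105:]
    vars_["oligo0_mut"] = mut
    return vars_, PoolIndex(vars_, read_len=130)


def test_assignment_round_trip_and_mismatch_tolerance(toy_index):
    vars_, idx = toy_index
    for oid in ("oligo3", "oligo7"):
        var = vars_[oid]
        f, r = var[:130], revcomp(var[-130:])
        assert idx.assign(f, r) == oid
        # two mismatches per mate still assign
        f2 = "AC" if f[:2] == "CA" else "CA"
        assert idx.assign(f2 + f[2:], r[:64] + ("A" if r[64] != "A" else "C") + r[65:]) == oid
        # three mismatches on one mate do not
        f3 = list(f)
        for pos in (0, 50, 101):
            f3[pos] = "A" if f[pos] != "A" else "C"
        assert idx.assign("".join(f3), r) is None


def test_discordant_mates_unassigned(toy_index):
    vars_, idx = toy_index
    f = vars_["oligo1"][:130]
    r = revcomp(vars_["oligo2"][-130:])
    assert idx.assign(f, r) is None


def test_equidistant_wt_mutant_pair_is_a_tie(toy_index):
    """A read halfway between a wild-type oligo and its companion (which
    differ at 5 motif positions) is ambiguous -> unassigned; reads matching
    either exactly resolve correctly because 5 > max_mismatch."""
    vars_, idx = toy_index
    wt, mut = vars_["oligo0"], vars_["oligo0_mut"]
    rc = revcomp(wt[-130:])
    assert idx.assign(wt[:130], rc) == "oligo0"
    assert idx.assign(mut[:130], rc) == "oligo0_mut"
    halfway = wt[:100] + "CAC" + wt[103:130]  # 3 mismatches to either: >2
    assert idx.assign(halfway, rc) is None


def test_count_umis_dedup_and_explicit_zero_rows():
    res = ProcessResult("s1")
    for umi in ["AAAAAAAA", "AAAAAAAA", "CCCCCCCC", "CCCCCCCC", "GGGGGGGG"]:
        res.umis["oligoA"].add(umi)
    table = count_umis([res], ["oligoA", "oligoB"])
    assert table.loc["oligoA", "s1"] == 3
    assert table.loc["oligoB", "s1"] == 0


def _simulate_and_process(tmp_path, error_rate, depth=4000, umi_length=8):
    cfg = SimConfig(seed=21, n_target_utrs=1, n_background_utrs=1,
                    read_depth=depth, seq_error_rate=error_rate,
                    umi_length=umi_length)
    utrs = synthdata.gen_utr_set(cfg)
    from tdploc import design

    pool = design.assemble_pool(
        [design.merge_meta_utr([r]) for r in utrs.records]
    )[:40]
    truth = synthdata.annotate_pool_truth(pool, utrs.truth, cfg)
    ab = pd.DataFrame({"s": np.ones(len(pool)) / len(pool)},
                      index=[r.oligo_id for r in pool])
    sheet = synthdata.gen_mpra_reads(pool, ab, cfg, str(tmp_path),
                                     np.random.default_rng(4))
    vars_ = {r.oligo_id: r.variable_seq for r in pool}
    idx = PoolIndex(vars_, cfg.read_len)
    res = process_sample(sheet["fastq1"][0], sheet["fastq2"][0], idx, "s",
                         umi_len=cfg.umi_length)
    return cfg, sheet, vars_, res


def test_error_free_run_keeps_and_assigns_every_pair(tmp_path):
    cfg, sheet, vars_, res = _simulate_and_process(tmp_path, 0.0)
    assert res.total == cfg.read_depth
    assert res.rejected_adapter == res.rejected_short == res.unassigned == 0
    assert res.assigned == res.total
    # assignment accuracy: every read returns to its source oligo
    idx = PoolIndex(vars_, cfg.read_len)
    for name, fwd, _q, rev, _q2 in read_fastq_pairs(sheet["fastq1"][0], sheet["fastq2"][0]):
        src = name.split("|")[1]
        f, r = trim_adapters(fwd, rev)
        _umi, rem = extract_umi(r, cfg.umi_length)
        assert idx.assign(f, rem) == src


def test_bookkeeping_partition_and_retention_at_default_error(tmp_path):
    cfg, _sheet, _vars, res = _simulate_and_process(tmp_path, 0.002)
    stats = res.stats
    assert (stats["rejected_adapter"] + stats["rejected_short"]
            + stats["unassigned"] + stats["assigned"]) == stats["total"]
    assert stats["assigned"] / stats["total"] >= 0.95


def test_umi_saturation_bounded_by_alphabet(tmp_path):
    """Depth far above 4^umi_len saturates unique-UMI counts (pigeonhole)."""
    cfg, _sheet, vars_, res = _simulate_and_process(tmp_path, 0.0, depth=2000,
                                                    umi_length=2)
    counts = count_umis([res], list(vars_))
    assert counts["s"].max() <= 4 ** 2
    assert counts["s"].sum() < res.assigned  # heavy collision regime


def test_empty_index_rejected():
    with pytest.raises(ValueError, match="empty"):
        PoolIndex({}, 130)
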