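"""SLAM-seq conversion counting and pulse-chase stability ratios.

After pulse labeling with 4SU and chase, the labeled fraction of an
RNA's molecules decays with its half-life, and labeling is read out as
T>C conversions at reference-T positions. Per oligo and sample the
conversion rate is pooled n_TC / n_T; the stability ratio of an oligo in
a genotype is rate(t=12 h) / rate(t=0 h), and the genotype effect is
Δstability = log2(ratio_KO / ratio_WT) — positive when the knockout
stabilizes the RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

DEFAULT_MIN_T = 200
MIN_BASE_QUAL = 20  # phred floor when qualities are present


@dataclass
class ConversionCounter:
    """Accumulates per-oligo T>C conversion counts for one sample.

    Feed with assigned read pairs in molecule orientation (the
    read-processing callback); reference-T positions below the Q20 base
    quality floor are skipped when qualities are present. Mismatches at
    non-T reference positions are tallied as diagnostics only.
    """

    reference: Dict[str, str]
    read_len: int
    n_tc: Dict[str, int] = field(default_factory=dict)
    n_t: Dict[str, int] = field(default_factory=dict)
    other_mismatch: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self._ref_arr = {}
        for oid, var in self.reference.items():
            rl = self.read_len
            pre = np.frombuffer(var[:rl].encode(), dtype=np.uint8)
            suf = np.frombuffer(var[-rl:].encode(), dtype=np.uint8)
            self._ref_arr[oid] = (pre, pre == ord("T"), suf, suf == ord("T"))

    def _count_one(self, oid: str, read: str, ref: np.ndarray, is_t: np.ndarray,
                   qual: str | None) -> None:
        arr = np.frombuffer(read.encode(), dtype=np.uint8)
        if arr.shape != ref.shape:
            return
        usable = is_t
        if qual is not None:
            q = np.frombuffer(qual.encode(), dtype=np.uint8) - 33
            if q.shape == arr.shape:
                usable = is_t & (q >= MIN_BASE_QUAL)
        self.n_t[oid] = self.n_t.get(oid, 0) + int(usable.sum())
        self.n_tc[oid] = self.n_tc.get(oid, 0) + int((arr[usable] == ord("C")).sum())
        mism = (arr != ref) & ~is_t
        self.other_mismatch[oid] = self.other_mismatch.get(oid, 0) + int(mism.sum())

    def __call__(self, oid: str, fwd_seq: str, suffix_seq: str,
                 fwd_qual: str | None = None, suffix_qual: str | None = None) -> None:
        pre, pre_t, suf, suf_t = self._ref_arr[oid]
        self._count_one(oid, fwd_seq, pre, pre_t, fwd_qual)
        self._count_one(oid, suffix_seq, suf, suf_t, suffix_qual)

    def table(self, sample: str) -> pd.DataFrame:
        oids = sorted(self.reference)
        return pd.DataFrame(
            {
                "oligo_id": oids,
                "sample": sample,
                "n_TC": [self.n_tc.get(o, 0) for o in oids],
                "n_T": [self.n_t.get(o, 0) for o in oids],
                "other_mismatch": [self.other_mismatch.get(o, 0) for o in oids],
            }
        )


def conversion_rates(conv: pd.DataFrame, min_T: int = DEFAULT_MIN_T) -> pd.DataFrame:
    """Pooled per-oligo conversion rate n_TC/n_T per sample (NA below min_T)."""
    df = conv.copy()
    df["rate"] = np.where(
        (df["n_T"] >= max(min_T, 1)), df["n_TC"] / df["n_T"].clip(lower=1), np.nan
    )
    return df


def stability_ratio(
    rates: pd.DataFrame,
    samples: pd.DataFrame,
    min_T: int = DEFAULT_MIN_T,
    background_rate: float = 0.0,
) -> pd.DataFrame:
    """Per-genotype t=12 h / t=0 h conversion-rate ratios per oligo.

    `rates` carries oligo_id/sample/rate; `samples` maps samples to
    genotype/timepoint. Replicate rates are pooled (summed counts) per
    (genotype, timepoint) before the ratio. Optional background
    subtraction removes a no-4SU conversion floor; the result is NA where
    coverage is below min_T or the t=0 rate is zero.
    """
    merged = rates.merge(samples[["sample", "genotype", "timepoint"]], on="sample")
    tps = sorted(merged["timepoint"].unique())
    if len(tps) != 2:
        raise ValueError(f"need exactly two timepoints, got {tps}")
    t0, t1 = tps
    pooled = (
        merged.groupby(["oligo_id", "genotype", "timepoint"])[["n_TC", "n_T"]]
        .sum()
        .reset_index()
    )
    pooled["rate"] = np.where(
        pooled["n_T"] >= max(min_T, 1),
        pooled["n_TC"] / pooled["n_T"].clip(lower=1) - background_rate,
        np.nan,
    )
    wide = pooled.pivot(index=["oligo_id", "genotype"], columns="timepoint", values="rate")
    ratio = wide[t1] / wide[t0].where(wide[t0] > 0)
    out = ratio.rename("stability_ratio").reset_index()
    out["rate_t0"] = wide[t0].to_numpy()
    out["rate_t1"] = wide[t1].to_numpy()
    return out


def delta_stability(ratios: pd.DataFrame) -> pd.DataFrame:
    """Δstability = log2(ratio_KO / ratio_WT) per oligo."""
    wide = ratios.pivot(index="oligo_id", columns="genotype", values="stability_ratio")
    missing = {"WT", "KO"} - set(wide.columns)
    if missing:
        raise ValueError(f"missing genotype(s): {sorted(missing)}")
    out = pd.DataFrame(index=wide.index)
    out["ratio_wt"] = wide["WT"]
    out["ratio_ko"] = wide["KO"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["delta_stability"] = np.log2(wide["KO"] / wide["WT"])
    out.loc[~np.isfinite(out["delta_stability"]), "delta_stability"] = np.nan
    return out
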