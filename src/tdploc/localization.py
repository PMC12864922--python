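"""Localization ratios and genotype contrasts.

The central statistic is the Localization Ratio of a feature (gene or
reporter oligo): LR = log2(relative abundance in the neurite fraction /
relative abundance in the cell-body fraction), and its knockout-minus-
wild-type difference ΔLR. Relative abundances are pseudocounted
total-count fractions; ΔLR significance is a two-sided Welch t across
replicate LRs with Benjamini-Hochberg FDR across features. The module
also carries the small targeted statistics of the same study design:
positional rolling ΔLR profiles along a UTR, ΔΔCt reporter fold
enrichment, and per-cell smFISH projection/soma spot ratios.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comparative_stats import wilcoxon_ranksum


def normalize_counts(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-sample relative abundances: (count + pc) / sum(count + pc)."""
    zero = counts.sum(axis=0) == 0
    if zero.any():
        raise ValueError(f"all-zero sample(s): {', '.join(counts.columns[zero])}")
    shifted = counts.astype(float) + pseudocount
    return shifted / shifted.sum(axis=0)


def compute_lr(
    rel: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature, per (genotype, replicate) LR from replicate-matched
    neurite/soma relative abundances.

    `samples` needs columns sample/compartment/genotype/replicate; each
    (genotype, replicate) must have exactly one neurite and one soma
    sample.
    """
    out = {}
    for (genotype, rep), grp in samples.groupby(["genotype", "replicate"]):
        comp = grp.set_index("compartment")["sample"]
        if not {"neurite", "soma"} <= set(comp.index):
            raise ValueError(
                f"genotype {genotype} replicate {rep}: need matched neurite and soma samples"
            )
        out[(genotype, rep)] = np.log2(rel[comp["neurite"]] / rel[comp["soma"]])
    lr = pd.DataFrame(out)
    lr.columns = pd.MultiIndex.from_tuples(lr.columns, names=["genotype", "replicate"])
    return lr


def delta_lr_test(lr: pd.DataFrame, method: str = "welch") -> pd.DataFrame:
    """ΔLR = mean LR(KO) - mean LR(WT) with a two-sided Welch t and BH FDR.

    With fewer than two replicates in either genotype the estimate is
    still reported but statistic/p are NA ("insufficient replicates").
    """
    if method != "welch":
        raise ValueError(f"unknown method {method!r}")
    wt = lr["WT"].to_numpy(float)
    ko = lr["KO"].to_numpy(float)
    res = pd.DataFrame(index=lr.index)
    res["mean_lr_wt"] = wt.mean(axis=1)
    res["mean_lr_ko"] = ko.mean(axis=1)
    res["delta_lr"] = res["mean_lr_ko"] - res["mean_lr_wt"]
    res["n_wt"] = wt.shape[1]
    res["n_ko"] = ko.shape[1]
    if wt.shape[1] >= 2 and ko.shape[1] >= 2:
        stat, p = stats.ttest_ind(ko, wt, axis=1, equal_var=False)
        # identical degenerate vectors give nan; call them no-change
        same = np.isnan(p)
        p = np.where(same, 1.0, p)
        stat = np.where(same, 0.0, stat)
        res["statistic"] = stat
        res["p_value"] = p
        res["fdr"] = multipletests(p, method="fdr_bh")[1]
    else:
        res["statistic"] = np.nan
        res["p_value"] = np.nan
        res["fdr"] = np.nan
    return res


def gene_delta_lr(
    counts: pd.DataFrame, samples: pd.DataFrame, pseudocount: float = 0.5,
    method: str = "welch",
) -> pd.DataFrame:
    """Counts + sample sheet -> LrTable (normalize, LR, ΔLR test)."""
    rel = normalize_counts(counts, pseudocount)
    lr = compute_lr(rel, samples)
    return delta_lr_test(lr, method=method)


def rolling_profile(
    delta_lr: pd.Series, starts: pd.Series, window: int = 5
) -> pd.DataFrame:
    """Centered rolling mean of ΔLR by tile start position (one gene,
    wild-type tiles only, ends shrink to the available tiles)."""
    df = pd.DataFrame({"start": starts, "delta_lr": delta_lr}).sort_values("start")
    df["rolling_delta_lr"] = (
        df["delta_lr"].rolling(window, center=True, min_periods=1).mean()
    )
    return df.reset_index(drop=True)


def ddct_fold(
    ct_target_cond: float, ct_ref_cond: float,
    ct_target_ctrl: float, ct_ref_ctrl: float,
) -> float:
    """Reporter fold enrichment by the ΔΔCt method: 2^-ΔΔCt."""
    for v in (ct_target_cond, ct_ref_cond, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** -ddct)


def smfish_ratio(
    projection: Sequence[float], soma: Sequence[float],
    groups: Sequence[str] | None = None,
) -> Tuple[pd.DataFrame, float | None, List[int]]:
    """Per-cell projection/soma spot ratio + two-group Wilcoxon rank-sum.

    Cells with zero soma spots are excluded (their indices are returned
    as the exclusion log). When `groups` labels two groups, the two-sided
    rank-sum p value for their ratios is returned, else None.
    """
    proj = np.asarray(projection, float)
    som = np.asarray(soma, float)
    if proj.shape != som.shape:
        raise ValueError("projection and soma must be the same length")
    excluded = [int(i) for i in np.nonzero(som == 0)[0]]
    keep = som > 0
    table = pd.DataFrame({
        "cell": np.arange(len(proj))[keep],
        "ratio": proj[keep] / som[keep],
    })
    p = None
    if groups is not None:
        grp = np.asarray(groups)[keep]
        table["group"] = grp
        names = pd.unique(grp)
        if len(names) == 2:
            a = table.loc[table["group"] == names[0], "ratio"]
            b = table.loc[table["group"] == names[1], "ratio"]
            p = wilcoxon_ranksum(a, b)
    return table, p, excluded
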