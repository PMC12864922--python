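"""RBNS enrichment: relative in vitro affinities (R values) per oligo.

R for an oligo is its depth-normalized frequency in a protein-bound pool
divided by its frequency in the input pool. R is reported per
(concentration, replicate) sample, with the unweighted mean across bound
samples as the summary; oligos whose input count falls below a floor are
NA'd because ratio variance explodes at small denominators.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

DEFAULT_MIN_INPUT = 10


def compute_r(
    bound: pd.DataFrame, input_counts: pd.Series, min_input: int = DEFAULT_MIN_INPUT
) -> pd.DataFrame:
    """R per oligo per bound sample: (bound freq) / (input freq).

    `bound` is oligos x bound samples, `input_counts` the matched input
    sample. Oligos with input count < min_input are NA.
    """
    if input_counts is None or len(input_counts) == 0:
        raise ValueError("missing input sample")
    input_counts = input_counts.reindex(bound.index)
    in_total = input_counts.sum()
    b_tot = bound.sum(axis=0)
    if in_total <= 0 or (b_tot <= 0).any():
        raise ValueError("input and bound samples need positive totals")
    in_freq = input_counts / in_total
    r = (bound / b_tot).div(in_freq, axis=0)
    r[input_counts < min_input] = np.nan
    return r


def summarize_r(r_by_sample: pd.DataFrame) -> pd.Series:
    """Unweighted mean R across bound samples (per-sample NAs excluded)."""
    return r_by_sample.mean(axis=1)


def concentration_concordance(
    r_by_sample: pd.DataFrame,
) -> Tuple[pd.DataFrame, list]:
    """Pairwise Spearman correlation of log R across samples + an
    average-linkage clustering order on distance 1 - rho (NA pairwise
    exclusion)."""
    if r_by_sample.shape[1] < 2:
        raise ValueError("need >=2 samples for concordance")
    logr = np.log(r_by_sample.replace(0, np.nan))
    cols = list(logr.columns)
    n = len(cols)
    rho = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    for i in range(n):
        for j in range(i + 1, n):
            pair = logr.iloc[:, [i, j]].dropna()
            val = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic if len(pair) > 2 else np.nan
            rho.iloc[i, j] = rho.iloc[j, i] = val
    dist = 1.0 - rho.fillna(0.0).to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    order = [cols[i] for i in leaves_list(average(squareform(dist, checks=False)))]
    return rho, order


def r_by_motif_count(
    mean_r: pd.Series, motif_counts: pd.Series, low_n: int = 5
) -> Tuple[pd.DataFrame, float, float]:
    """Median R per motif-count bin + Spearman trend test on unbinned values.

    Returns (per-bin table with a low-n flag, rho, p)."""
    df = pd.DataFrame({"r": mean_r, "n_motifs": motif_counts}).dropna()
    bins = (
        df.groupby("n_motifs")["r"]
        .agg(median_r="median", n="size")
        .reset_index()
    )
    bins["low_n"] = bins["n"] < low_n
    if df["n_motifs"].nunique() < 2 or df["r"].nunique() < 2:
        return bins, 0.0, 1.0
    res = stats.spearmanr(df["n_motifs"], df["r"])
    return bins, float(res.statistic), float(res.pvalue)
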