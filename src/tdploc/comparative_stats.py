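"""Integrative statistics across the localization, binding and stability assays.

5-mer enrichment between UTR sets (per-UTR presence/absence, Fisher exact,
BH FDR), CLIP peak-overlap and read-density contrasts, Wilcoxon rank-sum
group comparisons (exact for small untied groups, normal approximation
with continuity correction otherwise), motif/CLIP class assignment for
pool oligos, motif-count vs stability-change correlation, and the master
per-oligo join that drives the headline contrast suite.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import design

EXACT_MAX_N = 25
MOTIF_CLASSES = ("no_motif", "motif_no_clip", "motif_clip")


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p value.

    Exact null when min(n1, n2) <= 25 and the pooled sample has no ties;
    otherwise the normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(x), len(y)) <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(1.0, res.pvalue))


def all_kmers(k: int) -> List[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def kmer_enrichment(
    target_seqs: Sequence[str], background_seqs: Sequence[str], k: int = 5
) -> pd.DataFrame:
    """Per-UTR presence/absence k-mer enrichment of targets vs background.

    For every k-mer a 2x2 Fisher exact test (two-sided) on
    with/without counts, a pseudocounted log2 enrichment of presence
    fractions, and BH FDR across all 4^k k-mers; rows are ranked by
    enrichment (ties by p)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if not target_seqs or not background_seqs:
        raise ValueError("both sequence sets must be non-empty")

    def presence(seqs):
        counts = {}
        for seq in seqs:
            seq = seq.upper().replace("U", "T")
            seen = {seq[i : i + k] for i in range(len(seq) - k + 1)}
            for kmer in seen:
                counts[kmer] = counts.get(kmer, 0) + 1
        return counts

    t_with = presence(target_seqs)
    b_with = presence(background_seqs)
    nt, nb = len(target_seqs), len(background_seqs)
    rows = []
    for kmer in all_kmers(k):
        tw = t_with.get(kmer, 0)
        bw = b_with.get(kmer, 0)
        table = [[tw, nt - tw], [bw, nb - bw]]
        p = stats.fisher_exact(table, alternative="two-sided")[1]
        enr = np.log2(((tw + 0.5) / (nt + 1)) / ((bw + 0.5) / (nb + 1)))
        rows.append(
            {"kmer": kmer, "n_target_with": tw, "n_target_without": nt - tw,
             "n_bg_with": bw, "n_bg_without": nb - bw,
             "log2_enrichment": enr, "p": p}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["is_canonical_motif"] = out["kmer"].isin(design.MOTIFS)
    return out.sort_values(
        ["log2_enrichment", "p"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# interval overlap
# ---------------------------------------------------------------------------

def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    """>=1 nt overlap in half-open coordinates."""
    return max(s1, s2) < min(e1, e2)


def clip_overlap_stats(
    utr_intervals: pd.DataFrame,
    peaks: pd.DataFrame,
    reads: pd.DataFrame,
    groups: Mapping[str, str],
    control_group: str | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-UTR peak overlap + read density, summarized per group.

    `utr_intervals` needs chrom/start/end (one row per UTR, chrom = gene);
    returns (per-UTR table, per-group summary with fold ratios vs the
    control group)."""
    peak_by = {c: g[["start", "end"]].to_numpy() for c, g in peaks.groupby("chrom")} if len(peaks) else {}
    read_by = {c: g[["start", "end"]].to_numpy() for c, g in reads.groupby("chrom")} if len(reads) else {}
    rows = []
    for row in utr_intervals.itertuples(index=False):
        gene, s, e = row.chrom, int(row.start), int(row.end)
        pk = peak_by.get(gene, np.empty((0, 2), int))
        rd = read_by.get(gene, np.empty((0, 2), int))
        has_peak = bool(((pk[:, 0] < e) & (pk[:, 1] > s)).any()) if len(pk) else False
        n_reads = int(((rd[:, 0] < e) & (rd[:, 1] > s)).sum()) if len(rd) else 0
        kb = (e - s) / 1000.0
        rows.append(
            {"gene_id": gene, "group": groups.get(gene, "unassigned"),
             "has_peak": has_peak, "n_reads": n_reads,
             "read_density_kb": n_reads / kb if kb > 0 else np.nan}
        )
    per_utr = pd.DataFrame(rows)
    summary = (
        per_utr.groupby("group")
        .agg(n=("gene_id", "size"), frac_with_peak=("has_peak", "mean"),
             mean_density=("read_density_kb", "mean"))
        .reset_index()
    )
    if control_group is not None and control_group in set(summary["group"]):
        ctrl = summary.set_index("group").loc[control_group]
        summary["peak_fraction_fold"] = summary["frac_with_peak"] / ctrl["frac_with_peak"] if ctrl["frac_with_peak"] > 0 else np.nan
        summary["density_fold"] = summary["mean_density"] / ctrl["mean_density"] if ctrl["mean_density"] > 0 else np.nan
    return per_utr, summary


def group_compare(values: Sequence[float], labels: Sequence[str]) -> pd.DataFrame:
    """Median per group + pairwise two-sided Wilcoxon rank-sum contrasts."""
    df = pd.DataFrame({"value": np.asarray(values, float), "group": labels}).dropna()
    names = list(pd.unique(df["group"]))
    rows = []
    for a, b in itertools.combinations(names, 2):
        va = df.loc[df["group"] == a, "value"]
        vb = df.loc[df["group"] == b, "value"]
        rows.append(
            {"group_a": a, "group_b": b, "n_a": len(va), "n_b": len(vb),
             "median_a": va.median(), "median_b": vb.median(),
             "p": wilcoxon_ranksum(va, vb)}
        )
    return pd.DataFrame(rows)


def motif_class_assign(
    manifest: pd.DataFrame, peaks: pd.DataFrame
) -> pd.Series:
    """Class per pool oligo: no_motif / motif_no_clip / motif_clip.

    motif_clip iff any motif interval (in meta-UTR coordinates: tile
    start + local offset) overlaps any CLIP peak of the oligo's gene by
    >=1 nt (half-open). Mutant companions are labeled "mutant"."""
    peak_by = {c: g[["start", "end"]].to_numpy() for c, g in peaks.groupby("chrom")} if len(peaks) else {}
    out = []
    for row in manifest.itertuples(index=False):
        if row.is_mutant:
            out.append("mutant")
            continue
        hits = design.hits_from_str(row.motif_hits)
        if not hits:
            out.append("no_motif")
            continue
        pk = peak_by.get(row.gene_id, np.empty((0, 2), int))
        clipped = False
        for _m, s, e in hits:
            gs, ge = row.start + s, row.start + e
            if len(pk) and ((pk[:, 0] < ge) & (pk[:, 1] > gs)).any():
                clipped = True
                break
        out.append("motif_clip" if clipped else "motif_no_clip")
    return pd.Series(out, index=manifest["oligo_id"], name="motif_class")


def count_motifs(seq: str) -> int:
    """All overlapping canonical-motif occurrences in a sequence."""
    return len(design.find_motifs(seq))


def motifcount_stability_correlation(
    motif_counts: pd.Series, stability_change: pd.Series,
    bins: Sequence[int] = (0, 1, 2, 3, 4),
) -> Tuple[pd.DataFrame, float, float]:
    """Binned medians of stability change by 3' UTR motif count + Spearman.

    Counts >= the last bin edge are pooled into a "4+" style bin; the
    correlation is computed on the unbinned values."""
    df = pd.DataFrame({"n_motifs": motif_counts, "value": stability_change}).dropna()
    top = bins[-1]
    df["bin"] = df["n_motifs"].clip(upper=top).astype(int).astype(str)
    df.loc[df["n_motifs"] >= top, "bin"] = f"{top}+"
    medians = df.groupby("bin")["value"].agg(["median", "size"]).reset_index()
    if df["value"].nunique() < 2 or df["n_motifs"].nunique() < 2:
        return medians, 0.0, 1.0
    res = stats.spearmanr(df["n_motifs"], df["value"])
    return medians, float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# master join and headline contrasts
# ---------------------------------------------------------------------------

def build_master(
    manifest: pd.DataFrame,
    peaks: pd.DataFrame,
    delta_lr: pd.Series | None = None,
    mean_r: pd.Series | None = None,
    delta_stab: pd.Series | None = None,
    motif_pair_prob: pd.Series | None = None,
) -> pd.DataFrame:
    """Outer join of every per-oligo measurement keyed on oligo_id."""
    master = manifest.set_index("oligo_id")[
        ["gene_id", "start", "is_mutant", "companion_id", "n_motifs"]
    ].copy()
    master["motif_class"] = motif_class_assign(manifest, peaks)
    for name, series in (
        ("delta_lr", delta_lr), ("mean_r", mean_r),
        ("delta_stability", delta_stab), ("motif_pair_prob", motif_pair_prob),
    ):
        master[name] = series.reindex(master.index) if series is not None else np.nan
    if master[["delta_lr", "mean_r", "delta_stability"]].notna().sum().sum() == 0:
        warnings.warn("master join is empty: no measurement shares ids with the manifest")
    return master


def _contrast(name, va, vb, label_a, label_b):
    va = pd.Series(va).dropna()
    vb = pd.Series(vb).dropna()
    if len(va) == 0 or len(vb) == 0:
        return None
    return {
        "contrast": name, "group_a": label_a, "group_b": label_b,
        "n_a": len(va), "n_b": len(vb),
        "median_a": float(va.median()), "median_b": float(vb.median()),
        "p": wilcoxon_ranksum(va, vb),
    }


def headline_contrasts(master: pd.DataFrame, structure_q: float = 0.20) -> pd.DataFrame:
    """The contrast suite connecting the three assays on one pool.

    For each measured quantity (ΔLR, R, Δstability): motif/CLIP classes
    against motif-free oligos, wild-type motif_clip oligos against their
    mutant companions, and for ΔLR additionally the bottom vs top
    structure quantiles of motif pairing probability."""
    rows = []
    wild = master[~master["is_mutant"]]
    by_class = {c: wild[wild["motif_class"] == c] for c in MOTIF_CLASSES}
    mutants = master[master["is_mutant"]]
    for metric in ("delta_lr", "mean_r", "delta_stability"):
        for cls in ("motif_no_clip", "motif_clip"):
            row = _contrast(f"{metric}:{cls}_vs_no_motif",
                            by_class[cls][metric], by_class["no_motif"][metric],
                            cls, "no_motif")
            if row:
                rows.append(row)
        # wild-type motif_clip oligos vs their own mutant companions
        wt_clip = by_class["motif_clip"]
        comp = wt_clip["companion_id"].dropna()
        mut_vals = master[metric].reindex(comp[comp.isin(master.index)])
        row = _contrast(f"{metric}:motif_clip_vs_mutant",
                        wt_clip[metric], mut_vals, "motif_clip_wt", "mutant")
        if row:
            rows.append(row)
    scored = wild.dropna(subset=["motif_pair_prob", "delta_lr"])
    if len(scored) >= 5:
        ranked = scored.sort_values(["motif_pair_prob"], kind="mergesort")
        k = int(np.ceil(structure_q * len(ranked)))
        bottom, top = ranked.head(k), ranked.tail(k)
        row = _contrast("delta_lr:bottom20_vs_top20_structure",
                        bottom["delta_lr"], top["delta_lr"],
                        "single_stranded_motifs", "paired_motifs")
        if row:
            rows.append(row)
    # affinity quantiles vs localization: do the strongest binders move most?
    bound = wild.dropna(subset=["mean_r", "delta_lr"])
    if len(bound) >= 10:
        ranked = bound.sort_values(["mean_r"], kind="mergesort")
        k = int(np.ceil(structure_q * len(ranked)))
        row = _contrast("delta_lr:top20_r_vs_bottom20_r",
                        ranked.tail(k)["delta_lr"], ranked.head(k)["delta_lr"],
                        "high_affinity", "low_affinity")
        if row:
            rows.append(row)
    # stability change by measured localization direction
    stab = wild.dropna(subset=["delta_stability", "delta_lr"])
    if len(stab) >= 10:
        increased = stab[stab["delta_lr"] > 1]
        unchanged = stab[stab["delta_lr"].abs() <= 1]
        row = _contrast("delta_stability:increased_lr_vs_unchanged",
                        increased["delta_stability"], unchanged["delta_stability"],
                        "increased_lr", "unchanged_lr")
        if row:
            rows.append(row)
    return pd.DataFrame(rows)
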