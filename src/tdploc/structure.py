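"""Windowed base-pair probability profiling of reporter RNA sequences.

Occupied TDP-43 motifs sit in locally single-stranded RNA; the assays in
this package therefore need, for every 260-nt variable region, the
probability that each nucleotide is base-paired. The profile is computed
the way the MPRA folding analysis defines it: 80-nt windows sliding by
10 nt, and per position the summed probability of pairing with any
partner, averaged over the windows that cover the position.

The default backend is a McCaskill-style partition function over nested
secondary structures with a deliberately small energy model -- additive
per-pair energies (GC -3 kT, AU -2 kT, GU -1 kT), a minimum hairpin loop
of 3 nt, no stacking or dangle terms, plus one entropic closing penalty
per loop: every pair whose immediately enclosed positions are not
themselves paired (a hairpin, internal-loop or multiloop closure) pays a
fixed cost. The pair energies alone cannot distinguish a designed stem
from an accessible motif -- without any loop cost an isolated pair is
pure gain, so in an 80-nt window nearly every base with one available
partner is predicted paired. The loop-closing penalty (default 8 kT, the
magnitude of the Turner-rule loop-initiation terms) restores the
cooperativity that makes helices, and only helices, stable. The model
stays small enough that an exhaustive structure-enumeration oracle is
exact for short sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit

DEFAULT_PAIR_ENERGIES = {"GC": -3.0, "AU": -2.0, "GU": -1.0}
DEFAULT_LOOP_PENALTY = 8.0  # kT per loop closure (hairpin/internal/multi)
MIN_HAIRPIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    if not set(seq) <= set("ACGTUN"):
        raise ValueError("sequence must be over A/C/G/T/U/N")
    # N encodes as A but is flagged unpairable via a 5th row/col of zeros
    return np.array([4 if c == "N" else _CODE[c] for c in seq], dtype=np.int8)


@njit(cache=False)
def _pair_probs_kernel(codes, weight, loop_w, min_loop):  # pragma: no cover - numba
    n = codes.shape[0]
    Z = np.ones((n, n))
    Zb = np.zeros((n, n))
    for length in range(2, n + 1):
        for i in range(0, n - length + 1):
            j = i + length - 1
            w = weight[codes[i], codes[j]]
            if j - i >= min_loop + 1 and w > 0.0:
                # stacked continuation keeps the open loop; any other
                # enclosed content (incl. empty = hairpin) closes a loop
                inner = Z[i + 1, j - 1]
                stack = Zb[i + 1, j - 1]
                Zb[i, j] = w * (stack + loop_w * (inner - stack))
            acc = Z[i, j - 1]
            for k in range(i, j - min_loop):
                if Zb[k, j] > 0.0:
                    left = Z[i, k - 1] if k - 1 >= i else 1.0
                    acc += left * Zb[k, j]
            Z[i, j] = acc
    bS = np.zeros((n, n))
    bP = np.zeros((n, n))
    bS[0, n - 1] = 1.0
    P = np.zeros((n, n))
    for length in range(n, 1, -1):
        for i in range(0, n - length + 1):
            j = i + length - 1
            b = bS[i, j]
            if b > 0.0:
                bS[i, j - 1] += b
                for k in range(i, j - min_loop):
                    if Zb[k, j] > 0.0:
                        left = Z[i, k - 1] if k - 1 >= i else 1.0
                        bP[k, j] += b * left
                        if k - 1 >= i:
                            bS[i, k - 1] += b * Zb[k, j]
            pb = bP[i, j]
            if pb > 0.0 and j - 1 >= i + 1:
                w = weight[codes[i], codes[j]]
                bS[i + 1, j - 1] += pb * w * loop_w
                bP[i + 1, j - 1] += pb * w * (1.0 - loop_w)
    total = Z[0, n - 1]
    for i in range(n):
        for j in range(i + 1, n):
            if Zb[i, j] > 0.0:
                p = Zb[i, j] * bP[i, j] / total
                P[i, j] = p
                P[j, i] = p
    return P


@dataclass
class BasePairBackend:
    """Boltzmann base-pair probabilities over nested structures.

    Satisfies the FoldBackend contract: `pair_probabilities` returns a
    symmetric matrix with non-negative entries and row sums <= 1.
    """

    name: str = "basepair"
    pair_energies: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_ENERGIES)
    )
    loop_penalty: float = DEFAULT_LOOP_PENALTY
    min_hairpin_loop: int = MIN_HAIRPIN_LOOP

    def __post_init__(self):
        w = np.zeros((5, 5))
        pairs = {"GC": ("G", "C"), "AU": ("A", "T"), "GU": ("G", "T")}
        for key, (a, b) in pairs.items():
            val = math.exp(-self.pair_energies[key])
            w[_CODE[a], _CODE[b]] = val
            w[_CODE[b], _CODE[a]] = val
        self._weight = w

    def pair_probabilities(self, seq: str) -> np.ndarray:
        codes = encode(seq)
        n = len(codes)
        if n < 2:
            return np.zeros((n, n))
        return _pair_probs_kernel(
            codes, self._weight, math.exp(-self.loop_penalty), self.min_hairpin_loop
        )


def get_backend(name: str = "basepair", **kw) -> BasePairBackend:
    if name != "basepair":
        raise ValueError(f"unknown fold backend {name!r}")
    return BasePairBackend(**kw)


def fold_window(seq: str, backend: BasePairBackend | None = None) -> np.ndarray:
    """Pair-probability matrix of one (<=80 nt) window."""
    backend = backend or BasePairBackend()
    return backend.pair_probabilities(seq)


def positional_profile(
    seq: str,
    window: int = 80,
    slide: int = 10,
    backend: BasePairBackend | None = None,
) -> np.ndarray:
    """Per-position paired probability of `seq` from sliding windows.

    Each window contributes P_paired(i) = sum_j P(i, j); positions covered
    by several windows get the arithmetic mean of the window values. If the
    last regular window does not reach the 3' end, one extra window flush
    with the end is added so every position is covered.
    """
    if slide <= 0:
        raise ValueError("slide must be positive")
    n = len(seq)
    if window > n:
        raise ValueError("window longer than sequence")
    backend = backend or BasePairBackend()
    starts = list(range(0, n - window + 1, slide))
    if starts[-1] != n - window:
        starts.append(n - window)
    total = np.zeros(n)
    cover = np.zeros(n)
    for s in starts:
        mat = backend.pair_probabilities(seq[s : s + window])
        total[s : s + window] += mat.sum(axis=1)
        cover[s : s + window] += 1
    return total / cover


def motif_pair_prob(
    profile: np.ndarray, intervals: Sequence[Tuple[int, int]]
) -> Tuple[float, List[np.ndarray]]:
    """Mean pairing probability over motif positions + per-motif 5-nt vectors."""
    vectors = []
    for start, end in intervals:
        if start < 0 or end > len(profile):
            raise ValueError(f"motif interval [{start},{end}) outside profile")
        vectors.append(profile[start:end].copy())
    if not vectors:
        return float("nan"), []
    return float(np.mean(np.concatenate(vectors))), vectors


def score_pool(
    oligos: Sequence, backend: BasePairBackend | None = None,
    window: int = 80, slide: int = 10,
) -> pd.DataFrame:
    """Motif pairing scores for every motif-bearing oligo of a pool.

    Returns one row per oligo with >=1 motif: the mean motif pair
    probability and the per-motif detail; motif-free oligos are skipped.
    """
    backend = backend or BasePairBackend()
    rows = []
    for rec in oligos:
        if not rec.motif_hits:
            continue
        prof = positional_profile(rec.variable_seq, window, slide, backend)
        mean, vectors = motif_pair_prob(prof, [(s, e) for _m, s, e in rec.motif_hits])
        rows.append(
            {
                "oligo_id": rec.oligo_id,
                "gene_id": rec.gene_id,
                "is_mutant": rec.is_mutant,
                "n_motifs": len(rec.motif_hits),
                "motif_pair_prob": mean,
                "per_nt": ";".join(
                    ",".join(f"{v:.4f}" for v in vec) for vec in vectors
                ),
            }
        )
    return pd.DataFrame(rows)


def structure_quantile_split(
    scores: pd.DataFrame, q: float = 0.20,
    score_col: str = "motif_pair_prob", id_col: str = "oligo_id",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Top/bottom q fractions of oligos ranked by motif pairing probability.

    Rank is stable on (score, id) so ties split deterministically by id;
    each returned set has ceil(q*N) rows.
    """
    if len(scores) < 5:
        raise ValueError("need at least 5 scored oligos to split")
    if not 0 < q <= 0.5:
        raise ValueError("q must be in (0, 0.5]")
    ranked = scores.sort_values([score_col, id_col], kind="mergesort")
    k = math.ceil(q * len(ranked))
    return ranked.tail(k), ranked.head(k)
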