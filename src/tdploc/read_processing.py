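"""Paired-end amplicon reads -> per-oligo unique-UMI counts.

The reporter pools are a closed dictionary of known 260-mers, so general
alignment is replaced by seeded near-exact matching: after 5' adapter
removal (Hamming, <=2 mismatches) and UMI extraction (first 8 nt of the
reverse read), the forward remainder must match the 5' end of an oligo
variable region and the reverse remainder the reverse complement of its
3' end, each within a per-mate mismatch budget. Candidate oligos are
found through exact lookup of read segments (pigeonhole: with <=k
mismatches one of k+1 segments is exact), the unique best total-distance
oligo wins, and ties or mate-discordant pairs are left unassigned. N
counts as a mismatch during assignment and as a literal symbol in UMIs;
deduplication is exact-string UMI counting per (oligo, sample).

Every pair is accounted for: total = adapter-rejected + too-short +
unassigned + assigned, and the per-sample log reports each tally.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .config import FWD_ADAPTER, REV_ADAPTER
from .io import read_fastq_pairs, revcomp

DEFAULT_MAX_MISMATCH = 2
DEFAULT_UMI_LEN = 8


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings, early-exit past `limit`."""
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d


def trim_adapter(read: str, adapter: str, max_mismatch: int = DEFAULT_MAX_MISMATCH) -> Optional[str]:
    """Strip a 5' adapter within `max_mismatch`; None when it does not match."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if len(read) < len(adapter):
        return None
    if read.startswith(adapter):  # fast path
        return read[len(adapter):]
    if hamming(read[: len(adapter)], adapter, max_mismatch) <= max_mismatch:
        return read[len(adapter):]
    return None


def trim_adapters(
    fwd: str, rev: str,
    fwd_adapter: str = FWD_ADAPTER, rev_adapter: str = REV_ADAPTER,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> Optional[Tuple[str, str]]:
    """Trim both mates; the pair is rejected (None) if either mate fails."""
    f = trim_adapter(fwd, fwd_adapter, max_mismatch)
    if f is None:
        return None
    r = trim_adapter(rev, rev_adapter, max_mismatch)
    if r is None:
        return None
    return f, r


def extract_umi(rev_remainder: str, umi_len: int = DEFAULT_UMI_LEN) -> Optional[Tuple[str, str]]:
    """(UMI, remainder) from a trimmed reverse read; None when too short."""
    if umi_len < 0:
        raise ValueError("umi_len must be >= 0")
    if len(rev_remainder) <= umi_len:
        return None
    return rev_remainder[:umi_len], rev_remainder[umi_len:]


def _segments(s: str, k: int) -> List[Tuple[int, str]]:
    size = len(s) // k
    out = []
    for i in range(k):
        start = i * size
        end = len(s) if i == k - 1 else (i + 1) * size
        out.append((i, s[start:end]))
    return out


_COLLAPSE_FWD = str.maketrans("T", "C")  # molecule T>C conversions
_COLLAPSE_REV = str.maketrans("A", "G")  # the same, on the revcomp strand


def _hamming_free(read: str, ref: str, free_ref: str, free_read: str,
                  limit: int) -> int:
    """Hamming distance where (ref==free_ref, read==free_read) is no cost."""
    d = 0
    for x, y in zip(ref, read):
        if x != y and not (x == free_ref and y == free_read):
            d += 1
            if d > limit:
                return d
    return d


class PoolIndex:
    """Seeded near-exact matcher over the variable regions of a pool.

    With conversion_aware=True (SLAM samples), T>C conversions are
    expected biology: they are invisible to the exact/seed lookups
    (T and C collapse on the forward strand, A and G on the reverse) and
    cost nothing in the verification distance, so heavily labeled reads
    are not selected against.
    """

    def __init__(self, variable_seqs: Dict[str, str], read_len: int,
                 max_mismatch: int = DEFAULT_MAX_MISMATCH,
                 conversion_aware: bool = False):
        if not variable_seqs:
            raise ValueError("empty pool index")
        self.read_len = read_len
        self.max_mismatch = max_mismatch
        self.conversion_aware = conversion_aware
        self._prefix: Dict[str, str] = {}
        self._rc_suffix: Dict[str, str] = {}
        self._exact_f: Dict[str, List[str]] = defaultdict(list)
        self._exact_r: Dict[str, List[str]] = defaultdict(list)
        self._seed_f: Dict[Tuple[int, str], set] = defaultdict(set)
        self._seed_r: Dict[Tuple[int, str], set] = defaultdict(set)
        nseg = max_mismatch + 1
        for oid, var in variable_seqs.items():
            if len(var) < read_len:
                raise ValueError(f"{oid}: variable region shorter than read length")
            pre = var[:read_len]
            suf = revcomp(var[-read_len:])
            self._prefix[oid] = pre
            self._rc_suffix[oid] = suf
            kf, kr = self._keys(pre, suf)
            self._exact_f[kf].append(oid)
            self._exact_r[kr].append(oid)
            for key, seg in _segments(kf, nseg):
                self._seed_f[(key, seg)].add(oid)
            for key, seg in _segments(kr, nseg):
                self._seed_r[(key, seg)].add(oid)

    def _keys(self, f: str, r: str) -> Tuple[str, str]:
        if self.conversion_aware:
            return f.translate(_COLLAPSE_FWD), r.translate(_COLLAPSE_REV)
        return f, r

    def _dist_f(self, read: str, ref: str) -> int:
        if self.conversion_aware:
            return _hamming_free(read, ref, "T", "C", self.max_mismatch)
        return hamming(read, ref, self.max_mismatch)

    def _dist_r(self, read: str, ref: str) -> int:
        if self.conversion_aware:
            return _hamming_free(read, ref, "A", "G", self.max_mismatch)
        return hamming(read, ref, self.max_mismatch)

    def assign(self, fwd_rem: str, rev_rem: str) -> Optional[str]:
        """Best concordant oligo for a trimmed, UMI-stripped pair; None on
        rejection (too short), no hit, or tie."""
        rl = self.read_len
        if len(fwd_rem) < rl or len(rev_rem) < rl:
            return None
        f, r = fwd_rem[:rl], rev_rem[:rl]
        kf, kr = self._keys(f, r)
        # fast path: both mates exact and concordant
        hits_f = self._exact_f.get(kf)
        hits_r = self._exact_r.get(kr)
        if hits_f and hits_r:
            common = set(hits_f) & set(hits_r)
            if len(common) == 1:
                return next(iter(common))
        nseg = self.max_mismatch + 1
        candidates: set = set()
        for key, seg in _segments(kf, nseg):
            candidates |= self._seed_f.get((key, seg), set())
        for key, seg in _segments(kr, nseg):
            candidates |= self._seed_r.get((key, seg), set())
        best_id, best_d, tied = None, None, False
        for oid in candidates:
            df = self._dist_f(f, self._prefix[oid])
            if df > self.max_mismatch:
                continue
            dr = self._dist_r(r, self._rc_suffix[oid])
            if dr > self.max_mismatch:
                continue
            d = df + dr
            if best_d is None or d < best_d:
                best_id, best_d, tied = oid, d, False
            elif d == best_d:
                tied = True
        return None if tied else best_id


@dataclass
class ProcessResult:
    sample: str
    umis: Dict[str, set] = field(default_factory=lambda: defaultdict(set))
    reads: Dict[str, int] = field(default_factory=lambda: defaultdict(int))
    total: int = 0
    rejected_adapter: int = 0
    rejected_short: int = 0
    unassigned: int = 0
    assigned: int = 0

    @property
    def stats(self) -> Dict[str, int]:
        return {
            "sample": self.sample,
            "total": self.total,
            "rejected_adapter": self.rejected_adapter,
            "rejected_short": self.rejected_short,
            "unassigned": self.unassigned,
            "assigned": self.assigned,
        }


def process_sample(
    fq1: str,
    fq2: str,
    index: PoolIndex,
    sample: str,
    fwd_adapter: str = FWD_ADAPTER,
    rev_adapter: str = REV_ADAPTER,
    umi_len: int = DEFAULT_UMI_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    on_assigned: Callable[..., None] | None = None,
) -> ProcessResult:
    """Stream one FASTQ pair into per-oligo UMI sets.

    `on_assigned(oligo_id, fwd_seq, suffix_seq, fwd_qual, suffix_qual)`
    receives each assigned pair in molecule orientation (reverse mate
    already reverse-complemented back), which is what conversion counting
    needs.
    """
    res = ProcessResult(sample)
    rl = index.read_len
    for _name, fwd, q1, rev, q2 in read_fastq_pairs(fq1, fq2):
        res.total += 1
        trimmed = trim_adapters(fwd, rev, fwd_adapter, rev_adapter, max_mismatch)
        if trimmed is None:
            res.rejected_adapter += 1
            continue
        fwd_rem, rev_trimmed = trimmed
        ur = extract_umi(rev_trimmed, umi_len)
        if ur is None:
            res.rejected_short += 1
            continue
        umi, rev_rem = ur
        oid = index.assign(fwd_rem, rev_rem)
        if oid is None:
            res.unassigned += 1
            continue
        res.assigned += 1
        res.umis[oid].add(umi)
        res.reads[oid] += 1
        if on_assigned is not None:
            na = len(fwd) - len(fwd_rem)
            fq = q1[na : na + rl] if q1 else None
            nb = len(rev) - len(rev_rem)
            rq = q2[nb : nb + rl][::-1] if q2 else None
            on_assigned(oid, fwd_rem[:rl], revcomp(rev_rem[:rl]), fq, rq)
    return res


def count_umis(results: Sequence[ProcessResult], oligo_ids: Sequence[str]) -> pd.DataFrame:
    """Unique-UMI CountTable (oligos x samples); zero rows kept explicitly."""
    table = pd.DataFrame(
        {res.sample: [len(res.umis.get(oid, ())) for oid in oligo_ids]
         for res in results},
        index=pd.Index(oligo_ids, name="oligo_id"),
    )
    return table


def quantify(
    samplesheet: pd.DataFrame,
    variable_seqs: Dict[str, str],
    read_len: int,
    umi_len: int = DEFAULT_UMI_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    on_assigned_factory: Callable[[str], Callable | None] | None = None,
    conversion_aware: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run every sample of a sheet (columns sample/fastq1/fastq2) through the
    matcher; returns (CountTable, per-sample processing log)."""
    index = PoolIndex(variable_seqs, read_len, max_mismatch, conversion_aware)
    results = []
    for row in samplesheet.itertuples(index=False):
        cb = on_assigned_factory(row.sample) if on_assigned_factory else None
        results.append(
            process_sample(row.fastq1, row.fastq2, index, row.sample,
                           umi_len=umi_len, max_mismatch=max_mismatch,
                           on_assigned=cb)
        )
    counts = count_umis(results, list(variable_seqs))
    log = pd.DataFrame([r.stats for r in results])
    return counts, log
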