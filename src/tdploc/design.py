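"""Tiling oligo-pool design for 3' UTR reporter assays.

The designer turns a set of annotated 3' UTRs into a synthesis-ready pool:
transcript-level filtering, per-gene meta-UTR merging, dense tiling
(260-nt tiles every 6 nt, with 260-nt flank extension so UTR ends are
covered by full-depth tiles), TDP-43 motif annotation (GUGUG / UGUGU /
GUAUG on the DNA strand), motif-mutant companion oligos, and 20-nt PCR
handles. Coordinates are 0-based half-open throughout; tile starts inside
the upstream flank are negative offsets relative to the meta-UTR start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .io import read_fasta, write_fasta

#: Canonical TDP-43 binding 5-mers, written in the DNA alphabet (U -> T).
MOTIFS: Tuple[str, ...] = ("GTGTG", "TGTGT", "GTATG")
TILE_LEN = 260
TILE_STEP = 6
FLANK_LEN = 260
HANDLE_LEN = 20
#: Handle sequences are configurable; these defaults are arbitrary constants.
DEFAULT_FWD_HANDLE = "ACTGGCCGCTTCACTGGTGA"
DEFAULT_REV_HANDLE = "AGATCGGAAGAGCGTCGTGT"
DISALLOWED_TAGS = frozenset({"cds_end_NF", "mRNA_end_NF"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class UtrRecord:
    """One transcript's 3' UTR with the annotation the design filters need."""

    gene_id: str
    transcript_id: str
    sequence: str
    tags: frozenset = frozenset()
    polya_conserved: bool = True
    #: interval of this UTR in gene coordinates (0-based half-open)
    interval: Tuple[int, int] = (0, 0)
    upstream_flank: str = ""
    downstream_flank: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        if not set(self.sequence) <= set("ACGTN"):
            raise ValueError(f"{self.transcript_id}: non-DNA characters in sequence")
        if self.interval == (0, 0):
            self.interval = (0, len(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MetaUtr:
    """Union of the filter-passing isoform UTRs of one gene."""

    gene_id: str
    intervals: List[Tuple[int, int]]
    sequence: str
    transcript_ids: List[str]
    upstream_flank: str = ""
    downstream_flank: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class OligoRecord:
    oligo_id: str
    gene_id: str
    start: int  # tile start relative to meta-UTR start; negative in upstream flank
    variable_seq: str
    fwd_handle: str = DEFAULT_FWD_HANDLE
    rev_handle: str = DEFAULT_REV_HANDLE
    motif_hits: List[Tuple[str, int, int]] = field(default_factory=list)
    is_mutant: bool = False
    companion_id: str | None = None

    @property
    def full_seq(self) -> str:
        return self.fwd_handle + self.variable_seq + self.rev_handle


def filter_utrs(
    records: Iterable[UtrRecord], max_len: int = 10_000
) -> Tuple[List[UtrRecord], List[Tuple[str, str]]]:
    """Keep UTRs with clean 3'-end tags, length <= max_len and a conserved polyA site.

    Returns (retained, rejection log); the log records the first failed rule
    per transcript as one of "tag" / "length" / "polya".
    """
    kept, rejected = [], []
    for rec in records:
        if rec.tags & DISALLOWED_TAGS:
            rejected.append((rec.transcript_id, "tag"))
        elif rec.length > max_len:
            rejected.append((rec.transcript_id, "length"))
        elif not rec.polya_conserved:
            rejected.append((rec.transcript_id, "polya"))
        else:
            kept.append(rec)
    return kept, rejected


def _union_intervals(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[List[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


def merge_meta_utr(records: Sequence[UtrRecord]) -> MetaUtr:
    """Merge one gene's isoform UTR intervals into a meta-UTR.

    Disjoint segments are concatenated in coordinate order; the merged
    sequence is read out of the contributing transcripts (first covering
    transcript wins where isoforms overlap).
    """
    if not records:
        raise ValueError("merge_meta_utr needs at least one record")
    gene = records[0].gene_id
    if any(r.gene_id != gene for r in records):
        raise ValueError("merge_meta_utr got records from multiple genes")
    base: Dict[int, str] = {}
    for rec in records:
        start, end = rec.interval
        if end - start != rec.length:
            raise ValueError(f"{rec.transcript_id}: interval does not match sequence length")
        for offset, ch in enumerate(rec.sequence):
            base.setdefault(start + offset, ch)
    intervals = _union_intervals([r.interval for r in records])
    seq = "".join(base[pos] for s, e in intervals for pos in range(s, e))
    first = min(records, key=lambda r: r.interval[0])
    last = max(records, key=lambda r: r.interval[1])
    return MetaUtr(
        gene_id=gene,
        intervals=intervals,
        sequence=seq,
        transcript_ids=[r.transcript_id for r in records],
        upstream_flank=first.upstream_flank,
        downstream_flank=last.downstream_flank,
    )


def tile_starts(meta_length: int, tile_len: int = TILE_LEN, step: int = TILE_STEP,
                flank: int = FLANK_LEN) -> List[int]:
    """Tile start offsets: -flank, -flank+step, ... while the tile fits in the
    flank-extended sequence. Count = floor((L + 2*flank - tile_len)/step) + 1."""
    if step <= 0:
        raise ValueError("step must be positive")
    extended = meta_length + 2 * flank
    if extended < tile_len:
        raise ValueError(
            f"extended sequence ({extended} nt) shorter than tile length {tile_len}"
        )
    starts = []
    s = -flank
    while s + tile_len <= meta_length + flank:
        starts.append(s)
        s += step
    return starts


def find_motifs(seq: str) -> List[Tuple[str, int, int]]:
    """All (possibly overlapping) canonical-motif occurrences, left to right."""
    seq = seq.upper().replace("U", "T")
    hits = []
    for i in range(len(seq) - 4):
        window = seq[i : i + 5]
        if window in MOTIFS:
            hits.append((window, i, i + 5))
    return hits


def mutate_motifs(seq: str, hits: Sequence[Tuple[str, int, int]]) -> str:
    """Base-complement every position covered by >=1 motif hit.

    The per-motif substitutions (GUGUG->CACAC, UGUGU->ACACA, GUAUG->CAUAC)
    are all base-wise complements, so complementing the union span is the
    unique extension consistent with overlapping occurrences.
    """
    if not hits:
        return seq
    covered = set()
    for _motif, start, end in hits:
        if start < 0 or end > len(seq):
            raise ValueError(f"motif interval [{start},{end}) out of bounds")
        covered.update(range(start, end))
    out = list(seq)
    for pos in covered:
        out[pos] = out[pos].translate(_COMPLEMENT)
    return "".join(out)


def tile_meta_utr(meta: MetaUtr, tile_len: int = TILE_LEN, step: int = TILE_STEP,
                  flank: int = FLANK_LEN) -> List[Tuple[int, str]]:
    """(start, variable sequence) for every tile of a flank-extended meta-UTR."""
    if flank > 0 and (len(meta.upstream_flank) < flank or len(meta.downstream_flank) < flank):
        raise ValueError(f"{meta.gene_id}: flank sequences shorter than {flank} nt")
    up = meta.upstream_flank[len(meta.upstream_flank) - flank :] if flank else ""
    down = meta.downstream_flank[:flank]
    extended = up + meta.sequence + down
    out = []
    for start in tile_starts(meta.length, tile_len, step, flank):
        var = extended[start + flank : start + flank + tile_len]
        assert len(var) == tile_len
        out.append((start, var))
    return out


def assemble_pool(
    metas: Sequence[MetaUtr],
    fwd_handle: str = DEFAULT_FWD_HANDLE,
    rev_handle: str = DEFAULT_REV_HANDLE,
    tile_len: int = TILE_LEN,
    step: int = TILE_STEP,
    flank: int = FLANK_LEN,
) -> List[OligoRecord]:
    """Tile every meta-UTR and emit one mutant companion per motif-bearing tile."""
    if len(fwd_handle) != HANDLE_LEN or len(rev_handle) != HANDLE_LEN:
        raise ValueError(f"handles must be exactly {HANDLE_LEN} nt")
    records: List[OligoRecord] = []
    seen = set()
    for meta in metas:
        for start, var in tile_meta_utr(meta, tile_len, step, flank):
            oid = f"{meta.gene_id}:{start}"
            if oid in seen:
                raise ValueError(f"duplicate oligo id {oid}")
            seen.add(oid)
            hits = find_motifs(var)
            rec = OligoRecord(oid, meta.gene_id, start, var, fwd_handle, rev_handle,
                              motif_hits=hits)
            records.append(rec)
            if hits:
                mid = oid + ":mut"
                rec.companion_id = mid
                records.append(
                    OligoRecord(mid, meta.gene_id, start, mutate_motifs(var, hits),
                                fwd_handle, rev_handle, motif_hits=[],
                                is_mutant=True, companion_id=oid)
                )
    return records


def _hits_to_str(hits: Sequence[Tuple[str, int, int]]) -> str:
    return ";".join(f"{m}@{s}-{e}" for m, s, e in hits)


def hits_from_str(text: str) -> List[Tuple[str, int, int]]:
    if not isinstance(text, str) or not text:
        return []
    out = []
    for item in text.split(";"):
        motif, span = item.split("@")
        s, e = span.split("-")
        out.append((motif, int(s), int(e)))
    return out


def load_utrs(fasta_path: str, metadata_path: str) -> List[UtrRecord]:
    """UtrRecords from a UTR FASTA + metadata table (the design input
    interface: gene_id, transcript_id, tags, polya_conserved, intervals,
    flanks)."""
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(metadata_path, sep="\t", keep_default_na=False)
    records = []
    for row in meta.itertuples(index=False):
        records.append(
            UtrRecord(
                gene_id=row.gene_id,
                transcript_id=row.transcript_id,
                sequence=seqs[row.gene_id] if row.gene_id in seqs else seqs[row.transcript_id],
                tags=frozenset(t for t in str(row.tags).split(",") if t),
                polya_conserved=bool(row.polya_conserved),
                interval=(int(row.interval_start), int(row.interval_end)),
                upstream_flank=row.upstream_flank,
                downstream_flank=row.downstream_flank,
            )
        )
    return records


def pool_manifest(records: Sequence[OligoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "oligo_id": [r.oligo_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "start": [r.start for r in records],
            "is_mutant": [r.is_mutant for r in records],
            "companion_id": [r.companion_id or "" for r in records],
            "n_motifs": [len(r.motif_hits) for r in records],
            "motif_hits": [_hits_to_str(r.motif_hits) for r in records],
            "fwd_handle": [r.fwd_handle for r in records],
            "rev_handle": [r.rev_handle for r in records],
        }
    )


def write_pool(records: Sequence[OligoRecord], fasta_path: str, manifest_path: str) -> None:
    write_fasta(fasta_path, ((r.oligo_id, r.full_seq) for r in records))
    pool_manifest(records).to_csv(manifest_path, sep="\t", index=False)


def load_pool(fasta_path: str, manifest_path: str) -> List[OligoRecord]:
    """Reload OligoRecords from a pool FASTA + manifest (round-trip identical)."""
    seqs = read_fasta(fasta_path)
    manifest = pd.read_csv(manifest_path, sep="\t", keep_default_na=False)
    records = []
    for row in manifest.itertuples(index=False):
        full = seqs[row.oligo_id]
        nf, nr = len(row.fwd_handle), len(row.rev_handle)
        records.append(
            OligoRecord(
                oligo_id=row.oligo_id,
                gene_id=row.gene_id,
                start=int(row.start),
                variable_seq=full[nf : len(full) - nr],
                fwd_handle=row.fwd_handle,
                rev_handle=row.rev_handle,
                motif_hits=hits_from_str(row.motif_hits),
                is_mutant=bool(row.is_mutant),
                companion_id=row.companion_id or None,
            )
        )
    return records
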