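"""Iterative non-redundant pan-sequence construction ("augmentation").

Starting from a base reference, each assembly in turn is aligned to the
current pan-reference; aligned segments passing the identity/length
thresholds (defaults: identity >= 0.90 over >= 100 bp) are trimmed out of
its contigs, and the retained complement — the accession's novel sequence —
is appended to the pan-reference with full provenance before the next
accession is processed.

Alignment is a built-in exact k-mer anchor-chain aligner: anchors shared
between contig and pan are chained per (target, strand, diagonal), chains
are scored gap-free over the induced banded correspondence and extended
outward with an X-drop rule that reports the best-scoring endpoint.  A
dynamic-programming oracle validates the reported identities in the test
suite; the thresholds, not the aligner brand, are the contract here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord

logger = logging.getLogger("panpav")

__all__ = [
    "AlignmentSegment",
    "PanSegment",
    "PanReference",
    "TrimResult",
    "anchor_align",
    "trim_and_retain",
    "augment_iterative",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_RC = np.full(256, 255, dtype=np.uint8)
for _x, _y in zip(b"ACGT", b"TGCA"):
    _RC[_x] = _CODE[_y]


def _encode(seq: str) -> np.ndarray:
    """Sequence -> base codes (A,C,G,T -> 0..3, anything else -> 255)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    rc = codes[::-1].copy()
    valid = rc < 4
    rc[valid] = 3 - rc[valid]
    return rc


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and a validity mask (windows without N)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    kc = np.zeros(n, dtype=np.uint64)
    safe = np.where(codes < 4, codes, 0).astype(np.uint64)
    for j in range(k):
        kc = (kc << np.uint64(2)) | safe[j:j + n]
    bad = np.concatenate([[0], np.cumsum(codes >= 4)])
    valid = (bad[k:] - bad[:-k]) == 0
    return kc, valid


@dataclass
class AlignmentSegment:
    """One gap-free aligned segment between a contig and a pan target."""

    contig_id: str
    contig_start: int
    contig_end: int
    target_id: str
    target_start: int
    target_end: int
    strand: str          # '+' or '-'
    identity: float      # exact matches / alignment columns, in [0, 1]
    matches: int

    def __post_init__(self) -> None:
        if self.contig_end - self.contig_start < 1:
            raise ValueError("empty alignment segment")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class PanSegment:
    """A pan-reference segment: base chromosome or appended novel sequence."""

    seg_id: str
    codes: np.ndarray = field(repr=False)
    accession: str | None = None   # provenance: None for base segments
    contig: str | None = None
    start: int | None = None       # interval in the source contig
    end: int | None = None
    iteration: int = 0

    def __len__(self) -> int:
        return self.codes.size


class PanReference:
    """Base reference plus appended novel segments, with a k-mer index."""

    def __init__(self, reference: list[SequenceRecord]):
        self.segments: list[PanSegment] = []
        self._ids: set[str] = set()
        for rec in reference:
            self._append(PanSegment(rec.id, _encode(rec.seq)))
        self._index: tuple | None = None
        self._index_k: int | None = None

    def _append(self, seg: PanSegment) -> None:
        if seg.seg_id in self._ids:
            raise ValueError(f"duplicate pan segment id {seg.seg_id!r}")
        if len(seg) < 1:
            raise ValueError(f"empty pan segment {seg.seg_id!r}")
        self._ids.add(seg.seg_id)
        self.segments.append(seg)
        self._index = None

    def add_novel(self, seq: str, accession: str, contig: str,
                  start: int, end: int, iteration: int) -> PanSegment:
        seg = PanSegment(f"novel|{accession}|{contig}|{start}-{end}",
                         _encode(seq), accession, contig, start, end, iteration)
        self._append(seg)
        return seg

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.segments)

    def index(self, k: int):
        """(sorted k-mer codes, their global positions, segment starts)."""
        if self._index is not None and self._index_k == k:
            return self._index
        sep = np.full(k, 255, dtype=np.uint8)
        parts: list[np.ndarray] = []
        seg_starts = np.empty(len(self.segments), dtype=np.int64)
        off = 0
        for i, seg in enumerate(self.segments):
            seg_starts[i] = off
            parts.append(seg.codes)
            off += seg.codes.size
            if i < len(self.segments) - 1:
                parts.append(sep)
                off += k
        concat = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        kc, valid = _kmer_codes(concat, k)
        pos = np.flatnonzero(valid).astype(np.int64)
        codes = kc[pos]
        order = np.argsort(codes, kind="stable")
        self._index = (codes[order], pos[order], seg_starts)
        self._index_k = k
        return self._index

    def to_records(self) -> list[SequenceRecord]:
        inv = np.frombuffer(b"ACGT", dtype=np.uint8)
        out = []
        for seg in self.segments:
            b = np.where(seg.codes < 4, inv[np.minimum(seg.codes, 3)],
                         np.uint8(ord("N")))
            out.append(SequenceRecord(seg.seg_id, b.tobytes().decode()))
        return out

    def provenance_frame(self) -> pd.DataFrame:
        rows = [
            {"segment_id": s.seg_id, "accession": s.accession or "",
             "contig": s.contig or "", "start": -1 if s.start is None else s.start,
             "end": -1 if s.end is None else s.end, "iteration": s.iteration}
            for s in self.segments
        ]
        return pd.DataFrame(rows)


def _extend(qc: np.ndarray, tc: np.ndarray, qpos: int, tpos: int,
            direction: int, penalty: int, xdrop: int) -> tuple[int, int]:
    """Best-endpoint X-drop extension; returns (steps, matches gained).

    Steps outward base by base (direction -1 = left of qpos/tpos, +1 = right
    starting at qpos/tpos), scoring +1 per match and -penalty per mismatch,
    and reports the prefix with the maximum score, abandoning once the score
    falls ``xdrop`` below the best.
    """
    best, best_i, best_m = 0, 0, 0
    score, m = 0, 0
    i = 0
    nq, nt = qc.size, tc.size
    while True:
        i += 1
        if direction < 0:
            q, t = qpos - i, tpos - i
        else:
            q, t = qpos + i - 1, tpos + i - 1
        if q < 0 or t < 0 or q >= nq or t >= nt:
            break
        a, b = qc[q], tc[t]
        if a == b and a < 4:
            score += 1
            m += 1
            if score > best:
                best, best_i, best_m = score, i, m
        else:
            score -= penalty
            if score < best - xdrop:
                break
    return best_i, best_m


def anchor_align(
    contig: SequenceRecord,
    pan: PanReference,
    k: int = 21,
    max_gap: int = 300,
    max_occ: int = 16,
    penalty: int = 3,
    xdrop: int = 30,
) -> list[AlignmentSegment]:
    """Align a contig to the pan-reference via exact k-mer anchor chains.

    Anchors are chained per (target segment, strand, diagonal); each chain
    yields one gap-free segment whose identity is exact matches over
    alignment columns (N never matches).  Reverse-strand hits are found via
    the reverse complement.  Segments are returned sorted by contig start;
    no anchors means an empty list.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if len(contig) < k:
        raise ValueError("contig shorter than k")
    sorted_codes, sorted_pos, seg_starts = pan.index(k)
    fwd = _encode(contig.seq)
    L = fwd.size
    results: list[AlignmentSegment] = []

    for strand, qarr in (("+", fwd), ("-", _revcomp_codes(fwd))):
        kc, valid = _kmer_codes(qarr, k)
        qpositions = np.flatnonzero(valid)
        if qpositions.size == 0:
            continue
        qk = kc[qpositions]
        left = np.searchsorted(sorted_codes, qk, side="left")
        right = np.searchsorted(sorted_codes, qk, side="right")
        cnt = np.minimum(right - left, max_occ)
        tot = int(cnt.sum())
        if tot == 0:
            continue
        rep_left = np.repeat(left, cnt)
        within = np.arange(tot) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        tglobal = sorted_pos[rep_left + within]
        qpos = np.repeat(qpositions, cnt)
        seg_idx = np.searchsorted(seg_starts, tglobal, side="right") - 1
        tlocal = tglobal - seg_starts[seg_idx]
        diag = tlocal - qpos

        order = np.lexsort((qpos, diag, seg_idx))
        seg_o, diag_o, q_o, t_o = seg_idx[order], diag[order], qpos[order], tlocal[order]
        brk = np.flatnonzero(
            (np.diff(seg_o) != 0) | (np.diff(diag_o) != 0)
            | (np.diff(q_o) > max_gap))
        bounds = np.concatenate([[0], brk + 1, [len(order)]])

        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            si = int(seg_o[b0])
            tc = pan.segments[si].codes
            qs, qe = int(q_o[b0]), int(q_o[b1 - 1]) + k
            ts, te = int(t_o[b0]), int(t_o[b1 - 1]) + k
            qv = qarr[qs:qe]
            tv = tc[ts:te]
            m = int(np.count_nonzero((qv == tv) & (qv < 4)))
            dl, ml = _extend(qarr, tc, qs, ts, -1, penalty, xdrop)
            dr, mr = _extend(qarr, tc, qe, te, +1, penalty, xdrop)
            qs -= dl
            ts -= dl
            qe += dr
            te += dr
            m += ml + mr
            if strand == "+":
                cs, ce = qs, qe
            else:
                cs, ce = L - qe, L - qs
            results.append(AlignmentSegment(
                contig.id, cs, ce, pan.segments[si].seg_id, ts, te,
                strand, m / (qe - qs), m))

    results.sort(key=lambda s: (s.contig_start, s.contig_end, s.target_id))
    return results


@dataclass
class TrimResult:
    """Partition of a contig into qualifying / retained / discarded bases."""

    contig_id: str
    contig_length: int
    qualifying: list[tuple[int, int]]            # union of qualifying alignments
    retained: list[tuple[int, int, str]]         # novel intervals >= floor, with sequence
    discarded: list[tuple[int, int]]             # complement runs below the floor

    def conserved(self) -> bool:
        total = sum(e - s for s, e in self.qualifying)
        total += sum(e - s for s, e, _ in self.retained)
        total += sum(e - s for s, e in self.discarded)
        return total == self.contig_length


def trim_and_retain(
    contig: SequenceRecord,
    segments: list[AlignmentSegment],
    identity_min: float = 0.90,
    aligned_len_min: int = 100,
    min_retained_len: int = 100,
) -> TrimResult:
    """Subtract qualifying alignments from a contig; keep long novel runs.

    A segment qualifies when identity >= ``identity_min`` AND length >=
    ``aligned_len_min``; overlapping qualifying segments are unioned, never
    double-counted.  Complement runs of length >= ``min_retained_len`` are
    retained as novel sequence; shorter runs are discarded.  The three parts
    exactly partition the contig.
    """
    L = len(contig)
    covered = np.zeros(L, dtype=bool)
    for seg in segments:
        if seg.contig_id != contig.id:
            raise ValueError("segments from a different contig")
        if seg.identity >= identity_min and seg.length >= aligned_len_min:
            covered[seg.contig_start:seg.contig_end] = True

    def runs(mask: np.ndarray) -> list[tuple[int, int]]:
        if not mask.any():
            return []
        d = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if mask[0]:
            starts = np.concatenate([[0], starts])
        if mask[-1]:
            ends = np.concatenate([ends, [L]])
        return list(zip(starts.tolist(), ends.tolist()))

    qualifying = runs(covered)
    retained: list[tuple[int, int, str]] = []
    discarded: list[tuple[int, int]] = []
    for s, e in runs(~covered):
        if e - s >= min_retained_len:
            retained.append((s, e, contig.seq[s:e]))
        else:
            discarded.append((s, e))
    return TrimResult(contig.id, L, qualifying, retained, discarded)


def augment_iterative(
    reference: list[SequenceRecord],
    assemblies: dict[str, list[SequenceRecord]] | list[tuple[str, list[SequenceRecord]]],
    identity_min: float = 0.90,
    aligned_len_min: int = 100,
    min_retained_len: int = 100,
    k: int = 21,
    order: list[str] | None = None,
) -> tuple[PanReference, pd.DataFrame]:
    """Iteratively augment the reference with each accession's novel sequence.

    Accessions are processed in lexicographic id order by default (a fixed,
    configurable order).  For each accession every contig is aligned to the
    *current* pan, trimmed, and its retained sequences appended with
    provenance before the next accession is aligned.  The report gives per
    accession the novel bp, the fraction of its assembly that was novel, and
    the cumulative pan size.
    """
    if isinstance(assemblies, dict):
        items = list(assemblies.items())
    else:
        items = list(assemblies)
        ids = [a for a, _ in items]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate accession id in assemblies")
    lookup = dict(items)
    if len(lookup) != len(items):
        raise ValueError("duplicate accession id in assemblies")
    acc_order = order if order is not None else sorted(lookup)

    pan = PanReference(reference)
    rows = []
    for it, acc in enumerate(acc_order, start=1):
        contigs = lookup[acc]
        assembly_bp = sum(len(c) for c in contigs)
        novel_bp = 0
        for contig in contigs:
            segs = anchor_align(contig, pan, k=k)
            trim = trim_and_retain(contig, segs, identity_min,
                                   aligned_len_min, min_retained_len)
            for s, e, seq in trim.retained:
                pan.add_novel(seq, acc, contig.id, s, e, it)
                novel_bp += e - s
        rows.append({
            "accession": acc, "assembly_bp": assembly_bp, "novel_bp": novel_bp,
            "pct_novel": 100.0 * novel_bp / assembly_bp if assembly_bp else 0.0,
            "pan_bp": pan.total_bp,
        })
        logger.info("augment: %s added %d bp (pan now %d bp)", acc, novel_bp,
                    pan.total_bp)
    return pan, pd.DataFrame(rows)
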