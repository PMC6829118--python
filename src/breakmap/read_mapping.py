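"""Minimal seed-and-extend paired-end read mapper.

Sufficient for error-light synthetic reads: every non-overlapping k-mer of a
read is looked up in a complete two-strand k-mer index, candidate
placements are verified by ungapped Hamming comparison, and each mate is
reported at its unique fewest-mismatch placement (ties break to the
lexicographically smallest ``(chrom, pos)`` and clear the uniqueness flag).
There is no gapped or split alignment: a read straddling a rearrangement
junction accumulates mismatches on the minor side and, beyond the mismatch
allowance, is reported unmapped -- which is exactly the signal the junction
caller consumes downstream.

Externally produced SAM can be used interchangeably with this mapper's
output for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .synthetic_genome import ReferenceSet, SimulatedReads, revcomp

DEFAULT_K = 31
DEFAULT_MAX_MISMATCH = 3

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class MappingError(ValueError):
    pass


def _encode(seq: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _fwd_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.size - k + 1
    h = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        h = (h << np.uint64(2)) | codes[j:j + n].astype(np.uint64)
    return h


def _rc_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    # hash of the reverse complement of each k-mer, in place
    n = codes.size - k + 1
    h = np.zeros(n, dtype=np.uint64)
    for j in range(k - 1, -1, -1):
        h = (h << np.uint64(2)) | (np.uint64(3) - codes[j:j + n].astype(np.uint64))
    return h


@dataclass
class SeedIndex:
    """Complete sorted k-mer occurrence index over both strands.

    A ``+`` entry at ``(chrom, pos)`` records the forward k-mer starting at
    ``pos``; a ``-`` entry records the reverse complement of that k-mer.
    k must be odd (no self-complementary k-mers) and at most 31 (2-bit
    packing into uint64).
    """

    k: int
    names: tuple[str, ...]
    codes: dict[str, np.ndarray]
    hashes: np.ndarray      # sorted
    chrom_id: np.ndarray
    pos: np.ndarray
    strand: np.ndarray      # 0 = '+', 1 = '-'

    @property
    def n_entries(self) -> int:
        return self.hashes.size

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All occurrences of ``kmer`` as (chrom, pos, strand)."""
        if len(kmer) != self.k:
            raise MappingError(f"query length {len(kmer)} != k={self.k}")
        h = _fwd_hashes(_encode(kmer), self.k)[0]
        lo = int(np.searchsorted(self.hashes, h, side="left"))
        hi = int(np.searchsorted(self.hashes, h, side="right"))
        return [(self.names[self.chrom_id[i]], int(self.pos[i]),
                 "+-"[self.strand[i]]) for i in range(lo, hi)]


def build_index(ref: ReferenceSet, k: int = DEFAULT_K) -> SeedIndex:
    if k % 2 == 0:
        raise MappingError("k must be odd")
    if not 1 <= k <= 31:
        raise MappingError("k must be in 1..31")
    names = ref.names
    codes = {n: _encode(s) for n, s in ref.items()}
    hash_parts, cid_parts, pos_parts, strand_parts = [], [], [], []
    for ci, name in enumerate(names):
        c = codes[name]
        if c.size < k:
            continue
        n = c.size - k + 1
        for strand, h in ((0, _fwd_hashes(c, k)), (1, _rc_hashes(c, k))):
            hash_parts.append(h)
            cid_parts.append(np.full(n, ci, dtype=np.uint32))
            pos_parts.append(np.arange(n, dtype=np.uint32))
            strand_parts.append(np.full(n, strand, dtype=np.uint8))
    hashes = np.concatenate(hash_parts)
    order = np.argsort(hashes, kind="stable")
    return SeedIndex(
        k=k, names=names, codes=codes,
        hashes=hashes[order],
        chrom_id=np.concatenate(cid_parts)[order],
        pos=np.concatenate(pos_parts)[order],
        strand=np.concatenate(strand_parts)[order],
    )


@dataclass
class AlignmentRecord:
    """One mate's placement (or non-placement) plus cross-filled mate fields."""

    read_name: str
    is_read1: bool
    mapped: bool
    chrom: str | None
    pos: int                # 0-based leftmost reference position
    strand: str             # '+' or '-'
    match_length: int
    mismatches: int
    unique: bool
    seq: str                # as sequenced (5'->3' of the original read)
    mate_mapped: bool = False
    mate_chrom: str | None = None
    mate_pos: int = -1
    mate_strand: str = "+"
    proper: bool = False
    paired: bool = True

    @property
    def end(self) -> int:
        return self.pos + self.match_length


def _multi_arange(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated ranges lo[i]..hi[i] plus the owning row index."""
    counts = hi - lo
    keep = counts > 0
    cnts = counts[keep]
    if cnts.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    offs = np.repeat(np.cumsum(cnts) - cnts, cnts)
    flat = np.arange(offs.size, dtype=np.int64) - offs + np.repeat(lo[keep], cnts)
    rows = np.repeat(np.flatnonzero(keep), cnts)
    return flat, rows


def _map_mates(seqs: list[str], index: SeedIndex, max_mismatch: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                          np.ndarray, np.ndarray]:
    """Vectorised best-placement search for equal-length mates.

    Returns (mapped, chrom_id, start, strand, mismatches, unique) arrays.
    """
    n = len(seqs)
    L = len(seqs[0])
    k = index.k
    if any(len(s) != L for s in seqs):
        raise MappingError("batch mapping requires equal-length reads")
    if k > L:
        raise MappingError(f"k={k} exceeds read length {L}")

    mat = _CODE_LUT[np.frombuffer("".join(seqs).encode("ascii"),
                                  dtype=np.uint8)].reshape(n, L)
    rc_mat = (3 - mat[:, ::-1]).astype(np.uint8)

    offsets = sorted({*range(0, L - k + 1, k), L - k})
    cand_read, cand_cid, cand_start, cand_strand = [], [], [], []
    for q in offsets:
        sub = mat[:, q:q + k]
        h = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            h = (h << np.uint64(2)) | sub[:, j].astype(np.uint64)
        lo = np.searchsorted(index.hashes, h, side="left")
        hi = np.searchsorted(index.hashes, h, side="right")
        entry, rows = _multi_arange(lo, hi)
        if entry.size == 0:
            continue
        cid = index.chrom_id[entry].astype(np.int64)
        pos = index.pos[entry].astype(np.int64)
        strand = index.strand[entry].astype(np.int64)
        start = np.where(strand == 0, pos - q, pos + q + k - L)
        cand_read.append(rows)
        cand_cid.append(cid)
        cand_start.append(start)
        cand_strand.append(strand)

    empty = (np.zeros(n, bool), np.full(n, -1), np.full(n, -1),
             np.zeros(n, np.int64), np.full(n, L), np.zeros(n, bool))
    if not cand_read:
        return empty

    ridx = np.concatenate(cand_read)
    cid = np.concatenate(cand_cid)
    start = np.concatenate(cand_start)
    strand = np.concatenate(cand_strand)

    chrom_len = np.array([index.codes[nm].size for nm in index.names])
    ok = (start >= 0) & (start + L <= chrom_len[cid])
    ridx, cid, start, strand = ridx[ok], cid[ok], start[ok], strand[ok]
    if ridx.size == 0:
        return empty

    key = ((ridx * len(index.names) + cid) * 2 + strand).astype(np.uint64)
    key = (key << np.uint64(32)) | start.astype(np.uint64)
    _, uidx = np.unique(key, return_index=True)
    ridx, cid, start, strand = ridx[uidx], cid[uidx], start[uidx], strand[uidx]

    genome = np.concatenate([index.codes[nm] for nm in index.names])
    chrom_off = np.concatenate(([0], np.cumsum(chrom_len)))[:-1]
    mm = np.empty(ridx.size, dtype=np.int64)
    for c0 in range(0, ridx.size, 1_000_000):
        c1 = min(c0 + 1_000_000, ridx.size)
        gidx = (chrom_off[cid[c0:c1]] + start[c0:c1])[:, None] + np.arange(L)
        windows = genome[gidx]
        reads = np.where((strand[c0:c1] == 0)[:, None],
                         mat[ridx[c0:c1]], rc_mat[ridx[c0:c1]])
        mm[c0:c1] = (windows != reads).sum(axis=1)

    good = mm <= max_mismatch
    ridx, cid, start, strand, mm = (a[good] for a in (ridx, cid, start, strand, mm))

    mapped = np.zeros(n, bool)
    out_cid = np.full(n, -1, dtype=np.int64)
    out_start = np.full(n, -1, dtype=np.int64)
    out_strand = np.zeros(n, dtype=np.int64)
    out_mm = np.full(n, L, dtype=np.int64)
    out_unique = np.zeros(n, bool)
    if ridx.size:
        name_rank = np.argsort(np.argsort(np.asarray(index.names)))
        order = np.lexsort((strand, start, name_rank[cid], mm, ridx))
        ridx_s = ridx[order]
        first = np.unique(ridx_s, return_index=True)[1]
        sel = order[first]
        r = ridx[sel]
        mapped[r] = True
        out_cid[r] = cid[sel]
        out_start[r] = start[sel]
        out_strand[r] = strand[sel]
        out_mm[r] = mm[sel]
        # a read is unique unless its second-best candidate ties the best
        nxt = first + 1
        has_next = nxt < ridx_s.size
        tie = np.zeros(first.size, bool)
        hn = np.flatnonzero(has_next)
        tie[hn] = (ridx_s[nxt[hn]] == ridx_s[first[hn]]) & \
                  (mm[order[nxt[hn]]] == mm[order[first[hn]]])
        out_unique[r] = ~tie
    return mapped, out_cid, out_start, out_strand, out_mm, out_unique


def map_pairs(reads: SimulatedReads | tuple[Sequence[str], Sequence[str], Sequence[str]],
              index: SeedIndex,
              max_mismatch: int = DEFAULT_MAX_MISMATCH,
              insert_mean: float = 350.0,
              insert_sd: float = 35.0) -> list[AlignmentRecord]:
    """Map read pairs, cross-fill mate fields and set proper-pair flags.

    ``reads`` is either a :class:`SimulatedReads` or a ``(names, seq1,
    seq2)`` triple.  A pair is *proper* when both mates map to the same
    chromosome in FR orientation with an observed insert within
    ``insert_mean +/- 4 * insert_sd``.
    """
    if isinstance(reads, SimulatedReads):
        names, seq1, seq2 = reads.names, reads.seq1, reads.seq2
    else:
        names, seq1, seq2 = reads
    if len(seq1) != len(seq2) or len(names) != len(seq1):
        raise MappingError("mate lists of unequal length")
    n = len(names)
    if n == 0:
        return []

    flat = list(seq1) + list(seq2)
    mapped, cid, start, strand, mm, unique = _map_mates(flat, index, max_mismatch)

    records: list[AlignmentRecord] = []
    lo_ins = insert_mean - 4 * insert_sd
    hi_ins = insert_mean + 4 * insert_sd
    for i in range(n):
        recs = []
        for mate, j in ((True, i), (False, n + i)):
            L = len(flat[j])
            recs.append(AlignmentRecord(
                read_name=names[i], is_read1=mate,
                mapped=bool(mapped[j]),
                chrom=index.names[cid[j]] if mapped[j] else None,
                pos=int(start[j]), strand="+-"[int(strand[j])],
                match_length=L if mapped[j] else 0,
                mismatches=int(mm[j]) if mapped[j] else -1,
                unique=bool(unique[j]), seq=flat[j],
            ))
        r1, r2 = recs
        for a, b in ((r1, r2), (r2, r1)):
            a.mate_mapped = b.mapped
            a.mate_chrom = b.chrom
            a.mate_pos = b.pos
            a.mate_strand = b.strand
        if r1.mapped and r2.mapped and r1.chrom == r2.chrom and r1.strand != r2.strand:
            left, right = (r1, r2) if r1.pos <= r2.pos else (r2, r1)
            insert = right.end - left.pos
            if left.strand == "+" and lo_ins <= insert <= hi_ins:
                r1.proper = r2.proper = True
        records.extend(recs)
    return records


# --- SAM serialization ----------------------------------------------------

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_MATE_UNMAPPED = 0x8
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80


def sam_text(records: Iterable[AlignmentRecord], ref: ReferenceSet) -> str:
    """Serialize alignment records as SAM with @SQ headers."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in ref.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    for r in records:
        flag = _FLAG_PAIRED
        flag |= _FLAG_READ1 if r.is_read1 else _FLAG_READ2
        if r.proper:
            flag |= _FLAG_PROPER
        if not r.mapped:
            flag |= _FLAG_UNMAPPED
        if not r.mate_mapped:
            flag |= _FLAG_MATE_UNMAPPED
        if r.mapped and r.strand == "-":
            flag |= _FLAG_REVERSE
        if r.mate_mapped and r.mate_strand == "-":
            flag |= _FLAG_MATE_REVERSE
        rname = r.chrom if r.mapped else "*"
        pos = r.pos + 1 if r.mapped else 0
        mapq = 60 if (r.mapped and r.unique) else 0
        cigar = f"{r.match_length}M" if r.mapped else "*"
        if r.mate_mapped:
            rnext = "=" if (r.mapped and r.mate_chrom == r.chrom) else r.mate_chrom
            pnext = r.mate_pos + 1
        else:
            rnext, pnext = "*", 0
        tlen = 0
        if r.mapped and r.mate_mapped and r.mate_chrom == r.chrom:
            lo = min(r.pos, r.mate_pos)
            hi = max(r.end, r.mate_pos + len(r.seq))
            tlen = hi - lo if r.pos <= r.mate_pos else -(hi - lo)
        seq = r.seq if (not r.mapped or r.strand == "+") else revcomp(r.seq)
        qual = "I" * len(seq)
        nm = f"\tNM:i:{r.mismatches}" if r.mapped else ""
        lines.append("\t".join(map(str, (
            r.read_name, flag, rname, pos, mapq, cigar, rnext, pnext, tlen,
            seq, qual))) + nm)
    return "\n".join(lines) + "\n"


def write_sam(records: Iterable[AlignmentRecord], ref: ReferenceSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(sam_text(records, ref))


def read_sam(path) -> list[AlignmentRecord]:
    """Load alignment records from SAM (e.g. produced by an external mapper)."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            mapped = not aln.is_unmapped
            seq = aln.query_sequence or ""
            if mapped and aln.is_reverse:
                seq = revcomp(seq)
            records.append(AlignmentRecord(
                read_name=aln.query_name,
                is_read1=not aln.is_read2,
                mapped=mapped,
                chrom=aln.reference_name if mapped else None,
                pos=aln.reference_start if mapped else -1,
                strand="-" if (mapped and aln.is_reverse) else "+",
                match_length=aln.query_alignment_length if mapped else 0,
                mismatches=int(aln.get_tag("NM")) if aln.has_tag("NM") else 0,
                unique=(aln.mapping_quality > 0) if mapped else False,
                seq=seq,
                mate_mapped=not aln.mate_is_unmapped,
                mate_chrom=aln.next_reference_name if not aln.mate_is_unmapped else None,
                mate_pos=aln.next_reference_start,
                mate_strand="-" if aln.mate_is_reverse else "+",
                proper=aln.is_proper_pair,
            ))
    return records
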