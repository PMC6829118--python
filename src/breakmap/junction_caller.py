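"""Junction reconstruction and NHEJ-signature characterization.

Reads that span a fusion junction fail ungapped mapping; collecting them by
their mapped mates, merging them by greedy maximal exact overlap, and
aligning the resulting consensus against both wild-type references resolves
the junction at base precision: exact breakpoints, microhomology,
insertions (and whether they look templated from the flanks), and the
per-chromosome deletion accounting of the reciprocal event.  The output is
the computational analogue of PCR-amplifying and Sanger-sequencing the two
trans-breakpoint fragments.

Canonical representation: among the equivalent breakpoint placements a
microhomology allows, the one attributing the shared bases maximally to the
left (prefix) reference is reported -- the same convention the simulator's
truth records use, so recovery is testable as exact equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .discordant_clustering import BreakpointCandidate
from .read_mapping import AlignmentRecord
from .synthetic_genome import ReferenceSet, revcomp

BLUNT = "blunt"
MICROHOMOLOGY = "microhomology"
UNTEMPLATED = "untemplated-insertion"
TEMPLATED_DUP = "templated-duplication"

DEFAULT_OVERLAP_MIN = 20
DEFAULT_MATCH_FLOOR = 30
TEMPLATED_WINDOW = 3


class AssemblyError(ValueError):
    pass


class CharacterizeError(ValueError):
    pass


@dataclass
class JunctionConsensus:
    derivative_id: str
    sequence: str
    supporting_reads: int


def collect_junction_reads(alignments: Iterable[AlignmentRecord],
                           candidate: BreakpointCandidate,
                           margin: int = 700) -> list[str]:
    """Junction-spanning read sequences near a candidate, derivative-forward.

    An unmapped read whose uniquely mapped mate lies within ``margin`` of
    either candidate footprint *and* matches that side's strand consensus is
    taken to span the junction.  The strand filter matters because the two
    junctions of a reciprocal event sit close together on both partner
    chromosomes when deletions are small; their anchoring mates are only
    distinguishable by orientation.  Mate 1 reads are emitted as sequenced,
    mate 2 reads reverse-complemented, so all returned sequences run in the
    derivative's forward orientation.
    """
    regions = {
        candidate.chrom_a: (candidate.start_a - margin, candidate.end_a + margin,
                            candidate.strand_a),
        candidate.chrom_b: (candidate.start_b - margin, candidate.end_b + margin,
                            candidate.strand_b),
    }
    out: list[str] = []
    seen: set[str] = set()
    for r in alignments:
        if r.mapped or not r.mate_mapped or r.mate_chrom not in regions:
            continue
        lo, hi, strand = regions[r.mate_chrom]
        if r.mate_strand != strand or not (lo <= r.mate_pos <= hi):
            continue
        seq = r.seq if r.is_read1 else revcomp(r.seq)
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def _best_overlap(left: str, right: str, overlap_min: int, tol: int = 0) -> int:
    """Longest o >= overlap_min with left[-o:] matching right[:o], else 0.

    ``tol`` mismatches are allowed per overlap (0 = exact, the default; 1 is
    the tolerant mode for error-carrying reads).
    """
    if len(right) < overlap_min:
        return 0
    if tol > 0:
        for o in range(min(len(left), len(right)), overlap_min - 1, -1):
            if sum(a != b for a, b in zip(left[-o:], right[:o])) <= tol:
                return o
        return 0
    anchor = right[:overlap_min]
    t = left.find(anchor)
    limit = len(left) - overlap_min
    while 0 <= t <= limit:
        o = len(left) - t
        if o <= len(right) and left[t:] == right[:o]:
            return o
        t = left.find(anchor, t + 1)
    return 0


def assemble_junction(reads: Sequence[str],
                      overlap_min: int = DEFAULT_OVERLAP_MIN,
                      derivative_id: str = "der",
                      overlap_mismatch: int = 0) -> JunctionConsensus:
    """Greedy maximal-overlap merge of junction-spanning reads.

    Longest overlap first, ties broken by input order; raises if fewer than
    two reads are available or no overlap of at least ``overlap_min`` links
    the fragments into a single contig, and on ambiguous branching (two
    inconsistent extensions of equal overlap).  Overlaps are exact by
    default; ``overlap_mismatch=1`` tolerates one mismatch per overlap for
    reads simulated with a non-zero error rate (the left fragment's base
    wins in the merge).
    """
    if len(reads) < 2:
        raise AssemblyError("no junction-spanning reads (need at least 2)")

    # drop exact duplicates and contained fragments
    frags: list[str] = []
    for r in sorted(set(reads), key=len, reverse=True):
        if not any(r in f for f in frags):
            frags.append(r)
    # restore input order among survivors for deterministic tie-breaking
    frags = [r for r in dict.fromkeys(reads) if r in set(frags)]
    n_input = len(reads)
    if len(frags) == 1:
        return JunctionConsensus(derivative_id, frags[0], n_input)

    overlaps: dict[tuple[int, int], int] = {}
    active = {i: f for i, f in enumerate(frags)}

    def refresh(i: int) -> None:
        for j in active:
            if j != i:
                overlaps[(i, j)] = _best_overlap(active[i], active[j],
                                                 overlap_min, overlap_mismatch)
                overlaps[(j, i)] = _best_overlap(active[j], active[i],
                                                 overlap_min, overlap_mismatch)

    ids = list(active)
    for x, i in enumerate(ids):
        for j in ids[x + 1:]:
            overlaps[(i, j)] = _best_overlap(active[i], active[j],
                                             overlap_min, overlap_mismatch)
            overlaps[(j, i)] = _best_overlap(active[j], active[i],
                                             overlap_min, overlap_mismatch)

    next_id = len(frags)
    while len(active) > 1:
        best = max(overlaps.items(), key=lambda kv: kv[1])
        (bi, bj), o = best
        if o < overlap_min or o == 0:
            raise AssemblyError(
                f"no overlap >= {overlap_min} links the junction-spanning reads")
        rivals = [(i, j) for (i, j), v in overlaps.items() if v == o and i == bi]
        exts = {active[j][o:] if len(active[j]) > o else "" for _, j in rivals}
        if len(exts) > 1 and not _consistent_extensions(exts):
            raise AssemblyError("ambiguous branch: inconsistent equal-overlap extensions")
        merged = active[bi] + active[bj][o:]
        for key in [k for k in overlaps if bi in k or bj in k]:
            del overlaps[key]
        del active[bi], active[bj]
        # drop fragments the merge now contains
        for k in [k for k, f in active.items() if f in merged]:
            for key in [kk for kk in overlaps if k in kk]:
                del overlaps[key]
            del active[k]
        active[next_id] = merged
        refresh(next_id)
        next_id += 1
    return JunctionConsensus(derivative_id, next(iter(active.values())), n_input)


def _consistent_extensions(exts: set[str]) -> bool:
    longest = max(exts, key=len)
    return all(longest.startswith(e) for e in exts)


def write_consensus_fasta(consensi: Sequence[JunctionConsensus], path) -> None:
    with open(path, "w") as fh:
        for c in consensi:
            fh.write(f">{c.derivative_id} supporting_reads={c.supporting_reads}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i:i + 60] + "\n")


@dataclass
class JunctionCall:
    """Fully characterized fusion junction (1-based, prefix-maximal canon).

    ``left_pos`` is the last base of the left reference present in the
    derivative, ``right_pos`` the first base of the right reference.
    Exactly one of microhomology and insertion can be non-empty; the
    signature summarises the repair anatomy.
    """

    derivative_id: str
    left_chrom: str
    left_pos: int
    right_chrom: str
    right_pos: int
    mh_len: int
    mh_seq: str
    ins_seq: str
    ins_templated: bool
    signature: str
    supporting_reads: int = 0

    def to_dict(self) -> dict:
        return {
            "derivativeId": self.derivative_id,
            "leftChrom": self.left_chrom, "leftPos": self.left_pos,
            "rightChrom": self.right_chrom, "rightPos": self.right_pos,
            "mhLen": self.mh_len, "mhSeq": self.mh_seq,
            "insSeq": self.ins_seq, "insTemplated": self.ins_templated,
            "signature": self.signature,
            "supportingReads": self.supporting_reads,
        }


def _occurrences(hay: str, needle: str, lo: int, hi: int) -> list[int]:
    out = []
    t = hay.find(needle, max(0, lo))
    while t != -1 and t < hi:
        out.append(t)
        t = hay.find(needle, t + 1)
    return out


def characterize(consensus: str,
                 left_ref: tuple[str, str], right_ref: tuple[str, str],
                 left_region: tuple[int, int], right_region: tuple[int, int],
                 derivative_id: str = "der",
                 match_floor: int = DEFAULT_MATCH_FLOOR,
                 supporting_reads: int = 0) -> JunctionCall:
    """Resolve a junction consensus against both wild-type references.

    ``p`` is the longest consensus prefix matching the left reference
    within ``left_region`` and ``s`` the longest suffix matching the right
    reference within ``right_region``.  If ``p + s >= len(consensus)`` the
    junction carries ``p + s - len`` bases of microhomology; otherwise the
    unmatched middle is an insertion, flagged as templated when it copies
    up to three bases immediately flanking either breakpoint.
    """
    left_name, left_seq = left_ref
    right_name, right_seq = right_ref
    n = len(consensus)
    if n < 2 * match_floor:
        raise CharacterizeError("consensus shorter than twice the match floor")

    best_p, best_x = 0, -1
    for x in _occurrences(left_seq, consensus[:match_floor],
                          left_region[0], left_region[1]):
        p = match_floor
        while p < n and x + p < len(left_seq) and consensus[p] == left_seq[x + p]:
            p += 1
        if p > best_p:
            best_p, best_x = p, x
    if best_x < 0 or best_p < match_floor:
        raise CharacterizeError(
            f"consensus prefix does not anchor on {left_name} (floor {match_floor})")

    best_s, best_y = 0, -1
    for y in _occurrences(right_seq, consensus[n - match_floor:],
                          right_region[0], right_region[1]):
        s = match_floor
        while (s < n and y - (s - match_floor) - 1 >= 0
               and consensus[n - s - 1] == right_seq[y - (s - match_floor) - 1]):
            s += 1
        if s > best_s:
            best_s, best_y = s, y
    if best_y < 0 or best_s < match_floor:
        raise CharacterizeError(
            f"consensus suffix does not anchor on {right_name} (floor {match_floor})")

    p, s = best_p, best_s
    suffix_end = best_y + match_floor        # exclusive end of suffix match
    if p + s >= n:
        mh = p + s - n
        left_end0 = best_x + p
        right_start0 = (suffix_end - s) + mh
        mh_seq = left_seq[left_end0 - mh:left_end0]
        ins = ""
    else:
        mh, mh_seq = 0, ""
        left_end0 = best_x + p
        right_start0 = suffix_end - s
        ins = consensus[p:n - s]

    templated = False
    if ins and len(ins) <= TEMPLATED_WINDOW:
        d = len(ins)
        templated = (ins == left_seq[left_end0 - d:left_end0]
                     or ins == right_seq[right_start0:right_start0 + d])
    if mh > 0:
        signature = MICROHOMOLOGY
    elif ins:
        signature = TEMPLATED_DUP if templated else UNTEMPLATED
    else:
        signature = BLUNT
    return JunctionCall(
        derivative_id=derivative_id,
        left_chrom=left_name, left_pos=left_end0,
        right_chrom=right_name, right_pos=right_start0 + 1,
        mh_len=mh, mh_seq=mh_seq, ins_seq=ins, ins_templated=templated,
        signature=signature, supporting_reads=supporting_reads,
    )


@dataclass
class ReciprocalSummary:
    """Per-chromosome base accounting of a reciprocal translocation."""

    chrom_a: str
    chrom_b: str
    del_a: int
    del_b: int
    dup_total: int


def summarize_reciprocal(call_ab: JunctionCall, call_ba: JunctionCall,
                         ref: ReferenceSet,
                         derivatives: ReferenceSet | None = None
                         ) -> ReciprocalSummary:
    """Combine the two junction calls of one event into deletion totals.

    ``del_a`` counts reference-A bases present in neither derivative
    (microhomology counted once via the shared canon); the length identity
    ``len(der1) + len(der2) = len(A) + len(B) - delA - delB + dupTotal`` is
    verified when the derivative sequences are supplied.
    """
    if (call_ab.left_chrom != call_ba.right_chrom
            or call_ab.right_chrom != call_ba.left_chrom):
        raise ValueError("junction calls reference different chromosome pairs")
    chrom_a, chrom_b = call_ab.left_chrom, call_ab.right_chrom
    del_a = (call_ba.right_pos - 1) - call_ab.left_pos
    del_b = (call_ab.right_pos - 1) - call_ba.left_pos
    dup = len(call_ab.ins_seq) + len(call_ba.ins_seq)
    if derivatives is not None:
        lhs = sum(len(s) for _, s in derivatives.items())
        rhs = (ref.length(chrom_a) + ref.length(chrom_b) - del_a - del_b + dup)
        if lhs != rhs:
            raise ValueError(
                f"length accounting identity violated: {lhs} != {rhs}")
    return ReciprocalSummary(chrom_a, chrom_b, del_a, del_b, dup)


def bnd_vcf_text(calls: Sequence[JunctionCall], ref: ReferenceSet) -> str:
    """VCF 4.2 with one pair of cross-referencing BND records per junction."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
        '##INFO=<ID=EVENT,Number=1,Type=String,Description="ID of the rearrangement event">',
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Length of breakpoint microhomology">',
        '##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="Sequence of breakpoint microhomology">',
    ]
    for name, seq in ref.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in calls:
        ida = f"bnd_{call.derivative_id}_a"
        idb = f"bnd_{call.derivative_id}_b"
        ref_l = ref[call.left_chrom][call.left_pos - 1]
        ref_r = ref[call.right_chrom][call.right_pos - 1]
        hom = ""
        if call.mh_len > 0:
            hom = f";HOMLEN={call.mh_len};HOMSEQ={call.mh_seq}"
        alt_a = f"{ref_l}{call.ins_seq}[{call.right_chrom}:{call.right_pos}["
        alt_b = f"]{call.left_chrom}:{call.left_pos}]{call.ins_seq}{ref_r}"
        info_a = f"SVTYPE=BND;MATEID={idb};EVENT={call.derivative_id}{hom}"
        info_b = f"SVTYPE=BND;MATEID={ida};EVENT={call.derivative_id}{hom}"
        lines.append(f"{call.left_chrom}\t{call.left_pos}\t{ida}\t{ref_l}\t"
                     f"{alt_a}\t.\tPASS\t{info_a}")
        lines.append(f"{call.right_chrom}\t{call.right_pos}\t{idb}\t{ref_r}\t"
                     f"{alt_b}\t.\tPASS\t{info_b}")
    return "\n".join(lines) + "\n"


def write_bnd_vcf(calls: Sequence[JunctionCall], ref: ReferenceSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(bnd_vcf_text(calls, ref))
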