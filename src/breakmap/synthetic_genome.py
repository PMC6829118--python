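"""Synthetic references, reciprocal translocations and paired-end read simulation.

This module builds the fully controlled test bed for the breakpoint-mapping
pipeline: random reference chromosomes, a reciprocal translocation with
configurable junction anatomy (per-chromosome deletions, microhomology,
short templated duplications -- the classic non-homologous end-joining
repertoire), and targeted-capture paired-end Illumina-like reads around the
junctions.  Every simulated dataset carries a machine-readable truth record
so that downstream recovery is exactly testable.

Coordinates are 0-based half-open throughout this module; human-facing
reports elsewhere convert to 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_NON_ACGT = str.maketrans("", "", "ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered, named chromosome sequences over the strict {A,C,G,T} alphabet."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ReferenceError(f"duplicate sequence names: {names}")
        for name, seq in self.entries:
            if not seq:
                raise ReferenceError(f"empty sequence for {name!r}")
            if seq.translate(_NON_ACGT):
                raise ReferenceError(f"non-ACGT characters in {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def __getitem__(self, name: str) -> str:
        for n, s in self.entries:
            if n == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def length(self, name: str) -> int:
        return len(self[name])

    def items(self) -> tuple[tuple[str, str], ...]:
        return self.entries


def make_reference(spec: Iterable[tuple[str, int, int]]) -> ReferenceSet:
    """Deterministic i.i.d.-uniform ACGT chromosomes.

    Parameters
    ----------
    spec
        Iterable of ``(name, length, seed)``.  The same ``(length, seed)``
        always yields the identical sequence.
    """
    entries = []
    for name, length, seed in spec:
        if length < 1:
            raise ReferenceError(f"non-positive length for {name!r}")
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        entries.append((name, _BASE_BYTES[codes].tobytes().decode("ascii")))
    return ReferenceSet(tuple(entries))


class EventError(ValueError):
    pass


@dataclass(frozen=True)
class TranslocationEvent:
    """A reciprocal translocation between two chromosomes.

    The two derivative chromosomes are

    * ``der(A;B) = chrA[0:a1] + ins1 + chrB[b1:]``
    * ``der(B;A) = chrB[0:b2] + ins2 + chrA[a2:]``

    so ``delA = a2 - a1`` bases of chrA and ``delB = b1 - b2`` bases of chrB
    appear in neither derivative, and ``ins1``/``ins2`` are junction
    insertions (typically short templated duplications).
    """

    chr_a: str
    chr_b: str
    a1: int
    a2: int
    b1: int
    b2: int
    ins1: str = ""
    ins2: str = ""

    def __post_init__(self) -> None:
        if self.chr_a == self.chr_b:
            raise EventError("reciprocal translocation needs two distinct chromosomes")
        if not (0 <= self.a1 <= self.a2):
            raise EventError("require 0 <= a1 <= a2")
        if not (0 <= self.b2 <= self.b1):
            raise EventError("require 0 <= b2 <= b1")
        for ins in (self.ins1, self.ins2):
            if ins.translate(_NON_ACGT):
                raise EventError("insertions must be ACGT")

    @property
    def del_a(self) -> int:
        return self.a2 - self.a1

    @property
    def del_b(self) -> int:
        return self.b1 - self.b2


@dataclass(frozen=True)
class JunctionCanon:
    """Canonical representation of one fusion junction.

    ``left_end0`` is the 0-based exclusive end of the left-reference segment
    used by the derivative, ``right_start0`` the 0-based start of the right
    segment.  Microhomology is attributed maximally to the left (prefix)
    side, so among all equivalent breakpoint representations this is the one
    with the largest left anchor; the same convention is applied by the
    junction caller, making truth and call directly comparable.
    """

    left_end0: int
    right_start0: int
    mh_len: int
    mh_seq: str
    ins_seq: str


def canonical_junction(ref_left: str, cut_left: int, ref_right: str,
                       cut_right: int, ins: str = "") -> JunctionCanon:
    """Canonicalize a junction ``ref_left[:cut_left] + ins + ref_right[cut_right:]``.

    Homology between the two references around the cut makes the breakpoint
    representation ambiguous; this resolves it by extending the left match as
    far as possible (prefix-maximal canon).  An insertion that happens to
    match reference bases at either side is absorbed into the flanks; what
    cannot be absorbed is reported as ``ins_seq``.
    """
    n_ins = len(ins)

    def right_base(i: int) -> str | None:
        # base i positions to the right of the left cut, on the derivative
        if i < n_ins:
            return ins[i]
        j = cut_right + i - n_ins
        return ref_right[j] if j < len(ref_right) else None

    def left_base(i: int) -> str | None:
        # base i positions to the left of the right-segment start
        if i < n_ins:
            return ins[n_ins - 1 - i]
        j = cut_left - 1 - (i - n_ins)
        return ref_left[j] if j >= 0 else None

    p_ext = 0
    while cut_left + p_ext < len(ref_left):
        b = right_base(p_ext)
        if b is None or ref_left[cut_left + p_ext] != b:
            break
        p_ext += 1
    s_ext = 0
    while cut_right - 1 - s_ext >= 0:
        b = left_base(s_ext)
        if b is None or ref_right[cut_right - 1 - s_ext] != b:
            break
        s_ext += 1

    if p_ext + s_ext >= n_ins:
        mh = p_ext + s_ext - n_ins
        left_end0 = cut_left + p_ext
        right_start0 = cut_right + p_ext - n_ins
        return JunctionCanon(left_end0, right_start0, mh,
                             ref_left[left_end0 - mh:left_end0], "")
    left_end0 = cut_left + p_ext
    right_start0 = cut_right - s_ext
    return JunctionCanon(left_end0, right_start0, 0, "",
                         ins[p_ext:n_ins - s_ext])


@dataclass
class TruthRecord:
    """Canonical answer key for one simulated reciprocal translocation.

    Coordinates are the canonical (prefix-maximal) junction representation:
    ``a1``/``b1`` describe der(A;B) (chrA used up to ``a1``, chrB from
    ``b1``), ``b2``/``a2`` describe der(B;A).  ``ins1``/``ins2`` are the
    canonical residual insertions, which may differ from the literal event
    insertions when flanking homology absorbs part of them.
    """

    chr_a: str
    chr_b: str
    a1: int
    a2: int
    b1: int
    b2: int
    ins1: str
    ins2: str
    mh_len1: int
    mh_len2: int
    seed: int | None = None
    capture_windows: list[tuple[str, int, int]] = field(default_factory=list)
    mh_seq1: str = ""
    mh_seq2: str = ""

    @property
    def del_a(self) -> int:
        return self.a2 - self.a1

    @property
    def del_b(self) -> int:
        return self.b1 - self.b2

    @property
    def dup_total(self) -> int:
        return len(self.ins1) + len(self.ins2)

    def to_json(self) -> str:
        return json.dumps({
            "chrA": self.chr_a, "chrB": self.chr_b,
            "a1": self.a1, "a2": self.a2, "b1": self.b1, "b2": self.b2,
            "ins1": self.ins1, "ins2": self.ins2,
            "mhLen1": self.mh_len1, "mhLen2": self.mh_len2,
            "seed": self.seed,
            "captureWindows": [list(w) for w in self.capture_windows],
            "mhSeq1": self.mh_seq1, "mhSeq2": self.mh_seq2,
        })

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            chr_a=d["chrA"], chr_b=d["chrB"],
            a1=d["a1"], a2=d["a2"], b1=d["b1"], b2=d["b2"],
            ins1=d["ins1"], ins2=d["ins2"],
            mh_len1=d["mhLen1"], mh_len2=d["mhLen2"],
            seed=d["seed"],
            capture_windows=[tuple(w) for w in d["captureWindows"]],
            mh_seq1=d.get("mhSeq1", ""), mh_seq2=d.get("mhSeq2", ""),
        )


DER_AB = "derAB"
DER_BA = "derBA"


def apply_translocation(ref: ReferenceSet, event: TranslocationEvent,
                        seed: int | None = None,
                        capture_windows: Sequence[tuple[str, int, int]] = (),
                        ) -> tuple[ReferenceSet, TruthRecord]:
    """Build the two derivative chromosomes and the canonical truth record."""
    seq_a = ref[event.chr_a]
    seq_b = ref[event.chr_b]
    if event.a2 > len(seq_a):
        raise EventError("chrA offsets out of range")
    if event.b1 > len(seq_b):
        raise EventError("chrB offsets out of range")

    der_ab = seq_a[:event.a1] + event.ins1 + seq_b[event.b1:]
    der_ba = seq_b[:event.b2] + event.ins2 + seq_a[event.a2:]
    derivatives = ReferenceSet(((DER_AB, der_ab), (DER_BA, der_ba)))

    c1 = canonical_junction(seq_a, event.a1, seq_b, event.b1, event.ins1)
    c2 = canonical_junction(seq_b, event.b2, seq_a, event.a2, event.ins2)
    for chrom, start, end in capture_windows:
        if chrom not in derivatives and chrom not in ref:
            raise EventError(f"capture window on unknown sequence {chrom!r}")
        target = derivatives[chrom] if chrom in derivatives else ref[chrom]
        if not (0 <= start < end <= len(target)):
            raise EventError(f"capture window {chrom}:{start}-{end} out of bounds")

    truth = TruthRecord(
        chr_a=event.chr_a, chr_b=event.chr_b,
        a1=c1.left_end0, b1=c1.right_start0,
        b2=c2.left_end0, a2=c2.right_start0,
        ins1=c1.ins_seq, ins2=c2.ins_seq,
        mh_len1=c1.mh_len, mh_len2=c2.mh_len,
        mh_seq1=c1.mh_seq, mh_seq2=c2.mh_seq,
        seed=seed, capture_windows=list(capture_windows),
    )
    return derivatives, truth


def random_event(ref: ReferenceSet, chr_a: str, chr_b: str,
                 rng: np.random.Generator, *,
                 del_a: int = 6, del_b: int = 8,
                 mh1: int = 3, mh2: int = 0,
                 dup1: int = 0, dup2: int = 2,
                 ) -> tuple[ReferenceSet, TranslocationEvent]:
    """Draw breakpoints and plant the requested junction anatomy.

    Defaults mirror the junction anatomy of a classic NHEJ-repaired
    germline translocation:
    6 and 8 bp lost from the two partner chromosomes, a 3-nt microhomology
    at one fusion site and a short (1-3 nt) templated duplication at the
    other.  Microhomology is planted by copying the left-flank bases of one
    junction partner over the corresponding bases of the other, so it is a
    genuine shared sequence of the two (possibly modified) references; the
    modified ``ReferenceSet`` is returned alongside the event.  A junction
    cannot carry both microhomology and a duplication.
    """
    if mh1 and dup1:
        raise EventError("junction 1 cannot have both microhomology and duplication")
    if mh2 and dup2:
        raise EventError("junction 2 cannot have both microhomology and duplication")
    if min(del_a, del_b, mh1, mh2, dup1, dup2) < 0:
        raise EventError("junction edit sizes must be non-negative")

    len_a = ref.length(chr_a)
    len_b = ref.length(chr_b)
    a1 = int(rng.integers(len_a // 3, 2 * len_a // 3))
    b2 = int(rng.integers(len_b // 3, 2 * len_b // 3))
    a2 = a1 + del_a
    b1 = b2 + del_b

    seqs = {name: bytearray(seq, "ascii") for name, seq in ref.items()}
    if mh2:
        seqs[chr_a][a2 - mh2:a2] = seqs[chr_b][b2 - mh2:b2]
    if mh1:
        seqs[chr_b][b1 - mh1:b1] = seqs[chr_a][a1 - mh1:a1]
    new_ref = ReferenceSet(tuple((n, s.decode("ascii")) for n, s in seqs.items()))

    seq_a, seq_b = new_ref[chr_a], new_ref[chr_b]
    ins1 = ins2 = ""
    if dup1:
        ins1 = seq_a[a1 - dup1:a1] if rng.integers(2) == 0 else seq_b[b1:b1 + dup1]
    if dup2:
        ins2 = seq_b[b2 - dup2:b2] if rng.integers(2) == 0 else seq_a[a2:a2 + dup2]
    return new_ref, TranslocationEvent(chr_a, chr_b, a1, a2, b1, b2, ins1, ins2)


def _other_base(*avoid: int) -> int:
    for b in b"ACGT":
        if b not in avoid:
            return b
    raise AssertionError("unreachable")


def exemplar_event(ref: ReferenceSet, chr_a: str, chr_b: str,
                   rng: np.random.Generator) -> tuple[ReferenceSet, TranslocationEvent]:
    """An event with the published exemplar junction anatomy, exactly.

    6 bp deleted from chromosome A and 8 bp from chromosome B, a shared
    GCT triplet at the der(A;B) fusion (present once in the derivative)
    and a 2-nt templated duplication at the der(B;A) fusion.  The bases
    immediately beyond each junction edit are fixed to differ between the
    two references, so no accidental flanking homology can shift the
    canonical representation: the truth record reports the literal
    6 / 8 / GCT / 2-nt anatomy.
    """
    del_a, del_b = 6, 8
    len_a, len_b = ref.length(chr_a), ref.length(chr_b)
    a1 = int(rng.integers(len_a // 3, 2 * len_a // 3))
    b2 = int(rng.integers(len_b // 3, 2 * len_b // 3))
    a2, b1 = a1 + del_a, b2 + del_b

    seqs = {name: bytearray(seq, "ascii") for name, seq in ref.items()}
    A, B = seqs[chr_a], seqs[chr_b]
    # junction 1: one GCT copy on each partner, nothing shared beyond it
    A[a1 - 3:a1] = b"GCT"
    B[b1 - 3:b1] = b"GCT"
    if A[a1] == B[b1]:
        B[b1] = _other_base(A[a1])
    if A[a1 - 4] == B[b1 - 4]:
        B[b1 - 4] = _other_base(A[a1 - 4])          # inside the deleted B segment
    # junction 2: blunt apart from a 2-nt duplication templated from the A side
    if B[b2] == A[a2]:
        B[b2] = _other_base(A[a2])                  # inside the deleted B segment
    if A[a2 - 1] == A[a2 + 1]:
        A[a2 - 1] = _other_base(A[a2 + 1])          # inside the deleted A segment
    new_ref = ReferenceSet(tuple((n, s.decode("ascii")) for n, s in seqs.items()))
    ins2 = new_ref[chr_a][a2:a2 + 2]
    return new_ref, TranslocationEvent(chr_a, chr_b, a1, a2, b1, b2, "", ins2)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ReadSimConfig:
    """Targeted-capture paired-end simulation parameters.

    The defaults model the study design this package is built around:
    roughly 30-fold coverage of 2x100 nt Illumina read pairs with a
    350 +/- 35 nt insert, substitution errors only.
    """

    seed: int
    depth: float = 30.0
    read_len: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if self.insert_mean < 2 * self.read_len:
            raise SimulationError("insert_mean must be >= 2 * read_len")
        if not (0 <= self.error_rate < 1):
            raise SimulationError("error_rate must be in [0, 1)")


@dataclass
class SimulatedReads:
    """Paired reads plus per-fragment placement truth.

    ``start1`` is the 0-based start of mate 1 on the source sequence;
    mate 2 is the reverse complement of the fragment end, its leftmost
    source coordinate is ``start1 + frag_len - read_len``.
    """

    names: list[str]
    seq1: list[str]
    seq2: list[str]
    chrom: list[str]
    start1: np.ndarray
    frag_len: np.ndarray
    read_len: int

    @property
    def n_pairs(self) -> int:
        return len(self.names)

    @property
    def start2(self) -> np.ndarray:
        return self.start1 + self.frag_len - self.read_len

    def write_fastq(self, path1, path2) -> None:
        qual = "I" * self.read_len
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for name, s1, s2 in zip(self.names, self.seq1, self.seq2):
                f1.write(f"@{name}/1\n{s1}\n+\n{qual}\n")
                f2.write(f"@{name}/2\n{s2}\n+\n{qual}\n")


def _mutate(reads: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    joined = np.frombuffer("".join(reads).encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    lut[_BASE_BYTES] = np.arange(4)
    codes = lut[joined]
    hit = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    codes[hit] = (codes[hit] + shift) % 4
    out = _BASE_BYTES[codes].tobytes().decode("ascii")
    n = len(reads[0])
    return [out[i * n:(i + 1) * n] for i in range(len(reads))]


def simulate_paired_reads(seqs: ReferenceSet,
                          windows: Sequence[tuple[str, int, int]],
                          cfg: ReadSimConfig) -> SimulatedReads:
    """Simulate capture-window paired-end reads with placement truth.

    Per window, ``round(depth * window_len / (2 * read_len))`` fragments are
    drawn with start uniform in the window and length normal
    (``insert_mean``, ``insert_sd``) truncated to ``[2*read_len, window
    len]``; mate 1 reads the fragment start forward, mate 2 the fragment end
    reverse-complemented.  Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.read_len
    names: list[str] = []
    seq1: list[str] = []
    seq2: list[str] = []
    chroms: list[str] = []
    starts: list[np.ndarray] = []
    flens: list[np.ndarray] = []

    for wi, (chrom, wstart, wend) in enumerate(windows):
        seq = seqs[chrom]
        if not (0 <= wstart < wend <= len(seq)):
            raise SimulationError(f"window {chrom}:{wstart}-{wend} out of bounds")
        wlen = wend - wstart
        if wlen < cfg.insert_mean + 4 * cfg.insert_sd:
            raise SimulationError(
                f"window {chrom}:{wstart}-{wend} shorter than insert_mean + 4*insert_sd")
        n = int(round(cfg.depth * wlen / (2 * L)))
        flen = np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, n)).astype(np.int64)
        flen = np.clip(flen, 2 * L, wlen)
        start = wstart + (rng.random(n) * (wlen - flen + 1)).astype(np.int64)
        m1 = [seq[s:s + L] for s in start]
        m2 = [revcomp(seq[s + f - L:s + f]) for s, f in zip(start, flen)]
        if cfg.error_rate > 0:
            m1 = _mutate(m1, cfg.error_rate, rng)
            m2 = _mutate(m2, cfg.error_rate, rng)
        names.extend(f"{chrom}:{wi}:{i}" for i in range(n))
        seq1.extend(m1)
        seq2.extend(m2)
        chroms.extend([chrom] * n)
        starts.append(start)
        flens.append(flen)

    return SimulatedReads(
        names=names, seq1=seq1, seq2=seq2, chrom=chroms,
        start1=np.concatenate(starts) if starts else np.empty(0, np.int64),
        frag_len=np.concatenate(flens) if flens else np.empty(0, np.int64),
        read_len=L,
    )
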