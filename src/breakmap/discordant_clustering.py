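"""Inter-chromosomal read-pair detection, clustering and candidate calling.

A reciprocal translocation leaves a distinctive trace in paired-end data:
fragments straddling a fusion junction yield pairs whose mates map uniquely
to the two different partner chromosomes.  Grouping those pairs by
single-linkage on both footprints, filtering for repeated support, and
projecting the insert-size model into the unsequenced inner gap yields one
candidate breakpoint-interval pair per junction.  The two junctions of a
reciprocal event appear as two clusters with opposite orientation
consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .read_mapping import AlignmentRecord


class DiscordantError(ValueError):
    pass


@dataclass(frozen=True)
class PairEnd:
    chrom: str
    pos: int        # 0-based leftmost aligned base
    end: int        # 0-based exclusive end
    strand: str


@dataclass(frozen=True)
class DiscordantPair:
    """A unique-unique read pair with mates on different chromosomes.

    Side ``a`` is the lexicographically smaller chromosome, so pairs from
    the same junction always agree on side assignment.
    """

    read_name: str
    end_a: PairEnd
    end_b: PairEnd


def _to_end(r: AlignmentRecord) -> PairEnd:
    return PairEnd(r.chrom, r.pos, r.end, r.strand)


def find_discordant(alignments: Iterable[AlignmentRecord]) -> list[DiscordantPair]:
    """Extract unique-unique inter-chromosomal pairs from an alignment stream."""
    by_name: dict[str, list[AlignmentRecord]] = {}
    for r in alignments:
        by_name.setdefault(r.read_name, []).append(r)
    pairs = []
    for name, recs in by_name.items():
        if len(recs) != 2:
            raise DiscordantError(f"read {name!r} has {len(recs)} records; "
                                  "paired stream required")
        r1, r2 = recs
        if not (r1.mapped and r2.mapped and r1.unique and r2.unique):
            continue
        if r1.chrom == r2.chrom:
            continue
        if r1.chrom > r2.chrom:
            r1, r2 = r2, r1
        pairs.append(DiscordantPair(name, _to_end(r1), _to_end(r2)))
    return pairs


@dataclass
class DiscordantCluster:
    pairs: list[DiscordantPair]

    @property
    def support(self) -> int:
        return len(self.pairs)

    @property
    def chrom_a(self) -> str:
        return self.pairs[0].end_a.chrom

    @property
    def chrom_b(self) -> str:
        return self.pairs[0].end_b.chrom

    @property
    def orientation(self) -> tuple[str, str]:
        return self.pairs[0].end_a.strand, self.pairs[0].end_b.strand

    @property
    def footprint_a(self) -> tuple[int, int]:
        return (min(p.end_a.pos for p in self.pairs),
                max(p.end_a.end for p in self.pairs))

    @property
    def footprint_b(self) -> tuple[int, int]:
        return (min(p.end_b.pos for p in self.pairs),
                max(p.end_b.end for p in self.pairs))


def cluster(pairs: Sequence[DiscordantPair], max_gap: float) -> list[DiscordantCluster]:
    """Single-linkage clustering of discordant pairs.

    Two pairs join iff they share the chromosome pair and orientation
    consensus and both their A-ends and B-ends lie within ``max_gap``.
    Output is sorted by support descending, then (chrom_a, footprint start).
    """
    if max_gap <= 0:
        raise DiscordantError("max_gap must be positive")
    groups: dict[tuple, list[DiscordantPair]] = {}
    for p in pairs:
        key = (p.end_a.chrom, p.end_b.chrom, p.end_a.strand, p.end_b.strand)
        groups.setdefault(key, []).append(p)

    clusters: list[DiscordantCluster] = []
    for members in groups.values():
        members = sorted(members, key=lambda p: p.end_a.pos)
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[j].end_a.pos - members[i].end_a.pos > max_gap:
                    break
                if abs(members[j].end_b.pos - members[i].end_b.pos) <= max_gap:
                    parent[find(i)] = find(j)
        comp: dict[int, list[DiscordantPair]] = {}
        for i, p in enumerate(members):
            comp.setdefault(find(i), []).append(p)
        clusters.extend(DiscordantCluster(ps) for ps in comp.values())

    clusters.sort(key=lambda c: (-c.support, c.chrom_a, c.footprint_a[0]))
    return clusters


@dataclass(frozen=True)
class BreakpointCandidate:
    """A pair of breakpoint intervals implied by one discordant cluster.

    Intervals are 0-based half-open and are built from the insert-size
    model: on a ``+`` side the breakpoint lies in the unsequenced gap to
    the right of the innermost read end, on a ``-`` side to the left of the
    innermost read start.  The interval is padded by the mismatch allowance
    because a read may legally overhang the junction by up to that many
    tolerated mismatching bases.
    """

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    support: int
    strand_a: str
    strand_b: str
    name: str = "candidate"

    def interval(self, side: str) -> tuple[str, int, int]:
        if side == "a":
            return (self.chrom_a, self.start_a, self.end_a)
        return (self.chrom_b, self.start_b, self.end_b)


def _side_interval(footprint: tuple[int, int], strand: str, slack: int,
                   margin: int) -> tuple[int, int]:
    lo, hi = footprint
    if strand == "+":
        return max(0, hi - margin), hi + slack
    return max(0, lo - slack), lo + margin


def call_candidates(clusters: Sequence[DiscordantCluster],
                    insert_mean: float, insert_sd: float, read_len: int,
                    min_support: int = 3,
                    mismatch_margin: int = 3) -> list[BreakpointCandidate]:
    """Convert repeatedly supported clusters into breakpoint interval pairs."""
    if min_support < 1:
        raise DiscordantError("min_support must be >= 1")
    slack = int(round(insert_mean - 2 * read_len + 4 * insert_sd))
    out = []
    for i, c in enumerate(c for c in clusters if c.support >= min_support):
        sa, sb = c.orientation
        a_lo, a_hi = _side_interval(c.footprint_a, sa, slack, mismatch_margin)
        b_lo, b_hi = _side_interval(c.footprint_b, sb, slack, mismatch_margin)
        out.append(BreakpointCandidate(
            chrom_a=c.chrom_a, start_a=a_lo, end_a=a_hi,
            chrom_b=c.chrom_b, start_b=b_lo, end_b=b_hi,
            support=c.support, strand_a=sa, strand_b=sb,
            name=f"candidate{i + 1}",
        ))
    return out


def bedpe_text(candidates: Sequence[BreakpointCandidate]) -> str:
    """BEDPE serialization (0-based half-open, score = supporting pairs)."""
    lines = []
    for c in candidates:
        lines.append("\t".join(map(str, (
            c.chrom_a, c.start_a, c.end_a, c.chrom_b, c.start_b, c.end_b,
            c.name, c.support, c.strand_a, c.strand_b))))
    return "\n".join(lines) + ("\n" if lines else "")


def write_bedpe(candidates: Sequence[BreakpointCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(bedpe_text(candidates))
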