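"""End-to-end breakpoint discovery: simulate/map/cluster/assemble/characterize.

Ties the modules together the way the original breakpoint hunt proceeded:
targeted-capture paired-end reads are mapped to the wild-type references,
inter-chromosomal unique-unique pairs are clustered into two reciprocal
candidates, junction-spanning (unmapped) reads near each candidate are
assembled into a consensus, and each consensus is characterized against
both references to a canonical junction call.  The derivative carrying the
prefix of the lexicographically smaller chromosome is labelled ``derAB``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import discordant_clustering as dc
from . import junction_caller as jc
from . import read_mapping as rm
from . import synthetic_genome as sg


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the discovery pipeline, defaulting to the study design."""

    k: int = 31
    max_mismatch: int = 3
    min_support: int = 3
    overlap_min: int = 20
    match_floor: int = 30
    depth: float = 30.0
    read_len: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 35.0

    @property
    def max_gap(self) -> float:
        return self.insert_mean + 3 * self.insert_sd

    @property
    def search_margin(self) -> int:
        return int(2 * self.insert_mean)


@dataclass
class DiscoveryResult:
    candidates: list[dc.BreakpointCandidate]
    calls: list[jc.JunctionCall]
    summary: jc.ReciprocalSummary | None
    errors: list[str] = field(default_factory=list)
    consensi: list[jc.JunctionConsensus] = field(default_factory=list)


def discover_junctions(ref: sg.ReferenceSet,
                       alignments: list[rm.AlignmentRecord],
                       cfg: PipelineConfig = PipelineConfig(),
                       derivatives: sg.ReferenceSet | None = None
                       ) -> DiscoveryResult:
    """Run clustering + junction calling over an alignment stream."""
    pairs = dc.find_discordant(alignments)
    clusters = dc.cluster(pairs, cfg.max_gap)
    candidates = dc.call_candidates(
        clusters, cfg.insert_mean, cfg.insert_sd, cfg.read_len,
        min_support=cfg.min_support, mismatch_margin=cfg.max_mismatch)

    calls: list[jc.JunctionCall] = []
    consensi: list[jc.JunctionConsensus] = []
    errors: list[str] = []
    for cand in candidates:
        # the '+' side is upstream of the junction and forms the prefix
        if cand.strand_a == "+":
            left, right = ("a", "b")
        else:
            left, right = ("b", "a")
        lchrom, llo, lhi = cand.interval(left)
        rchrom, rlo, rhi = cand.interval(right)
        der_id = jc_derivative_id(lchrom, rchrom)
        try:
            reads = jc.collect_junction_reads(alignments, cand,
                                              margin=cfg.search_margin)
            consensus = jc.assemble_junction(reads, cfg.overlap_min, der_id)
            consensi.append(consensus)
            call = jc.characterize(
                consensus.sequence,
                (lchrom, ref[lchrom]), (rchrom, ref[rchrom]),
                (llo - cfg.search_margin, lhi + cfg.search_margin),
                (rlo - cfg.search_margin, rhi + cfg.search_margin),
                derivative_id=der_id, match_floor=cfg.match_floor,
                supporting_reads=consensus.supporting_reads)
            calls.append(call)
        except (jc.AssemblyError, jc.CharacterizeError) as exc:
            errors.append(f"{der_id}: {exc}")

    summary = None
    ab = [c for c in calls if c.derivative_id == sg.DER_AB]
    ba = [c for c in calls if c.derivative_id == sg.DER_BA]
    if len(ab) == 1 and len(ba) == 1:
        try:
            summary = jc.summarize_reciprocal(ab[0], ba[0], ref, derivatives)
        except ValueError as exc:
            errors.append(str(exc))
    return DiscoveryResult(candidates, calls, summary, errors, consensi)


def jc_derivative_id(left_chrom: str, right_chrom: str) -> str:
    """derAB when the prefix comes from the lexicographically smaller name."""
    return sg.DER_AB if left_chrom < right_chrom else sg.DER_BA


@dataclass
class SimulatedCase:
    ref: sg.ReferenceSet
    derivatives: sg.ReferenceSet
    truth: sg.TruthRecord
    result: DiscoveryResult
    wt_candidates: list[dc.BreakpointCandidate]


def default_event_params(rng: np.random.Generator) -> dict[str, int]:
    """Random NHEJ-style junction anatomy for simulation studies.

    Deletions up to 10 bp per chromosome; each junction independently
    blunt, microhomologous (1-4 nt) or carrying a short templated
    duplication (1-3 nt).
    """
    params = {"del_a": int(rng.integers(0, 11)), "del_b": int(rng.integers(0, 11))}
    for jxn, (mh_key, dup_key) in ((1, ("mh1", "dup1")), (2, ("mh2", "dup2"))):
        kind = rng.integers(0, 3)
        params[mh_key] = int(rng.integers(1, 5)) if kind == 1 else 0
        params[dup_key] = int(rng.integers(1, 4)) if kind == 2 else 0
    return params


def simulate_case(seed: int,
                  chrom_len: int = 1_000_000,
                  window: int = 100_000,
                  cfg: PipelineConfig = PipelineConfig(),
                  event_params: dict[str, int] | None = None,
                  with_wt_run: bool = True,
                  chrom_names: tuple[str, str] = ("chr5", "chr8")) -> SimulatedCase:
    """One full simulated discovery run plus a matched wild-type control.

    Two random chromosomes are rearranged by a seeded reciprocal
    translocation; capture windows of ``window`` nt are centred on each
    derivative junction (and, for the control, on the corresponding
    wild-type positions).  Both samples are mapped against the same
    wild-type index; the control must produce no candidates.
    """
    rng = np.random.default_rng(seed)
    name_a, name_b = sorted(chrom_names)
    base = sg.make_reference([
        (name_a, chrom_len, int(rng.integers(2 ** 31))),
        (name_b, chrom_len, int(rng.integers(2 ** 31))),
    ])
    if event_params is None:
        event_params = default_event_params(rng)
    ref, event = sg.random_event(base, name_a, name_b, rng, **event_params)

    half = window // 2
    windows_mut = [
        (sg.DER_AB, event.a1 - half, event.a1 + half),
        (sg.DER_BA, event.b2 - half, event.b2 + half),
    ]
    derivatives, truth = sg.apply_translocation(
        ref, event, seed=seed, capture_windows=windows_mut)

    sim_cfg = sg.ReadSimConfig(seed=int(rng.integers(2 ** 31)),
                               depth=cfg.depth, read_len=cfg.read_len,
                               insert_mean=cfg.insert_mean,
                               insert_sd=cfg.insert_sd)
    reads_mut = sg.simulate_paired_reads(derivatives, windows_mut, sim_cfg)

    index = rm.build_index(ref, cfg.k)
    aln_mut = rm.map_pairs(reads_mut, index, cfg.max_mismatch,
                           cfg.insert_mean, cfg.insert_sd)
    result = discover_junctions(ref, aln_mut, cfg, derivatives)

    wt_candidates: list[dc.BreakpointCandidate] = []
    if with_wt_run:
        windows_wt = [
            (event.chr_a, event.a1 - half, event.a1 + half),
            (event.chr_b, event.b2 - half, event.b2 + half),
        ]
        wt_cfg = sg.ReadSimConfig(seed=int(rng.integers(2 ** 31)),
                                  depth=cfg.depth, read_len=cfg.read_len,
                                  insert_mean=cfg.insert_mean,
                                  insert_sd=cfg.insert_sd)
        reads_wt = sg.simulate_paired_reads(ref, windows_wt, wt_cfg)
        aln_wt = rm.map_pairs(reads_wt, index, cfg.max_mismatch,
                              cfg.insert_mean, cfg.insert_sd)
        wt_pairs = dc.find_discordant(aln_wt)
        wt_clusters = dc.cluster(wt_pairs, cfg.max_gap)
        wt_candidates = dc.call_candidates(
            wt_clusters, cfg.insert_mean, cfg.insert_sd, cfg.read_len,
            min_support=cfg.min_support, mismatch_margin=cfg.max_mismatch)

    return SimulatedCase(ref, derivatives, truth, result, wt_candidates)


def matches_truth(case: SimulatedCase) -> bool:
    """Exact canonical-form recovery of both junctions and the summary."""
    truth, res = case.truth, case.result
    if res.summary is None or len(res.calls) != 2:
        return False
    by_id = {c.derivative_id: c for c in res.calls}
    ab, ba = by_id.get(sg.DER_AB), by_id.get(sg.DER_BA)
    if ab is None or ba is None:
        return False
    return (
        ab.left_chrom == truth.chr_a and ab.right_chrom == truth.chr_b
        and ab.left_pos == truth.a1            # 1-based last base == 0-based excl end
        and ab.right_pos == truth.b1 + 1
        and ab.mh_len == truth.mh_len1 and ab.ins_seq == truth.ins1
        and ba.left_chrom == truth.chr_b and ba.right_chrom == truth.chr_a
        and ba.left_pos == truth.b2
        and ba.right_pos == truth.a2 + 1
        and ba.mh_len == truth.mh_len2 and ba.ins_seq == truth.ins2
        and res.summary.del_a == truth.del_a
        and res.summary.del_b == truth.del_b
        and res.summary.dup_total == truth.dup_total
    )
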