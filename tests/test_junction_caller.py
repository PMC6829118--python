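"""Junction assembly, characterization, reciprocal summary and BND output."""

import numpy as np
import pytest

from breakmap import junction_caller as jc
from breakmap import synthetic_genome as sg
from breakmap.pipeline import PipelineConfig

from conftest import dna
from oracle_utils import random_split_case, split_enumeration


class TestAssembleJunction:
    def test_two_read_exact_merge(self):
        rng = np.random.default_rng(0)
        truth = dna(rng, 160)
        r1, r2 = truth[:100], truth[60:160]  # 40 nt overlap
        cons = jc.assemble_junction([r1, r2])
        assert cons.sequence == truth
        assert cons.supporting_reads == 2

    def test_many_reads_tile_region(self):
        rng = np.random.default_rng(1)
        truth = dna(rng, 300)
        reads = [truth[i:i + 100] for i in range(0, 201, 10)]
        rng.shuffle(reads)
        cons = jc.assemble_junction(reads)
        assert cons.sequence == truth

    def test_single_read_errors(self):
        with pytest.raises(jc.AssemblyError, match="junction-spanning"):
            jc.assemble_junction(["ACGT" * 30])

    def test_disjoint_sides_error(self):
        rng = np.random.default_rng(2)
        with pytest.raises(jc.AssemblyError, match="no overlap"):
            jc.assemble_junction([dna(rng, 100), dna(rng, 100)])

    def test_overlap_below_floor_not_used(self):
        rng = np.random.default_rng(3)
        truth = dna(rng, 190)
        with pytest.raises(jc.AssemblyError):
            jc.assemble_junction([truth[:100], truth[90:]], overlap_min=20)
        # same pair passes once the floor admits the 10 nt overlap
        assert jc.assemble_junction([truth[:100], truth[90:]],
                                    overlap_min=10).sequence == truth

    def test_mismatch_tolerant_mode(self):
        rng = np.random.default_rng(4)
        truth = dna(rng, 160)
        r1 = truth[:100]
        r2 = list(truth[60:160])
        r2[10] = "ACGT"[("ACGT".index(r2[10]) + 1) % 4]  # error inside the overlap
        r2 = "".join(r2)
        with pytest.raises(jc.AssemblyError):
            jc.assemble_junction([r1, r2])
        cons = jc.assemble_junction([r1, r2], overlap_mismatch=1)
        assert cons.sequence == truth  # left fragment's base wins

    def test_calls_consistent_with_derivative_sequence(self, small_case):
        ders = small_case.derivatives
        for call in small_case.result.calls:
            der_seq = ders[call.derivative_id]
            # reconstruct what the pipeline characterized: the canonical
            # junction neighbourhood must exist verbatim in the derivative
            left = small_case.ref[call.left_chrom]
            right = small_case.ref[call.right_chrom]
            neighborhood = (left[call.left_pos - 50:call.left_pos]
                            + call.ins_seq
                            + right[call.right_pos - 1:call.right_pos + 49])
            assert neighborhood in der_seq


class TestCharacterize:
    def _regions(self, seq):
        return (0, len(seq))

    def test_blunt_junction(self):
        rng = np.random.default_rng(10)
        left, right = dna(rng, 5000), dna(rng, 5000)
        cons, left2, right2 = None, left, right
        # force no flanking homology at the chosen cuts
        x0, y0 = 2000, 3000
        if left[x0] == right[y0]:
            right = right[:y0] + ("A" if left[x0] != "A" else "C") + right[y0 + 1:]
        if left[x0 - 1] == right[y0 - 1]:
            right = right[:y0 - 1] + ("G" if left[x0 - 1] != "G" else "T") + right[y0:]
        cons = left[x0 - 80:x0] + right[y0:y0 + 80]
        call = jc.characterize(cons, ("cA", left), ("cB", right),
                               self._regions(left), self._regions(right))
        assert call.signature == jc.BLUNT
        assert call.mh_len == 0 and call.ins_seq == ""
        assert call.left_pos == x0          # 1-based last base == 0-based cut
        assert call.right_pos == y0 + 1

    def test_gct_microhomology(self):
        # a single shared GCT triplet at the fusion: mh 3, signature
        # microhomology, breakpoint attributed to the left side
        rng = np.random.default_rng(11)
        left, right = dna(rng, 4000), dna(rng, 4000)
        x0, y0 = 1500, 2500
        left = left[:x0 - 3] + "GCT" + left[x0:]
        right = right[:y0 - 3] + "GCT" + right[y0:]
        if left[x0] == right[y0]:
            right = right[:y0] + ("A" if left[x0] != "A" else "C") + right[y0 + 1:]
        if left[x0 - 4] == right[y0 - 4]:
            right = (right[:y0 - 4] + ("G" if left[x0 - 4] != "G" else "T")
                     + right[y0 - 3:])
        cons = left[x0 - 90:x0] + right[y0:y0 + 90]
        call = jc.characterize(cons, ("cA", left), ("cB", right),
                               self._regions(left), self._regions(right))
        assert call.signature == jc.MICROHOMOLOGY
        assert call.mh_len == 3 and call.mh_seq == "GCT"
        assert call.ins_seq == ""
        assert call.left_pos == x0 and call.right_pos == y0 + 1

    def test_templated_duplication_flagged(self):
        rng = np.random.default_rng(12)
        left, right = dna(rng, 4000), dna(rng, 4000)
        x0, y0 = 1800, 2100
        ins = left[x0 - 2:x0]  # copies the two bases left of the break
        if right[y0] == ins[0]:
            right = right[:y0] + ("A" if ins[0] != "A" else "C") + right[y0 + 1:]
        if left[x0] == ins[0]:
            left = left[:x0] + ("A" if ins[0] != "A" else "C") + left[x0 + 1:]
        cons = left[x0 - 80:x0] + ins + right[y0:y0 + 80]
        call = jc.characterize(cons, ("cA", left), ("cB", right),
                               self._regions(left), self._regions(right))
        assert call.ins_seq == ins and call.ins_templated
        assert call.signature == jc.TEMPLATED_DUP

    def test_matches_split_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            cons, left, right = random_split_case(rng)
            p, s, mh, ins = split_enumeration(cons, left, right)
            call = jc.characterize(cons, ("cA", left), ("cB", right),
                                   (0, len(left)), (0, len(right)))
            assert call.mh_len == mh
            assert call.ins_seq == ins
            # the canonical decomposition must reproduce the consensus
            rebuilt = (left[:call.left_pos] + call.ins_seq
                       + right[call.right_pos - 1:])
            assert cons in rebuilt

    def test_unanchored_consensus_errors(self):
        rng = np.random.default_rng(14)
        left, right = dna(rng, 3000), dna(rng, 3000)
        with pytest.raises(jc.CharacterizeError):
            jc.characterize(dna(rng, 200), ("cA", left), ("cB", right),
                            (0, 3000), (0, 3000))


class TestSummarize:
    def test_full_pipeline_recovers_reported_deletions(self):
        # 6 bp from chromosome A, 8 bp from chromosome B, plus a short
        # duplication: the exemplar anatomy survives the whole pipeline
        from breakmap import pipeline as pl, read_mapping as rm
        rng = np.random.default_rng(21)
        base = sg.make_reference([("chr5", 300_000, 31), ("chr8", 300_000, 32)])
        ref, ev = sg.exemplar_event(base, "chr5", "chr8", rng)
        half = 15_000
        wins = [(sg.DER_AB, ev.a1 - half, ev.a1 + half),
                (sg.DER_BA, ev.b2 - half, ev.b2 + half)]
        ders, truth = sg.apply_translocation(ref, ev, capture_windows=wins)
        reads = sg.simulate_paired_reads(ders, wins, sg.ReadSimConfig(seed=33))
        aln = rm.map_pairs(reads, rm.build_index(ref))
        res = pl.discover_junctions(ref, aln, derivatives=ders)
        assert res.summary is not None
        assert (res.summary.del_a, res.summary.del_b) == (6, 8)
        assert res.summary.dup_total == len(truth.ins2)
        by_id = {c.derivative_id: c for c in res.calls}
        assert by_id[sg.DER_AB].mh_seq == "GCT"
        assert by_id[sg.DER_BA].ins_templated

    def test_blunt_event_zero_totals(self):
        rng = np.random.default_rng(22)
        ref = sg.make_reference([("cA", 20_000, 1), ("cB", 20_000, 2)])
        a1, b2 = 9000, 11000
        call_ab = jc.JunctionCall(sg.DER_AB, "cA", a1, "cB", b2 + 1,
                                  0, "", "", False, jc.BLUNT)
        call_ba = jc.JunctionCall(sg.DER_BA, "cB", b2, "cA", a1 + 1,
                                  0, "", "", False, jc.BLUNT)
        s = jc.summarize_reciprocal(call_ab, call_ba, ref)
        assert (s.del_a, s.del_b, s.dup_total) == (0, 0, 0)

    def test_mismatched_chrom_pairs_rejected(self):
        call_ab = jc.JunctionCall(sg.DER_AB, "cA", 10, "cB", 11, 0, "", "",
                                  False, jc.BLUNT)
        call_xy = jc.JunctionCall(sg.DER_BA, "cX", 10, "cA", 11, 0, "", "",
                                  False, jc.BLUNT)
        with pytest.raises(ValueError):
            jc.summarize_reciprocal(call_ab, call_xy, None)

    def test_length_identity_holds_end_to_end(self, small_case):
        res = small_case.result
        assert res.summary is not None
        ref, ders = small_case.ref, small_case.derivatives
        lhs = sum(len(s) for _, s in ders.items())
        rhs = (ref.length(res.summary.chrom_a) + ref.length(res.summary.chrom_b)
               - res.summary.del_a - res.summary.del_b + res.summary.dup_total)
        assert lhs == rhs


class TestBndVcf:
    def _calls(self, small_case):
        return small_case.result.calls

    def test_two_records_per_junction_cross_referenced(self, small_case, tmp_path):
        import pysam
        calls = self._calls(small_case)
        path = tmp_path / "calls.vcf"
        jc.write_bnd_vcf(calls, small_case.ref, path)
        with pysam.VariantFile(str(path)) as vcf:
            recs = list(vcf)
        assert len(recs) == 2 * len(calls)
        by_id = {r.id: r for r in recs}
        for r in recs:
            mate = by_id[r.info["MATEID"]]
            assert mate.info["MATEID"] == r.id

    def test_roundtrip_positions_and_homology(self, small_case, tmp_path):
        import pysam
        calls = self._calls(small_case)
        path = tmp_path / "calls.vcf"
        jc.write_bnd_vcf(calls, small_case.ref, path)
        with pysam.VariantFile(str(path)) as vcf:
            recs = {r.id: r for r in vcf}
        for call in calls:
            a = recs[f"bnd_{call.derivative_id}_a"]
            b = recs[f"bnd_{call.derivative_id}_b"]
            assert (a.chrom, a.pos) == (call.left_chrom, call.left_pos)
            assert (b.chrom, b.pos) == (call.right_chrom, call.right_pos)
            assert f"[{call.right_chrom}:{call.right_pos}[" in a.alts[0]
            assert f"]{call.left_chrom}:{call.left_pos}]" in b.alts[0]
            if call.mh_len > 0:
                assert a.info["HOMLEN"] == call.mh_len
                assert a.info["HOMSEQ"] == call.mh_seq
            else:
                assert "HOMLEN" not in a.info
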