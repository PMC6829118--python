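"""Reference generation, translocation application and read simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from breakmap import synthetic_genome as sg

from conftest import dna


class TestMakeReference:
    def test_length_and_determinism(self):
        ref1 = sg.make_reference([("c5", 100_000, 7)])
        ref2 = sg.make_reference([("c5", 100_000, 7)])
        assert ref1.length("c5") == 100_000
        assert ref1["c5"] == ref2["c5"]

    def test_gc_fraction_binomial(self):
        # central 99.9% binomial interval around p=0.5, computed independently
        n = 100_000
        seq = sg.make_reference([("c5", n, 7)])["c5"]
        gc = seq.count("G") + seq.count("C")
        lo, hi = stats.binom.interval(0.999, n, 0.5)
        assert lo <= gc <= hi

    def test_alphabet_strict(self):
        seq = sg.make_reference([("x", 5000, 1)])["x"]
        assert set(seq) <= set("ACGT")

    def test_duplicate_names_rejected(self):
        with pytest.raises(sg.ReferenceError):
            sg.make_reference([("a", 1000, 1), ("a", 1000, 2)])

    def test_nonpositive_length_rejected(self):
        with pytest.raises(sg.ReferenceError):
            sg.make_reference([("a", 0, 1)])


class TestApplyTranslocation:
    def _ref(self, seed=3, n=20_000):
        return sg.make_reference([("cA", n, seed), ("cB", n, seed + 1)])

    def test_no_edit_conserves_length(self):
        ref = self._ref()
        ev = sg.TranslocationEvent("cA", "cB", 9000, 9000, 11000, 11000)
        ders, _ = sg.apply_translocation(ref, ev)
        assert (len(ders[sg.DER_AB]) + len(ders[sg.DER_BA])
                == ref.length("cA") + ref.length("cB"))

    def test_derivative_structure(self):
        ref = self._ref()
        ev = sg.TranslocationEvent("cA", "cB", 9000, 9006, 11008, 11000, "", "TT")
        ders, _ = sg.apply_translocation(ref, ev)
        assert ders[sg.DER_AB] == ref["cA"][:9000] + ref["cB"][11008:]
        assert ders[sg.DER_BA] == ref["cB"][:11000] + "TT" + ref["cA"][9006:]

    def test_length_accounting_identity(self):
        # base-accounting oracle: every reference base lands in exactly one of
        # {der1, der2, deleted}, so lengths satisfy the identity for any event
        rng = np.random.default_rng(0)
        ref = self._ref()
        for _ in range(20):
            a1 = int(rng.integers(5000, 15000))
            b2 = int(rng.integers(5000, 15000))
            ev = sg.TranslocationEvent(
                "cA", "cB", a1, a1 + int(rng.integers(0, 11)),
                b2 + int(rng.integers(0, 11)), b2,
                dna(rng, int(rng.integers(0, 4))), dna(rng, int(rng.integers(0, 4))))
            ders, _ = sg.apply_translocation(ref, ev)
            expect = (ref.length("cA") + ref.length("cB")
                      - ev.del_a - ev.del_b + len(ev.ins1) + len(ev.ins2))
            assert len(ders[sg.DER_AB]) + len(ders[sg.DER_BA]) == expect

    def test_reported_junction_anatomy(self):
        # deletions of 6 and 8 bp, a GCT microhomology triplet and a short
        # templated duplication: the truth record reports these exact values
        rng = np.random.default_rng(5)
        ref, ev = sg.exemplar_event(self._ref(), "cA", "cB", rng)
        _, truth = sg.apply_translocation(ref, ev)
        assert (truth.del_a, truth.del_b) == (6, 8)
        assert truth.mh_len1 == 3 and truth.mh_seq1 == "GCT"
        assert truth.mh_len2 == 0 and 1 <= len(truth.ins2) <= 3

    def test_out_of_range_rejected(self):
        ref = self._ref()
        with pytest.raises(sg.EventError):
            sg.apply_translocation(
                ref, sg.TranslocationEvent("cA", "cB", 9000, 99_000, 11000, 11000))
        with pytest.raises(sg.EventError):
            sg.TranslocationEvent("cA", "cB", 9000, 8000, 11000, 11000)

    def test_truth_json_roundtrip(self, small_case):
        truth = small_case.truth
        again = sg.TruthRecord.from_json(truth.to_json())
        assert again == truth


class TestCanonicalJunction:
    def test_backward_microhomology_attributed_to_prefix(self):
        # shared GCT left of both cuts: mh reported, coordinates unshifted
        left = "AAAACCCCGCT"
        right = "TTGCT" + "ACCA"
        canon = sg.canonical_junction(left, 11, right, 5, "")
        assert canon.mh_len == 3 and canon.mh_seq == "GCT"
        assert canon.left_end0 == 11 and canon.right_start0 == 5
        assert canon.ins_seq == ""

    def test_forward_homology_shifts_right(self):
        left = "AACCTTGG" + "CA"          # cut at 8; left continues CA
        right = "GGGG" + "CAGT"           # cut at 4; right starts CA -> f=2
        canon = sg.canonical_junction(left, 8, right, 4, "")
        # forward extension CA (2) plus backward GG (2): 4 nt of homology,
        # all attributed to the left side
        assert canon.mh_len == 4 and canon.mh_seq == "GGCA"
        assert canon.left_end0 == 10 and canon.right_start0 == 6

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_reconstruction_identity(self, data):
        # canonical decomposition always rebuilds the literal derivative,
        # and microhomology excludes insertion
        base = st.text(alphabet="ACGT", min_size=12, max_size=40)
        left = data.draw(base)
        right = data.draw(base)
        cut_l = data.draw(st.integers(6, len(left)))
        cut_r = data.draw(st.integers(0, len(right) - 6))
        ins = data.draw(st.text(alphabet="ACGT", max_size=4))
        canon = sg.canonical_junction(left, cut_l, right, cut_r, ins)
        rebuilt = left[:canon.left_end0] + canon.ins_seq + right[canon.right_start0:]
        assert rebuilt == left[:cut_l] + ins + right[cut_r:]
        assert not (canon.mh_len > 0 and canon.ins_seq)
        assert len(canon.mh_seq) == canon.mh_len


class TestReadSimulation:
    def _setup(self, seed=5):
        ref = sg.make_reference([("c", 110_000, seed)])
        cfg = sg.ReadSimConfig(seed=seed)
        return ref, cfg

    def test_pair_count_formula(self):
        # depth * W / (2L): 30 * 100000 / 200 = 15000
        ref, cfg = self._setup()
        reads = sg.simulate_paired_reads(ref, [("c", 0, 100_000)], cfg)
        assert reads.n_pairs == 15_000
        assert cfg.depth == 30  # study-design default coverage

    def test_error_free_reads_are_exact_substrings(self):
        ref, cfg = self._setup()
        seq = ref["c"]
        reads = sg.simulate_paired_reads(ref, [("c", 2000, 12_000)], cfg)
        L = cfg.read_len
        for i in range(reads.n_pairs):
            s1 = int(reads.start1[i])
            s2 = int(reads.start2[i])
            assert reads.seq1[i] == seq[s1:s1 + L]
            assert reads.seq2[i] == sg.revcomp(seq[s2:s2 + L])

    def test_bit_reproducible(self):
        ref, _ = self._setup()
        r1 = sg.simulate_paired_reads(ref, [("c", 0, 10_000)], sg.ReadSimConfig(seed=42))
        r2 = sg.simulate_paired_reads(ref, [("c", 0, 10_000)], sg.ReadSimConfig(seed=42))
        assert r1.seq1 == r2.seq1 and r1.seq2 == r2.seq2
        assert np.array_equal(r1.start1, r2.start1)

    def test_window_too_short_rejected(self):
        ref, cfg = self._setup()
        with pytest.raises(sg.SimulationError):
            sg.simulate_paired_reads(ref, [("c", 0, 400)], cfg)

    def test_config_validation(self):
        with pytest.raises(sg.SimulationError):
            sg.ReadSimConfig(seed=None)
        with pytest.raises(sg.SimulationError):
            sg.ReadSimConfig(seed=1, insert_mean=150.0)
        with pytest.raises(sg.SimulationError):
            sg.ReadSimConfig(seed=1, error_rate=1.5)

    def test_error_rate_substitutions_only(self):
        ref, _ = self._setup()
        cfg = sg.ReadSimConfig(seed=8, error_rate=0.05)
        reads = sg.simulate_paired_reads(ref, [("c", 0, 5000)], cfg)
        seq = ref["c"]
        L = cfg.read_len
        n_mm = sum(
            sum(a != b for a, b in zip(reads.seq1[i], seq[int(reads.start1[i]):int(reads.start1[i]) + L]))
            for i in range(reads.n_pairs))
        total = reads.n_pairs * L
        lo, hi = stats.binom.interval(0.999, total, 0.05)  # every hit changes the base
        assert lo <= n_mm <= hi

    def test_fastq_output(self, tmp_path):
        ref, cfg = self._setup()
        reads = sg.simulate_paired_reads(ref, [("c", 0, 2000)], cfg)
        p1, p2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        reads.write_fastq(p1, p2)
        lines = p1.read_text().splitlines()
        assert len(lines) == 4 * reads.n_pairs
        assert lines[0].startswith("@") and lines[0].endswith("/1")
        assert set(lines[3]) == {"I"}
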