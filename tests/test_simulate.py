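"""Synthetic-read generation, read allocation, pileup construction, scoring."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyase.formats import TranscriptRecord, read_mpileup
from polyase.simulate import (
    allocate_reads,
    build_strain_reference,
    evaluate_recovery,
    fragment_reads,
    generate_fragments,
    placements_to_pileup,
    simulate_experiment,
    write_fastq,
)


class TestBuildStrainReference:
    def test_substitution(self):
        rec = build_strain_reference(TranscriptRecord("t", "ACGT"), [(2, "T")])
        assert rec.sequence == "ATGT"

    def test_no_variants_identity(self):
        rec = build_strain_reference(TranscriptRecord("t", "ACGT"), [])
        assert rec.sequence == "ACGT"

    def test_two_variants_order_independent(self):
        base = TranscriptRecord("t", "ACGTACGT")
        a = build_strain_reference(base, [(1, "G"), (5, "T")]).sequence
        b = build_strain_reference(base, [(5, "T"), (1, "G")]).sequence
        assert a == b == "GCGTTCGT"

    def test_reference_equal_substitution_warns(self):
        with pytest.warns(UserWarning, match="discriminate"):
            build_strain_reference(TranscriptRecord("t", "ACGT"), [(1, "A")])

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            build_strain_reference(TranscriptRecord("t", "ACGT"), [(5, "A")])


class TestAllocateReads:
    def test_worked_allocation(self):
        # Fractions 10/60, 20/60, 30/60 of 500 fragments: exact quotas
        # 83.3/166.7/250, largest remainder closes the total.
        assert allocate_reads(500, [10, 20, 30]) == [83, 167, 250]

    def test_zero_total(self):
        assert allocate_reads(0, [10, 20, 30]) == [0, 0, 0]

    def test_single_expressed_allele(self):
        assert allocate_reads(7, [1, 0, 0]) == [7, 0, 0]

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            allocate_reads(5, [0, 0, 0])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.integers(0, 10_000),
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=6).filter(
            lambda w: sum(w) > 0
        ),
    )
    def test_totals_conserved_exactly(self, total, weights):
        counts = allocate_reads(total, weights)
        assert sum(counts) == total
        assert all(c >= 0 for c in counts)


class TestGenerateFragments:
    def test_fragment_equal_to_transcript_has_single_start(self):
        rec = TranscriptRecord("t", "A" * 250)
        rng = np.random.default_rng(0)
        placements = generate_fragments(rec, 20, "s", rng)
        assert {p.start for p in placements} == {1}

    def test_fragment_covers_two_reads_with_inner_gap(self):
        rec = TranscriptRecord("t", "A" * 500)
        p = generate_fragments(rec, 1, "s", np.random.default_rng(1))[0]
        intervals = p.covered_intervals()
        covered = sum(last - first + 1 for first, last, _ in intervals)
        assert covered == 200
        (f1, l1, fwd1), (f2, l2, fwd2) = intervals
        assert fwd1 and not fwd2
        assert f2 - l1 - 1 == 50  # inner gap

    def test_coverage_mass_is_200_per_fragment(self, tmp_path):
        rec = TranscriptRecord("t", "".join("ACGT" * 125))
        rng = np.random.default_rng(2)
        n = 37
        placements = generate_fragments(rec, n, "s", rng)
        path = tmp_path / "sim.mpileup"
        placements_to_pileup(placements, [rec], {"s": {"t": rec.sequence}}, path)
        total_depth = sum(col.depth for col in read_mpileup(path))
        assert total_depth == 200 * n

    def test_short_transcript_falls_back_to_single_reads(self):
        rec = TranscriptRecord("t", "ACGT" * 30)  # length 120 < 250
        placements = generate_fragments(rec, 5, "s", np.random.default_rng(3))
        assert all(not p.paired and p.read_length == 100 for p in placements)

    def test_reads_are_exact_substrings(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        rec = TranscriptRecord("t", seq)
        p = generate_fragments(rec, 1, "s", rng)[0]
        r1, r2 = fragment_reads(p, seq)
        assert r1 == seq[p.start - 1 : p.start + 99]
        mate2 = seq[p.start + 149 : p.start + 249]
        revcomp = mate2.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert r2 == revcomp

    def test_fastq_has_two_reads_per_fragment(self, tmp_path):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        rec = TranscriptRecord("t", seq)
        placements = generate_fragments(rec, 8, "s", rng)
        write_fastq(placements, {"s": {"t": seq}}, tmp_path / "r1.fq", tmp_path / "r2.fq")
        r1 = (tmp_path / "r1.fq").read_text().splitlines()
        r2 = (tmp_path / "r2.fq").read_text().splitlines()
        assert len(r1) == len(r2) == 8 * 4
        assert all(len(line) == 100 for line in r1[1::4] + r2[1::4])


class TestPlacementsToPileup:
    def test_single_fragment_depth_profile(self, tmp_path):
        rec = TranscriptRecord("t", "A" * 300)
        from polyase.simulate import FragmentPlacement

        p = FragmentPlacement("t", "s", 1)
        path = tmp_path / "one.mpileup"
        placements_to_pileup([p], [rec], {"s": {"t": rec.sequence}}, path)
        depth = {col.position: col.depth for col in read_mpileup(path)}
        assert all(depth.get(i) == 1 for i in range(1, 101))
        assert all(i not in depth for i in range(101, 151))  # inner gap
        assert all(depth.get(i) == 1 for i in range(151, 251))

    def test_overlapping_fragments_add(self, tmp_path):
        rec = TranscriptRecord("t", "C" * 300)
        from polyase.simulate import FragmentPlacement

        placements = [FragmentPlacement("t", "s", 1), FragmentPlacement("t", "s", 1)]
        path = tmp_path / "two.mpileup"
        placements_to_pileup(placements, [rec], {"s": {"t": rec.sequence}}, path)
        assert {col.depth for col in read_mpileup(path)} == {2}

    def test_variant_positions_show_strain_base(self, tmp_path):
        ref = TranscriptRecord("t", "C" * 300)
        strain_seq = "C" * 49 + "T" + "C" * 250  # variant at position 50
        from polyase.simulate import FragmentPlacement

        path = tmp_path / "var.mpileup"
        placements_to_pileup(
            [FragmentPlacement("t", "s", 1)], [ref], {"s": {"t": strain_seq}}, path
        )
        by_pos = {col.position: col for col in read_mpileup(path)}
        assert by_pos[50].bases == "T"  # forward-mate mismatch, uppercase
        assert by_pos[49].bases == "C"

    def test_pileup_round_trip_through_parser(self, tmp_path):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        rec = TranscriptRecord("t", seq)
        placements = generate_fragments(rec, 25, "s", rng)
        path = tmp_path / "rt.mpileup"
        placements_to_pileup(placements, [rec], {"s": {"t": seq}}, path)
        expected = np.zeros(600, dtype=int)
        for p in placements:
            for first, last, _ in p.covered_intervals():
                expected[first - 1 : last] += 1
        observed = np.zeros(600, dtype=int)
        for col in read_mpileup(path):
            observed[col.position - 1] = col.depth
            assert len(col.observations) == col.depth
        assert (observed == expected).all()


class TestEvaluateRecovery:
    def frame(self, rows):
        return pd.DataFrame(rows, index=[f"t{i}" for i in range(len(rows))],
                            columns=["s1", "s2", "s3"])

    def test_perfect_recovery(self):
        truth = self.frame([[10, 20, 30], [5, 5, 90]])
        table, summary = evaluate_recovery(truth, truth * 3.0)
        assert np.allclose(table["r"], 1.0)
        assert summary["fraction_r_gt_0.8"] == 1.0

    def test_reversed_values_anticorrelate(self):
        truth = self.frame([[10, 20, 30]])
        est = self.frame([[30, 20, 10]])
        table, _ = evaluate_recovery(truth, est)
        assert table["r"].iloc[0] == pytest.approx(-1.0)

    def test_constant_truth_is_flagged_undefined(self):
        # Near-equal true values: the correlation carries no signal even
        # when absolute recovery is good.
        truth = self.frame([[20, 20, 20]])
        est = self.frame([[19, 21, 20]])
        table, summary = evaluate_recovery(truth, est)
        assert np.isnan(table["r"].iloc[0])
        assert table["flag"].iloc[0] == "constant"
        assert summary["fraction_r_gt_0.8"] == 0.0

    def test_mismatched_transcripts_rejected(self):
        truth = self.frame([[1, 2, 3]])
        est = self.frame([[1, 2, 3]])
        est.index = ["other"]
        with pytest.raises(ValueError):
            evaluate_recovery(truth, est)


class TestReproducibility:
    def test_same_seed_same_bytes(self, tmp_path):
        kwargs = dict(n_transcripts=3, transcript_length=600,
                      parental_fragments=60, triploid_fragments=(50, 80))
        a = simulate_experiment(tmp_path / "a", seed=123, **kwargs)
        b = simulate_experiment(tmp_path / "b", seed=123, **kwargs)
        for key in a:
            assert filecmp.cmp(a[key], b[key], shallow=False), key

    def test_different_seed_differs(self, tmp_path):
        kwargs = dict(n_transcripts=2, transcript_length=600,
                      parental_fragments=40, triploid_fragments=(50, 80))
        a = simulate_experiment(tmp_path / "a", seed=1, **kwargs)
        b = simulate_experiment(tmp_path / "b", seed=2, **kwargs)
        assert not filecmp.cmp(a["reference"], b["reference"], shallow=False)
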