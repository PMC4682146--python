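import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from operscan import matrices as mm
from operscan.simulate import (generate_library_measurements,
                               single_mutant_library, spacer_single_variants)

REF = "TTAAGACGATCTTAAG"


def counting_oracle_pwm(seqs, pseudocount):
    """Hand-rolled per-column frequency counting."""
    L = len(seqs[0])
    probs = np.zeros((L, 4))
    for i in range(L):
        for b, base in enumerate("ACGT"):
            c = sum(1 for s in seqs if s[i] == base)
            probs[i, b] = (c + pseudocount) / (len(seqs) + 4 * pseudocount)
    return probs


class TestPWM:
    def test_single_sequence_no_pseudocount_is_one_hot(self):
        pwm = mm.build_pwm(["TTAAG"], pseudocount=0.0)
        assert mm.score_sequence(pwm, "TTAAG") == pytest.approx(5 * np.log2(4))

    def test_zero_pseudocount_with_missing_base_errors(self):
        with pytest.raises(ValueError, match="pseudocount"):
            mm.score_sequence(mm.build_pwm(["TTAAG"], pseudocount=0.0), "TTAAC")

    def test_identical_training_set_has_consensus_argmax(self):
        pwm = mm.build_pwm(["TTAAG"] * 10, pseudocount=1.0)
        assert pwm.consensus == "TTAAG"
        assert mm.score_sequence(pwm, "TTAAG") == pytest.approx(pwm.max_score())

    def test_matches_counting_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 16)) for _ in range(20)]
        pwm = mm.build_pwm(seqs, pseudocount=1.0)
        assert np.allclose(pwm.probabilities, counting_oracle_pwm(seqs, 1.0),
                           atol=1e-9)

    def test_score_is_columnwise_lookup_sum(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(12)]
        pwm = mm.build_pwm(seqs)
        probe = "ACGTACGT"
        expected = sum(pwm.log_odds[i, "ACGT".index(c)]
                       for i, c in enumerate(probe))
        assert mm.score_sequence(pwm, probe) == pytest.approx(expected)

    def test_single_position_score_difference(self):
        pwm = mm.build_pwm(["TTAAG", "TTAAG", "CTAAG"])
        d = mm.score_sequence(pwm, "TTAAG") - mm.score_sequence(pwm, "CTAAG")
        assert d == pytest.approx(pwm.log_odds[0, 3] - pwm.log_odds[0, 1])

    def test_score_rejects_ambiguity(self):
        pwm = mm.build_pwm(["TTAAG"])
        with pytest.raises(ValueError):
            mm.score_sequence(pwm, "TTANG")

    def test_score_bounds(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(9)]
        pwm = mm.build_pwm(seqs)
        s = mm.score_sequence(pwm, "".join(rng.choice(list("ACGT"), 6)))
        assert pwm.min_score() - 1e-12 <= s <= pwm.max_score() + 1e-12


class TestInformationContent:
    def test_deterministic_and_uniform_columns(self):
        pwm = mm.PositionWeightMatrix(
            np.array([[1.0, 0, 0, 0], [0.25, 0.25, 0.25, 0.25]]),
            np.full(4, 0.25))
        ic = mm.information_content(pwm)
        assert ic[0] == pytest.approx(2.0)
        assert ic[1] == pytest.approx(0.0)

    def test_half_half_column_is_one_bit(self):
        pwm = mm.PositionWeightMatrix(np.array([[0.5, 0.5, 0.0, 0.0]]),
                                      np.full(4, 0.25))
        assert mm.information_content(pwm)[0] == pytest.approx(1.0)


class TestStrengthLink:
    def test_exponential_anchor_point(self):
        link = mm.StrengthLink(1.6, 1.9)
        assert mm.operator_strength(0.0, link) == pytest.approx(np.e ** 1.9)

    def test_fitted_values_evaluate_as_expected(self):
        link = mm.StrengthLink(1.6, 1.9)
        assert mm.operator_strength(1.0, link) == pytest.approx(np.exp(3.5))

    def test_linear_clamps_at_zero(self):
        link = mm.StrengthLink(1.0, 0.0, form="linear")
        assert mm.operator_strength(-2.0, link) == 0.0

    def test_monotone_increasing_in_score(self):
        link = mm.StrengthLink(1.6, 1.9)
        ss = np.linspace(-5, 5, 50)
        vals = [mm.operator_strength(s, link) for s in ss]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_noiseless_fit_recovers_parameters(self, rng):
        S = rng.uniform(-3, 3, size=30)
        fc = np.exp(1.6 * S + 1.9)
        link, info = mm.fit_strength_params(S, fc)
        assert link.a == pytest.approx(1.6, abs=1e-9)
        assert link.b == pytest.approx(1.9, abs=1e-9)
        assert info["rss"] == pytest.approx(0.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        link, _ = mm.fit_strength_params([0.0, 1.0], [np.e ** 1.0, np.e ** 2.0])
        assert link.a == pytest.approx(1.0)
        assert link.b == pytest.approx(1.0)

    def test_noisy_fit_recovers_slope(self):
        rng = np.random.default_rng(99)
        S = rng.uniform(-3, 3, size=50)
        fc = np.exp(1.6 * S + 1.9) * rng.lognormal(0, 0.2, size=50)
        link, _ = mm.fit_strength_params(S, fc)
        assert abs(link.a - 1.6) < 0.15

    def test_identical_scores_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            mm.fit_strength_params([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])


class TestEnergyConversion:
    def test_reference_is_zero(self):
        assert mm.fold_change_to_energy(5.0, 5.0) == 0.0

    def test_tenfold_reduction_is_2_3_kbt(self):
        assert mm.fold_change_to_energy(0.1) == pytest.approx(2.302585, abs=1e-6)

    @settings(max_examples=50, derandomize=True)
    @given(x=st.floats(1e-6, 1e6))
    def test_inverse_pair(self, x):
        assert mm.energy_to_fold_change(mm.fold_change_to_energy(x)) == \
            pytest.approx(x, rel=1e-12)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            mm.fold_change_to_energy(0.0)


class TestPentamerEnergies:
    def test_neutral_mutant_gives_zero(self):
        m = mm.LibraryMeasurement("c1", "ATAAGACGATCTTAAG", 1.0)
        dE, missing = mm.build_pentamer_energies([m], REF,
                                                 mirror_downstream=False)
        assert dE[0, 0] == 0.0 and not missing[0, 0]

    def test_full_upstream_library_fills_15_cells(self):
        constructs = single_mutant_library(REF)
        assert len(constructs) == 15
        ms = [mm.LibraryMeasurement(f"c{i}", s, 0.5)
              for i, s in enumerate(constructs)]
        dE, missing = mm.build_pentamer_energies(ms, REF,
                                                 mirror_downstream=False)
        assert (~missing[:5]).sum() == 20  # 15 measured + 5 reference cells
        assert np.count_nonzero(dE[:5]) == 15

    def test_mirroring_copies_upstream_to_downstream(self):
        ms = [mm.LibraryMeasurement("c", "CTAAGACGATCTTAAG", 0.1)]
        dE, missing = mm.build_pentamer_energies(ms, REF, mirror_downstream=True)
        assert dE[11, 1] == pytest.approx(dE[0, 1])
        assert not missing[11, 1]

    def test_multi_mutant_rejected(self):
        with pytest.raises(ValueError, match="one mutated position"):
            mm.build_pentamer_energies(
                [mm.LibraryMeasurement("c", "CCAAGACGATCTTAAG", 0.5)], REF)

    def test_conflicting_duplicates_rejected(self):
        ms = [mm.LibraryMeasurement("c1", "CTAAGACGATCTTAAG", 0.5),
              mm.LibraryMeasurement("c2", "CTAAGACGATCTTAAG", 0.7)]
        with pytest.raises(ValueError, match="conflict"):
            mm.build_pentamer_energies(ms, REF)

    def test_noiseless_generator_round_trip(self, truth_matrix):
        ref = truth_matrix.reference_sequence
        constructs = single_mutant_library(ref, positions=range(0, 5)) + \
            single_mutant_library(ref, positions=range(11, 16))
        ms = generate_library_measurements(truth_matrix, constructs,
                                           noise_cv=0.0)
        dE, missing = mm.build_pentamer_energies(ms, ref,
                                                 mirror_downstream=False)
        filled = ~missing
        assert np.allclose(dE[filled], truth_matrix.dE[filled], atol=1e-12)


class TestSpacerEnergies:
    def test_single_variant_exactly_determines_its_cell(self):
        var = REF[:5] + "CCGATC" + REF[11:]  # A->C at spacer position 5
        ms = [mm.LibraryMeasurement("c", var, 0.5)]
        dE, missing = mm.fit_spacer_energies(ms, REF)
        assert dE[5, 1] == pytest.approx(-np.log(0.5))
        assert not missing[5, 1]
        assert np.count_nonzero(dE) == 1

    def test_full_spacer_library_exact_recovery(self, truth_matrix):
        ref = truth_matrix.reference_sequence
        constructs = spacer_single_variants(ref, n=18)
        ms = generate_library_measurements(truth_matrix, constructs,
                                           noise_cv=0.0)
        dE, missing = mm.fit_spacer_energies(ms, ref)
        filled = ~missing
        assert np.allclose(dE[filled], truth_matrix.dE[filled], atol=1e-9)

    def test_underdetermined_solution_is_minimum_norm(self, truth_matrix):
        ref = truth_matrix.reference_sequence
        constructs = spacer_single_variants(ref, n=7)
        ms = generate_library_measurements(truth_matrix, constructs,
                                           noise_cv=0.0)
        dE, missing = mm.fit_spacer_energies(ms, ref)
        # reproduces every observation
        for m in ms:
            codes = [c for c in m.operator_sequence]
            e = sum(dE[i, "ACGT".index(codes[i])] for i in range(16))
            assert e == pytest.approx(-np.log(m.relative_expression), abs=1e-9)
        # minimal norm among solutions: pinv oracle
        X = np.zeros((7, 18))
        free = [(i, b) for i in range(5, 11) for b in range(4)
                if "ACGT"[b] != ref[i]]
        y = []
        for r, m in enumerate(ms):
            for j, (i, b) in enumerate(free):
                if m.operator_sequence[i] == "ACGT"[b]:
                    X[r, j] = 1
            y.append(-np.log(m.relative_expression))
        oracle = np.linalg.pinv(X) @ np.array(y)
        got = np.array([dE[i, b] for i, b in free])
        assert np.allclose(got, oracle, atol=1e-9)

    def test_all_zero_design_errors(self):
        ms = [mm.LibraryMeasurement("c", REF, 1.0)]
        with pytest.raises(ValueError, match="all-zero"):
            mm.fit_spacer_energies(ms, REF)

    def test_pentamer_variation_rejected(self):
        bad = "C" + REF[1:]
        with pytest.raises(ValueError, match="outside the spacer"):
            mm.fit_spacer_energies([mm.LibraryMeasurement("c", bad, 0.5)], REF)


class TestEnergyMatrix:
    def test_all_zero_matrix_predicts_reference_everywhere(self, rng):
        m = mm.EnergyMatrix(np.zeros((16, 4)), REF, reference_fold_change=7.0)
        probe = "".join(rng.choice(list("ACGT"), 16))
        assert m.predicted_fold_change(probe) == pytest.approx(7.0)

    def test_layout_is_16_positions(self, truth_matrix):
        assert truth_matrix.dE.shape == (16, 4)
        with pytest.raises(ValueError):
            mm.EnergyMatrix(np.zeros((15, 4)), REF[:15])

    def test_reference_energy_is_zero(self, truth_matrix):
        assert truth_matrix.sequence_energy(
            truth_matrix.reference_sequence) == 0.0

    def test_single_mutant_energy_is_its_cell(self, truth_matrix):
        ref = truth_matrix.reference_sequence
        mutant = "C" + ref[1:] if ref[0] != "C" else "A" + ref[1:]
        b = "ACGT".index(mutant[0])
        assert truth_matrix.sequence_energy(mutant) == \
            pytest.approx(truth_matrix.dE[0, b])

    def test_energy_additivity_over_k_mutants(self, truth_matrix, rng):
        """The energy of any k-mutant is the sum of its single-mutant energies."""
        ref = truth_matrix.reference_sequence
        for _ in range(10):
            positions = rng.choice(16, size=3, replace=False)
            seq = list(ref)
            total = 0.0
            for i in positions:
                b = rng.choice([x for x in "ACGT" if x != ref[i]])
                seq[i] = b
                single = ref[:i] + b + ref[i + 1:]
                total += truth_matrix.sequence_energy(single)
            assert truth_matrix.sequence_energy("".join(seq)) == \
                pytest.approx(total, abs=1e-12)

    def test_tsv_round_trip(self, truth_matrix, tmp_path):
        p = tmp_path / "matrix.tsv"
        truth_matrix.to_tsv(p)
        again = mm.EnergyMatrix.from_tsv(p)
        assert np.allclose(again.dE, truth_matrix.dE, atol=1e-12)
        assert again.reference_sequence == truth_matrix.reference_sequence

    def test_wrong_length_sequence_errors(self, truth_matrix):
        with pytest.raises(ValueError):
            truth_matrix.sequence_energy("TTAAG")


class TestAssembleMatrix:
    def test_assembled_matrix_predicts_reference(self, truth_matrix):
        ref = truth_matrix.reference_sequence
        pent_constructs = (single_mutant_library(ref, range(0, 5))
                           + single_mutant_library(ref, range(11, 16)))
        sp_constructs = spacer_single_variants(ref, n=18)
        pent = mm.build_pentamer_energies(
            generate_library_measurements(truth_matrix, pent_constructs, 0.0),
            ref, mirror_downstream=False)
        sp = mm.fit_spacer_energies(
            generate_library_measurements(truth_matrix, sp_constructs, 0.0), ref)
        matrix = mm.assemble_energy_matrix(pent, sp, ref)
        assert matrix.dE.shape == (16, 4)
        assert matrix.sequence_energy(ref) == 0.0
        assert np.allclose(matrix.dE, truth_matrix.dE, atol=1e-9)

    def test_wrong_reference_length_errors(self):
        z = (np.zeros((16, 4)), np.ones((16, 4), dtype=bool))
        with pytest.raises(ValueError):
            mm.assemble_energy_matrix(z, z, "TTAAG")


class TestMatrixRecovery:
    def test_recovery_correlation_under_noise(self, truth_matrix):
        """Full single-mutant library + 7 spacer variants at 10% CV, 3 reps."""
        ref = truth_matrix.reference_sequence
        pent_constructs = (single_mutant_library(ref, range(0, 5))
                           + single_mutant_library(ref, range(11, 16)))
        sp_constructs = spacer_single_variants(ref, n=7)
        pent_ms = generate_library_measurements(truth_matrix, pent_constructs,
                                                noise_cv=0.1, n_replicates=3,
                                                seed=202)
        sp_ms = generate_library_measurements(truth_matrix, sp_constructs,
                                              noise_cv=0.1, n_replicates=3,
                                              seed=203)
        pent = mm.build_pentamer_energies(pent_ms, ref, mirror_downstream=False)
        sp = mm.fit_spacer_energies(sp_ms, ref)
        matrix = mm.assemble_energy_matrix(pent, sp, ref)
        cells = ~matrix.missing
        ref_codes = np.array(["ACGT".index(c) for c in ref])
        cells[np.arange(16), ref_codes] = False  # reference gauge cells
        r = np.corrcoef(matrix.dE[cells], truth_matrix.dE[cells])[0, 1]
        assert r > 0.95


class TestPwmDerivedMatrix:
    def test_reference_bases_are_zero(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 16)) for _ in range(30)]
        pwm = mm.build_pwm(seqs)
        em = mm.pwm_to_energy_matrix(pwm, mm.StrengthLink(1.6, 1.9))
        ref_codes = [("ACGT").index(c) for c in em.reference_sequence]
        assert all(em.dE[i, b] == 0 for i, b in enumerate(ref_codes))

    def test_strength_ratio_identity(self, rng):
        """exp(-ddE) between two sequences equals their strength ratio."""
        seqs = ["".join(rng.choice(list("ACGT"), 16)) for _ in range(30)]
        pwm = mm.build_pwm(seqs)
        link = mm.StrengthLink(1.6, 1.9)
        em = mm.pwm_to_energy_matrix(pwm, link)
        for _ in range(5):
            s1 = "".join(rng.choice(list("ACGT"), 16))
            s2 = "".join(rng.choice(list("ACGT"), 16))
            ratio = (mm.operator_strength(mm.score_sequence(pwm, s1), link)
                     / mm.operator_strength(mm.score_sequence(pwm, s2), link))
            d = em.sequence_energy(s1) - em.sequence_energy(s2)
            assert np.exp(-d) == pytest.approx(ratio, rel=1e-9)
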