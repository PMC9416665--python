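import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from idrmem import (
    DISORDERED_PARAMS,
    HELIX_PARAMS,
    ModelParameters,
    ResidueClass,
    classify_residues,
    distance_factor,
    log_weights,
    predict,
    propensity_profile,
    statistical_weight,
)

from .conftest import naive_weight

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=30)


class TestClassifyResidues:
    def test_charge_assignment(self):
        rc = classify_residues("KRDEG", termini="capped")
        assert [c.symbol for c in rc.classes] == ["+", "+", "-", "-", "0"]
        assert not rc.n_term_site and not rc.c_term_site

    def test_free_termini_pseudo_sites(self):
        rc = classify_residues("GGG", termini="free")
        assert all(c is ResidueClass.NEUTRAL for c in rc.classes)
        assert rc.n_term_site and rc.c_term_site

    def test_case_and_whitespace_normalization(self):
        assert classify_residues("kr de g", "capped") == classify_residues(
            "KRDEG", "capped"
        )

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            classify_residues("", "free")

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            classify_residues("GGZG", "free")

    def test_x_is_neutral_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            rc = classify_residues("GXG", "capped")
        assert rc.classes[1] is ResidueClass.NEUTRAL
        assert "X" in caplog.text

    def test_histidine_is_neutral(self):
        rc = classify_residues("H", "capped")
        assert rc.classes[0] is ResidueClass.NEUTRAL

    def test_bad_termini_value(self):
        with pytest.raises(ValueError):
            classify_residues("GG", "loose")


class TestModelParameters:
    def test_published_sets(self):
        assert (DISORDERED_PARAMS.q_plus, DISORDERED_PARAMS.q_minus,
                DISORDERED_PARAMS.q_zero) == (2.43, 0.26, 0.59)
        assert (HELIX_PARAMS.q_plus, HELIX_PARAMS.q_minus, HELIX_PARAMS.q_zero) == (
            2.29, 0.64, 1.17)
        assert (DISORDERED_PARAMS.a_pm, DISORDERED_PARAMS.b_pm,
                DISORDERED_PARAMS.a_zero) == (0.0982, 0.00305, 0.521)

    @pytest.mark.parametrize("bad", [{"q_plus": 0.0}, {"q_minus": -1.0}, {"a_pm": -0.1}])
    def test_invariants_enforced(self, bad):
        kwargs = dict(q_plus=2.0, q_minus=0.3, q_zero=0.6)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)


class TestDistanceFactor:
    def test_neutral_at_zero_is_amplitude(self, disordered):
        assert distance_factor(ResidueClass.NEUTRAL, 0, disordered) == pytest.approx(0.59)

    def test_positive_at_ten(self, disordered):
        # 1 + 1.43 / (1 + 0.982 + 0.305), by hand
        expected = 1 + 1.43 / (1 + 0.0982 * 10 + 0.00305 * 100)
        assert distance_factor(ResidueClass.POSITIVE, 10, disordered) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(1.625, abs=5e-4)

    def test_neutral_at_one(self, disordered):
        assert distance_factor(ResidueClass.NEUTRAL, 1, disordered) == pytest.approx(
            1 - 0.41 / 1.521
        )

    def test_large_distance_approaches_one(self, disordered):
        assert distance_factor(ResidueClass.POSITIVE, 1e9, disordered) == pytest.approx(
            1.0, abs=1e-6
        )

    @pytest.mark.parametrize("cls", list(ResidueClass))
    @pytest.mark.parametrize("params", [DISORDERED_PARAMS, HELIX_PARAMS])
    def test_bounded_between_one_and_amplitude(self, cls, params):
        q0 = params.amplitude(cls)
        lo, hi = min(1.0, q0), max(1.0, q0)
        for d in range(0, 501):
            f = distance_factor(cls, d, params)
            assert lo <= f <= hi

    @pytest.mark.parametrize("cls", list(ResidueClass))
    def test_monotone_toward_one(self, cls, disordered):
        vals = np.array([distance_factor(cls, d, disordered) for d in range(501)])
        diffs = np.diff(vals)
        if disordered.amplitude(cls) > 1:
            assert np.all(diffs < 0)
        elif disordered.amplitude(cls) < 1:
            assert np.all(diffs > 0)

    def test_negative_distance_errors(self, disordered):
        with pytest.raises(ValueError):
            distance_factor(ResidueClass.NEUTRAL, -1, disordered)


class TestStatisticalWeight:
    def test_neutral_pentamer_center(self, disordered):
        rc = classify_residues("GGGGG", "capped")
        f1 = distance_factor(ResidueClass.NEUTRAL, 1, disordered)
        f2 = distance_factor(ResidueClass.NEUTRAL, 2, disordered)
        expected = 0.59 * f1**2 * f2**2
        assert statistical_weight(3, rc, disordered) == pytest.approx(expected)
        assert expected == pytest.approx(0.201, abs=5e-4)

    def test_single_residue_capped(self, disordered):
        rc = classify_residues("G", "capped")
        assert statistical_weight(1, rc, disordered) == pytest.approx(0.59)

    def test_single_k_free_termini(self, disordered):
        rc = classify_residues("K", "free")
        assert statistical_weight(1, rc, disordered) == pytest.approx(
            2.43 * 2.43 * 0.26
        )

    def test_index_out_of_range(self, disordered):
        rc = classify_residues("GG", "capped")
        with pytest.raises(IndexError):
            statistical_weight(3, rc, disordered)
        with pytest.raises(IndexError):
            statistical_weight(0, rc, disordered)

    @pytest.mark.parametrize("termini", ["free", "capped"])
    def test_matches_naive_product_oracle(self, termini, disordered):
        rng = np.random.default_rng(42)
        for _ in range(200):
            length = int(rng.integers(1, 31))
            seq = "".join(rng.choice(list(AA), length))
            rc = classify_residues(seq, termini)
            logw = log_weights(rc, disordered)
            for n in range(1, length + 1):
                assert math.exp(logw[n - 1]) == pytest.approx(
                    naive_weight(n, rc, disordered), rel=1e-10
                )

    @given(sequences)
    def test_reversal_symmetry_palindromic_classes(self, seq):
        # reversing the sequence reverses the class string; a palindrome
        # of classes is built by mirroring
        rc = classify_residues(seq + seq[::-1], "capped")
        logw = log_weights(rc, DISORDERED_PARAMS)
        np.testing.assert_allclose(logw, logw[::-1], rtol=1e-12)

    @given(sequences, st.integers(min_value=0, max_value=29))
    def test_positive_substitution_never_decreases_weight(self, seq, pos):
        pos = pos % len(seq)
        mutated = seq[:pos] + "K" + seq[pos + 1 :]
        if seq[pos] in "KRDE":
            return  # only neutral -> positive substitutions claimed
        for params in (DISORDERED_PARAMS, HELIX_PARAMS):
            before = log_weights(classify_residues(seq, "capped"), params)
            after = log_weights(classify_residues(mutated, "capped"), params)
            assert np.all(after >= before - 1e-12)


class TestPropensityProfile:
    def test_normalization_max_is_c(self, disordered):
        rc = classify_residues("MKKRDDEAGHW", "free")
        for c in (1.0, 0.37):
            prof = propensity_profile(rc, disordered, c=c)
            assert prof.propensities.max() == pytest.approx(c, abs=1e-12)
            np.testing.assert_allclose(
                prof.propensities, c * prof.weights / prof.w_max, rtol=1e-12
            )

    def test_all_weights_positive(self, disordered):
        prof = predict("MKKRDDEAGHW")
        assert np.all(prof.weights > 0)

    def test_neutral_homopolymer_symmetric_and_nearly_flat_interior(self, disordered):
        # exact translational symmetry only holds for an infinite chain;
        # on a finite one the profile is mirror-symmetric with a slowly
        # varying interior (attenuation tails differ by a few percent)
        rc = classify_residues("G" * 41, "capped")
        prof = propensity_profile(rc, disordered)
        np.testing.assert_allclose(prof.weights, prof.weights[::-1], rtol=1e-10)
        interior = prof.propensities[15:26]
        np.testing.assert_allclose(interior, interior[0], rtol=0.05)

    def test_central_lysine_is_global_max(self, disordered):
        rc = classify_residues("GGGGKGGGG", "capped")
        prof = propensity_profile(rc, disordered)
        # brute-force oracle: naive product at every n
        naive = [naive_weight(n, rc, disordered) for n in range(1, 10)]
        assert int(np.argmax(naive)) == 4
        assert int(np.argmax(prof.propensities)) == 4
        assert prof.argmax_index() == 5

    def test_numbering_offset(self, disordered):
        prof = predict("GGGGKGGGG", termini="capped", numbering_offset=580)
        assert prof.indices[0] == 581
        assert prof.argmax_index() == 585

    def test_invalid_scale(self, disordered):
        rc = classify_residues("GG", "capped")
        with pytest.raises(ValueError):
            propensity_profile(rc, disordered, c=0.0)

    def test_long_sequence_no_overflow(self, disordered):
        prof = predict("KR" * 2500, termini="free")
        assert np.all(np.isfinite(prof.propensities))
        assert prof.propensities.max() == pytest.approx(1.0)

    def test_predict_unknown_mode(self):
        with pytest.raises(ValueError):
            predict("GG", mode="folded")
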