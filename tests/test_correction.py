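"""Natural-abundance correction: matrix construction, NNLS inversion,
enrichment extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deutg import (
    CorrectionOptions,
    IonFormula,
    IsotopologueSpectrum,
    build_correction_matrix,
    correct_spectrum,
    enrichment_from_fractions,
    enrichment_table,
    simulate_test,
)
from deutg.correction import natural_shift_distribution
from deutg.isotopes import NATURAL_ABUNDANCE
from deutg.studies import recover_partition

from oracle_isotopes import labeled_species_distribution, molecule_distribution

GLUCOSE = {"C": 6, "H": 11, "O": 6}


class TestMatrixConstruction:
    def test_no_heavy_isotopes_gives_identity(self):
        """Without natural heavy isotopes there is no spectral overlap."""
        opts = CorrectionOptions(
            tracer_purity=1.0,
            natural_abundances={"C": (1.0,), "H": (1.0,), "O": (1.0,)},
            max_shift=2,
        )
        m = build_correction_matrix(IonFormula(), opts)
        assert np.allclose(m, np.eye(3))

    def test_column0_matches_bruteforce_enumeration(self, pure_matrix):
        """Unlabeled-glucose column equals exhaustive isotope enumeration."""
        oracle = molecule_distribution(GLUCOSE, NATURAL_ABUNDANCE)
        expected = np.array([oracle.get(k, 0.0) for k in range(3)])
        assert np.max(np.abs(pure_matrix[:, 0] - expected)) < 1e-10

    def test_labeled_column_matches_impurity_enumeration(self, default_matrix):
        """Fully-labeled column at purity 0.99: mass at +2 scaled by 0.99^2,
        single-position impurity feeding shift +1, per the enumeration oracle."""
        oracle = labeled_species_distribution(GLUCOSE, NATURAL_ABUNDANCE, 2, 0.99)
        expected = np.array([oracle.get(k, 0.0) for k in range(3)])
        assert np.max(np.abs(default_matrix[:, 2] - expected)) < 1e-10
        # the impurity channel moves visible mass from shift 2 to shift 1
        # relative to a perfectly pure tracer
        pure = build_correction_matrix(IonFormula(), CorrectionOptions(tracer_purity=1.0))
        assert default_matrix[2, 2] < pure[2, 2]
        assert default_matrix[1, 2] > pure[1, 2]

    def test_entries_bounded_columns_subunit_diagonal_dominant(self, default_matrix):
        m = default_matrix
        assert np.all((m >= 0) & (m <= 1))
        assert np.all(m.sum(axis=0) <= 1 + 1e-12)
        # each species' largest mass sits at its own shift
        assert np.all(np.argmax(m, axis=0) == np.arange(m.shape[1]))

    def test_tracer_shift_exceeding_spectrum_raises(self):
        opts = CorrectionOptions(max_shift=1, n_label_positions=2)
        with pytest.raises(ValueError, match="tracer shift exceeds spectrum length"):
            build_correction_matrix(IonFormula(), opts)

    def test_bad_formula_rejected(self):
        with pytest.raises(ValueError):
            IonFormula(element_counts={"C": 6, "H": 1, "O": 6})  # H < label count
        with pytest.raises(ValueError):
            IonFormula(element_counts={})


class TestSpectrumCorrection:
    def test_noiseless_roundtrip(self, default_matrix):
        truth = np.array([0.7, 0.0, 0.3])
        observed = default_matrix @ truth
        spec = IsotopologueSpectrum("s", 0.0, observed)
        frac, resid, flag = correct_spectrum(spec, default_matrix)
        assert np.max(np.abs(frac - truth)) < 1e-8
        assert not flag

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=3, max_size=3)
        .filter(lambda v: sum(v) > 1e-6)
    )
    def test_roundtrip_any_fraction_vector(self, default_matrix, raw):
        """Forward-convolve then correct recovers any valid fraction vector."""
        truth = np.array(raw) / sum(raw)
        spec = IsotopologueSpectrum("s", 0.0, default_matrix @ truth)
        frac, _, _ = correct_spectrum(spec, default_matrix)
        assert np.max(np.abs(frac - truth)) < 1e-8

    def test_identity_matrix_normalizes_only(self):
        spec = IsotopologueSpectrum("s", 0.0, [2.0, 0.0, 6.0])
        frac, resid, _ = correct_spectrum(spec, np.eye(3))
        assert np.allclose(frac, [0.25, 0.0, 0.75])
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_stays_nonnegative_and_close(self, default_matrix, rng):
        truth = np.array([0.55, 0.05, 0.40])
        for _ in range(50):
            obs = default_matrix @ truth * (1 + 0.03 * rng.standard_normal(3))
            frac, _, _ = correct_spectrum(
                IsotopologueSpectrum("s", 0.0, np.clip(obs, 0, None)), default_matrix
            )
            assert np.all(frac >= 0)
            assert np.max(np.abs(frac - truth)) < 0.1

    def test_empty_spectrum_raises(self, default_matrix):
        spec = IsotopologueSpectrum("s", 0.0, [0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="empty spectrum"):
            correct_spectrum(spec, default_matrix)

    def test_high_residual_sets_qc_flag_not_error(self, default_matrix):
        # junk spectrum far from the matrix column space
        spec = IsotopologueSpectrum("s", 0.0, [0.0, 1.0, 0.0])
        frac, resid, flag = correct_spectrum(spec, default_matrix, residual_threshold=0.05)
        assert flag and resid > 0.05
        assert np.all(frac >= 0)


class TestEnrichment:
    @pytest.mark.parametrize(
        "fractions, expected",
        [([1.0, 0.0, 0.0], 0.0), ([0.0, 0.0, 1.0], 1.0), ([0.6, 0.05, 0.35], 0.35)],
    )
    def test_enrichment_is_m2_fraction(self, fractions, expected):
        point = enrichment_from_fractions(np.array(fractions))
        assert point.enrichment == pytest.approx(expected)
        assert point.enrichment_raw == pytest.approx(expected)

    def test_baseline_sample_enrichment_near_zero(self, rng):
        """A pre-injection blood draw, after correction, shows <= 1% apparent
        tracer despite the natural M+2 background in its spectrum."""
        out = simulate_test(
            __import__("deutg").lfd_params(), "GTT", rng, noise=True
        )
        part = recover_partition(out)
        enr0 = part.exogenous[0] / part.total[0]
        assert enr0 <= 0.01

    def test_enrichment_table_and_uncorrected_mode(self, default_matrix):
        import pandas as pd

        truth = np.array([0.8, 0.0, 0.2])
        areas = 1e5 * (default_matrix @ truth)
        df = pd.DataFrame(
            [{"animal_id": "a1", "time_min": 0.0, "sample_id": "a1_t0",
              "area_m0": areas[0], "area_m1": areas[1], "area_m2": areas[2]}]
        )
        corrected = enrichment_table(df, correct=True)
        assert corrected["enrichment"].iloc[0] == pytest.approx(0.2, abs=1e-8)
        uncorrected = enrichment_table(df, correct=False)
        # ratio mode is just the M+2 share of total area
        assert uncorrected["enrichment"].iloc[0] == pytest.approx(
            areas[2] / areas.sum(), abs=1e-12
        )
        # on a tracer-free sample the uncorrected ratio keeps the natural
        # M+2 background while correction removes it
        base = 1e5 * default_matrix[:, 0]
        df0 = pd.DataFrame(
            [{"animal_id": "a1", "time_min": 0.0, "sample_id": "a1_t0",
              "area_m0": base[0], "area_m1": base[1], "area_m2": base[2]}]
        )
        assert enrichment_table(df0, correct=False)["enrichment"].iloc[0] > 0.01
        assert enrichment_table(df0, correct=True)["enrichment"].iloc[0] < 1e-8
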