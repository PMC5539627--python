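"""Scatter corrections, gap-segment derivatives and treatment parsing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nircal.preprocessing import (
    PreprocessSpec,
    Preprocessor,
    apply_treatment,
    detrend,
    gap_segment_derivative,
    msc,
    parse_treatment,
    snv,
)


class TestParseTreatment:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Standard MSC 2,4,4,1", ("msc", 2, 4, 4, 1)),
            ("Detrend only 0,0,1,1", ("dt", 0, 0, 1, 1)),
            ("SNV only 1,4,4,1", ("snv", 1, 4, 4, 1)),
            ("Detrend only 2,10,10,1", ("dt", 2, 10, 10, 1)),
            ("SNV-DT 1,4,4,1", ("snv-dt", 1, 4, 4, 1)),
            ("None 0,0,1,1", ("none", 0, 0, 1, 1)),
        ],
    )
    def test_known_strings(self, text, expected):
        spec = parse_treatment(text)
        assert (
            spec.scatter,
            spec.derivative,
            spec.gap,
            spec.smooth1,
            spec.smooth2,
        ) == expected

    @pytest.mark.parametrize(
        "text", ["just words", "Wavelet 2,4,4,1", "MSC 2,4", "MSC 2,4,4,1,9"]
    )
    def test_unparseable_strings(self, text):
        with pytest.raises(ValueError):
            parse_treatment(text)

    def test_derivative_requires_gap(self):
        with pytest.raises(ValueError, match="gap"):
            PreprocessSpec("none", derivative=1, gap=0)

    def test_round_trip_via_str(self):
        spec = parse_treatment("Standard MSC 2,4,4,1")
        assert parse_treatment(str(spec)) == spec


class TestSNV:
    def test_small_example(self):
        np.testing.assert_allclose(snv([[1.0, 2.0, 3.0]]), [[-1, 0, 1]])

    def test_rows_centred_and_scaled(self, rng):
        out = snv(rng.normal(2.0, 3.0, (15, 60)))
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    @given(
        scale=st.floats(0.1, 50),
        offset=st.floats(-20, 20),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance(self, scale, offset, seed):
        x = np.random.default_rng(seed).normal(size=(2, 30))
        np.testing.assert_allclose(snv(scale * x + offset), snv(x), atol=1e-8)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="row 1"):
            snv(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))


class TestDetrend:
    def test_annihilates_quadratic(self):
        wl = np.arange(1100.0, 2002.0, 2.0)
        row = 2 + 0.01 * wl + 1e-5 * wl**2
        out = detrend(row[None, :], wl)
        np.testing.assert_allclose(out, 0, atol=1e-8)

    def test_zeros_map_to_zeros(self):
        wl = np.linspace(0, 1, 10)
        np.testing.assert_allclose(detrend(np.zeros((2, 10)), wl), 0)

    def test_residual_orthogonal_to_quadratic_basis(self, rng):
        """Normal equations: the detrended row has zero projection on
        {1, lambda, lambda^2}."""
        wl = np.arange(1100.0, 2002.0, 2.0)
        x = rng.normal(size=(4, wl.size))
        resid = detrend(x, wl)
        z = (wl - wl.mean()) / ((wl[-1] - wl[0]) / 2)
        for basis in (np.ones_like(z), z, z**2):
            np.testing.assert_allclose(resid @ basis, 0, atol=1e-8)

    def test_linearity(self, rng):
        wl = np.linspace(1100, 2000, 51)
        a, b = rng.normal(size=(2, 3, 51))
        lhs = detrend(2.0 * a + 3.0 * b, wl)
        rhs = 2.0 * detrend(a, wl) + 3.0 * detrend(b, wl)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            detrend(np.ones((1, 2)), np.array([1.0, 2.0]))


class TestMSC:
    def test_reference_row_unchanged(self, rng):
        ref = rng.normal(0.5, 0.2, 80)
        out, coef = msc(ref[None, :], ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)
        np.testing.assert_allclose(coef[0], [0.0, 1.0], atol=1e-10)

    def test_recovers_known_offset_and_slope(self, rng):
        ref = rng.normal(0.5, 0.2, 80)
        row = 1.0 + 2.0 * ref
        out, coef = msc(row[None, :], ref)
        np.testing.assert_allclose(coef[0], [1.0, 2.0], atol=1e-10)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_frozen_reference_matches_joint_correction(self, rng):
        """Correcting validation rows with the stored calibration reference
        equals correcting them jointly against that same reference."""
        cal = rng.normal(0.5, 0.1, (20, 60))
        val = rng.normal(0.5, 0.1, (5, 60))
        ref = cal.mean(axis=0)
        out_frozen, _ = msc(val, ref)
        out_joint, _ = msc(np.vstack([cal, val]), ref)
        np.testing.assert_allclose(out_frozen, out_joint[20:], atol=1e-12)

    def test_flat_reference_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            msc(np.ones((2, 10)) * 3.0, np.ones(10))


class TestGapSegmentDerivative:
    def test_identity_treatment(self, rng):
        x = rng.normal(size=(3, 30))
        out, wl = gap_segment_derivative(x, 0, 0, 1, 1)
        np.testing.assert_array_equal(out, x)
        assert wl.size == 30

    def test_first_derivative_of_line_is_constant(self):
        wl = np.arange(1100.0, 1200.0, 2.0)
        slope = 0.03
        out, _ = gap_segment_derivative(slope * wl[None, :], 1, 4, 1, 1, wl)
        np.testing.assert_allclose(out, slope * 4 * 2.0, atol=1e-10)

    def test_second_gap_difference_matches_brute_force(self):
        x = np.array([1.0, 4.0, 9.0, 16.0, 25.0, 36.0, 49.0])  # quadratic
        out, _ = gap_segment_derivative(x[None, :], 2, 2, 1, 1)
        # brute force: (x[i+2]-x[i]) applied twice
        d1 = x[2:] - x[:-2]
        d2 = d1[2:] - d1[:-2]
        np.testing.assert_array_equal(out[0], d2)
        assert np.ptp(out) == 0  # second difference of a quadratic is constant

    def test_smoothing_and_edge_accounting(self, rng):
        x = rng.normal(size=(2, 50))
        out, wl = gap_segment_derivative(x, 2, 4, 4, 3, np.arange(50.0))
        lost = (4 - 1) + 2 * 4 + (3 - 1)
        assert out.shape[1] == 50 - lost
        assert wl.size == out.shape[1]

    def test_window_larger_than_spectrum_rejected(self):
        with pytest.raises(ValueError):
            gap_segment_derivative(np.ones((1, 10)), 2, 6, 1, 1)

    def test_linearity(self, rng):
        a, b = rng.normal(size=(2, 3, 40))
        lhs, _ = gap_segment_derivative(2 * a - b, 1, 3, 5, 2)
        ra, _ = gap_segment_derivative(a, 1, 3, 5, 2)
        rb, _ = gap_segment_derivative(b, 1, 3, 5, 2)
        np.testing.assert_allclose(lhs, 2 * ra - rb, atol=1e-10)


class TestPreprocessor:
    def test_identity_spec(self, rng):
        x = rng.normal(size=(4, 20))
        out, _ = apply_treatment("None 0,0,1,1", x)
        np.testing.assert_array_equal(out, x)

    def test_snv_spec_matches_snv(self):
        out, _ = apply_treatment("SNV only 0,0,1,1", np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1, 0, 1]])

    def test_composition_matches_manual_chain(self, averaged_small_dataset):
        spectra, _, _ = averaged_small_dataset
        wl = spectra.grid.wavelengths
        x = spectra.absorbance
        out, _ = apply_treatment("Standard MSC 2,4,4,1", x, wavelengths=wl)
        corrected, _ = msc(x)
        manual, _ = gap_segment_derivative(corrected, 2, 4, 4, 1, wl)
        np.testing.assert_allclose(out, manual, atol=1e-12)

    def test_frozen_statistics_are_idempotent(self, averaged_small_dataset):
        """Transforming the calibration set through a fitted preprocessor
        reproduces fit_transform output exactly."""
        spectra, _, _ = averaged_small_dataset
        pp = Preprocessor("Standard MSC 2,4,4,1", spectra.grid.wavelengths)
        first = pp.fit_transform(spectra.absorbance)
        again = pp.transform(spectra.absorbance)
        np.testing.assert_array_equal(first, again)

    def test_validation_uses_calibration_msc_reference(self, rng):
        cal = rng.normal(0.5, 0.1, (20, 40))
        val = rng.normal(0.5, 0.1, (6, 40))
        pp = Preprocessor("Standard MSC 0,0,1,1").fit(cal)
        expected, _ = msc(val, cal.mean(axis=0))
        np.testing.assert_allclose(pp.transform(val), expected, atol=1e-12)
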