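"""Dual-domain FFT features against independent brute-force oracles."""

import math

import numpy as np
import pytest

from s21density import (
    FeatureConfig,
    SubBandMask,
    Standardizer,
    block_features,
    extract_features,
    fft_along,
    polar_decompose,
    sf_features,
)
from s21density.estimators import BlockPCAExtractor
from s21density.features import FeatureVector, feature_vector_length, stack_features
from s21density.preprocess import remove_dc_bias
from s21density.s21_io import TxBlock

from conftest import make_random_scan


def _block(values, tx_index=0):
    values = np.atleast_2d(np.asarray(values, dtype=complex))
    freqs = 1e9 + 5e6 * np.arange(values.shape[1])
    return TxBlock(values=values, tx_index=tx_index, column_freqs_hz=freqs)


# --- independent oracles ---------------------------------------------------


def dft_double_sum(values, axis):
    """Direct double-sum DFT via an explicit kernel matrix (no FFT routine)."""
    values = np.asarray(values, dtype=complex)
    n = values.shape[axis]
    k = np.arange(n)
    kernel = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return kernel @ values if axis == 0 else values @ kernel.T


def dft_loops(values, axis):
    """Pure-Python loop DFT, for tiny inputs only."""
    values = np.asarray(values, dtype=complex)
    out = np.zeros_like(values)
    if axis == 1:
        rows, n = values.shape
        for i in range(rows):
            for k in range(n):
                out[i, k] = sum(
                    values[i, m] * complex(math.cos(2 * math.pi * k * m / n),
                                           -math.sin(2 * math.pi * k * m / n))
                    for m in range(n)
                )
    else:
        return dft_loops(values.T, axis=1).T
    return out


class TestFFTAlong:
    def test_constant_signal(self):
        out = fft_along(_block([[1, 1, 1, 1]]), "rf_spectral")
        np.testing.assert_allclose(out.values, [[4, 0, 0, 0]], atol=1e-12)

    def test_impulse(self):
        out = fft_along(_block([[1, 0, 0, 0]]), "rf_spectral")
        np.testing.assert_allclose(out.values, [[1, 1, 1, 1]], atol=1e-12)

    @pytest.mark.parametrize("domain,axis", [("rf_spectral", 1), ("spatial", 0)])
    def test_matches_double_sum_oracle(self, rng, domain, axis):
        for _ in range(100):
            vals = rng.standard_normal((4, 8)) + 1j * rng.standard_normal((4, 8))
            got = fft_along(_block(vals), domain).values
            np.testing.assert_allclose(got, dft_double_sum(vals, axis), atol=1e-9)

    def test_matches_loop_oracle_on_tiny_block(self, rng):
        vals = rng.standard_normal((2, 5)) + 1j * rng.standard_normal((2, 5))
        got = fft_along(_block(vals), "rf_spectral").values
        np.testing.assert_allclose(got, dft_loops(vals, axis=1), atol=1e-9)

    def test_dc_coefficient_vanishes_after_dc_removal(self, rng):
        vals = rng.standard_normal((16, 64)) + 1j * rng.standard_normal((16, 64))
        cleaned = remove_dc_bias(_block(vals))
        coeffs = fft_along(cleaned, "rf_spectral").values
        assert np.abs(coeffs[:, 0]).max() < 1e-9 * np.abs(vals).max()


class TestPolarDecompose:
    def test_pythagorean_example(self):
        polar = polar_decompose(fft_along(_block([[3 + 4j, 0]]), "rf_spectral"), 1)
        # k=0 coefficient is the sum 3+4j
        np.testing.assert_allclose(polar.magnitude, [[5.0]])
        np.testing.assert_allclose(polar.phase, [[math.atan2(4, 3)]])

    def test_phase_branch_and_zero_conventions(self):
        from s21density.features import CoefficientBlock

        coeffs = CoefficientBlock(values=np.array([[-1 + 0j, 0j]]), domain="rf_spectral")
        polar = polar_decompose(coeffs, 2)
        assert polar.phase[0, 0] == pytest.approx(math.pi)  # (-pi, pi] branch
        assert polar.magnitude[0, 1] == 0.0 and polar.phase[0, 1] == 0.0

    def test_component_count_out_of_range(self):
        coeffs = fft_along(_block(np.ones((3, 4))), "spatial")
        with pytest.raises(ValueError, match="outside"):
            polar_decompose(coeffs, 4)  # only 3 rows available in the spatial domain


class TestBlockFeatures:
    def test_zero_block_gives_all_zero_statistics(self):
        fb = block_features(_block(np.zeros((4, 8))), FeatureConfig(n_components=3))
        assert fb.as_array(FeatureConfig(n_components=3)).tolist() == [0.0] * 8

    def test_eight_statistics_in_canonical_order(self, rng):
        cfg = FeatureConfig(n_components=5)
        vals = rng.standard_normal((6, 10)) + 1j * rng.standard_normal((6, 10))
        arr = block_features(_block(vals), cfg).as_array(cfg)
        assert arr.shape == (8,)
        # spectral magnitude stats come first, spatial phase stats last
        polar = polar_decompose(fft_along(_block(vals), "rf_spectral"), 5)
        assert arr[0] == pytest.approx(polar.magnitude.mean())
        assert arr[1] == pytest.approx(polar.magnitude.std())

    def test_matches_step_by_step_oracle(self, rng):
        """Independent recomputation: loop over rows/columns with the kernel
        DFT, truncate, polar-decompose and pool by hand."""
        cfg = FeatureConfig(n_components=40)
        vals = rng.standard_normal((80, 200)) + 1j * rng.standard_normal((80, 200))
        got = block_features(_block(vals), cfg).as_array(cfg)

        expect = []
        for axis in (1, 0):  # rf_spectral then spatial
            coeffs = dft_double_sum(vals, axis)
            kept = coeffs[:, :40] if axis == 1 else coeffs[:40, :]
            mag = np.hypot(kept.real, kept.imag).ravel()
            ph = np.arctan2(kept.imag, kept.real).ravel()
            for q in (mag, ph):
                expect += [q.mean(), np.sqrt(((q - q.mean()) ** 2).mean())]
        np.testing.assert_allclose(got, np.array(expect), rtol=1e-9)


class TestExtractFeatures:
    def test_whole_band_vector_length_is_80(self, full_scan):
        fv = extract_features(full_scan, FeatureConfig())
        assert fv.values.shape == (80,)
        assert fv.names[0] == "tx00_full_spec_mag_mean"

    def test_per_band_five_band_mask_gives_400(self, full_scan):
        cfg = FeatureConfig(mode="per_band", mask="1011 1100")
        fv = extract_features(full_scan, cfg)
        assert fv.values.shape == (8 * 10 * 5,)

    @pytest.mark.parametrize(
        "use_mag,use_phase,expected", [(True, True, 80), (True, False, 40), (False, True, 40)]
    )
    def test_flag_halving(self, full_scan, use_mag, use_phase, expected):
        cfg = FeatureConfig(use_magnitude=use_mag, use_phase=use_phase)
        assert extract_features(full_scan, cfg).values.shape == (expected,)

    def test_deterministic(self, full_scan):
        a = extract_features(full_scan)
        b = extract_features(full_scan)
        assert np.array_equal(a.values, b.values)

    def test_global_phase_factor(self, small_scan):
        """A global complex scale e^{j theta} leaves magnitude features exactly
        invariant and shifts every retained phase entry by theta (mod 2 pi)."""
        theta = 0.3
        rotated = make_random_scan(small_scan.geometry, np.random.default_rng(0))
        rotated.matrix = small_scan.matrix * np.exp(1j * theta)
        cfg = FeatureConfig(n_components=4, use_phase=False)
        a = extract_features(small_scan, cfg)
        b = extract_features(rotated, cfg)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)
        # per-entry phase shift, checked at the polar level
        from s21density.s21_io import split_by_transmitter

        blk = remove_dc_bias(split_by_transmitter(small_scan)[0])
        rot = remove_dc_bias(split_by_transmitter(rotated)[0])
        pa = polar_decompose(fft_along(blk, "rf_spectral"), 4).phase
        pb = polar_decompose(fft_along(rot, "rf_spectral"), 4).phase
        # k=0 is numerically zero after DC removal, so its phase is noise
        wrapped = np.angle(np.exp(1j * (pb[:, 1:] - pa[:, 1:] - theta)))
        np.testing.assert_allclose(wrapped, 0.0, atol=1e-9)


class TestStandardizer:
    def test_training_set_maps_to_zero_mean_unit_std(self, rng):
        X = rng.standard_normal((20, 7)) * 3.0 + 5.0
        std = Standardizer().fit(X)
        Z = std.transform(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_flagged_and_zeroed(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 4.2
        std = Standardizer().fit(X)
        assert std.zero_variance_mask_.tolist() == [False, True, False]
        assert np.all(std.transform(X)[:, 1] == 0.0)

    def test_vector_at_training_mean_maps_to_zero(self, rng):
        X = rng.standard_normal((12, 5))
        std = Standardizer().fit(X)
        fv = FeatureVector(values=X.mean(axis=0), names=tuple(f"f{i}" for i in range(5)))
        np.testing.assert_allclose(std.transform(fv).values, 0.0, atol=1e-12)

    def test_needs_two_vectors(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            Standardizer().fit(rng.standard_normal((1, 4)))


class TestSFFeatures:
    def test_forced_arithmetic(self):
        arr = sf_features(_block([[1, 2], [3, 4]]))
        mean, std, lo, hi, med, rng_, shannon = arr
        assert (mean, lo, hi, med, rng_) == (2.5, 1.0, 4.0, 2.5, 3.0)

    def test_uniform_magnitudes_reach_max_entropy(self):
        arr = sf_features(_block(np.full((2, 8), 3.0)))
        assert arr[-1] == pytest.approx(np.log(16))

    def test_all_zero_block_has_zero_entropy(self):
        assert sf_features(_block(np.zeros((2, 4))))[-1] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        vals = rng.standard_normal((6, 9)) + 1j * rng.standard_normal((6, 9))
        a = [abs(v) for row in vals for v in row]
        n = len(a)
        mean = sum(a) / n
        var = sum((x - mean) ** 2 for x in a) / n
        tot = sum(a)
        shannon = -sum((x / tot) * math.log(x / tot) for x in a if x > 0)
        expect = [mean, math.sqrt(var), min(a), max(a), float(np.median(a)),
                  max(a) - min(a), shannon]
        np.testing.assert_allclose(sf_features(_block(vals)), expect, rtol=1e-9)


class TestBlockPCA:
    def _scans(self, geometry, rng, n):
        return [make_random_scan(geometry, rng) for _ in range(n)]

    def test_rank_guard(self, small_geometry, rng):
        scans = self._scans(small_geometry, rng, 4)  # centred rank 3
        with pytest.raises(ValueError, match="rank"):
            BlockPCAExtractor(n_pcs=4).fit(scans)

    def test_training_mean_projects_to_zero(self, small_geometry, rng):
        scans = self._scans(small_geometry, rng, 8)
        ext = BlockPCAExtractor(n_pcs=3).fit(scans)
        # a synthetic scan whose |S21| equals the training mean magnitude
        mean_abs = np.mean([np.abs(s.matrix) for s in scans], axis=0)
        probe = make_random_scan(small_geometry, rng)
        probe.matrix = mean_abs.astype(complex)
        np.testing.assert_allclose(ext.transform([probe]), 0.0, atol=1e-9)

    def test_first_pc_matches_eigendecomposition(self, small_geometry, rng):
        """Dominant-axis variance agrees with a brute-force eigendecomposition
        of the covariance matrix (independent of sklearn)."""
        scans = self._scans(small_geometry, rng, 12)
        ext = BlockPCAExtractor(n_pcs=2).fit(scans)
        A = np.vstack([np.abs(s.matrix[: small_geometry.n_rx]).ravel() for s in scans])
        C = np.cov(A, rowvar=False, ddof=1)
        eigvals = np.linalg.eigvalsh(C)
        np.testing.assert_allclose(
            ext.pcas_[0].explained_variance_[0], eigvals[-1], rtol=1e-8
        )


class TestVectorLengthFormula:
    def test_formula_spot_checks(self, full_scan):
        for mask, mode, both, expected in [
            ("1111 1111", "per_band", True, 640),
            ("1000 0001", "per_band", True, 160),
            ("0100 0000", "per_band", False, 40),
            ("1111 1111", "whole_band", True, 80),
        ]:
            cfg = FeatureConfig(mode=mode, mask=mask, use_phase=both)
            assert feature_vector_length(10, cfg) == expected
            assert extract_features(full_scan, cfg).values.size == expected
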