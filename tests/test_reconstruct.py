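"""Reconstruction stages: segmentation, constraints, ASM / PCOF / ItPR."""

import inspect

import numpy as np
import pytest
from scipy import ndimage

from pcof import (
    BeadPhantomSpec,
    ComplexField,
    GridSpec,
    Hologram,
    PCOFParams,
    PhaseMap,
    ReferenceBeam,
    SupportMask,
    VarianceMap,
    apply_support,
    dc_filter,
    itpr_reconstruct,
    make_bead_phantom,
    pcof_reconstruct,
    phase_only,
    preprocess_hologram,
    recombine,
    reconstruct_asm,
    render_hologram,
    threshold_mask,
    unwrap_phase,
    variance_map,
)
import pcof.reconstruct as reconstruct_mod

from conftest import WAVELENGTH, PITCH, Z_RECORD


def variance_oracle(patch, mode="as-printed"):
    """Direct single-window evaluation of the variance statistic."""
    mu = patch.mean()
    if mode == "as-printed":
        return np.mean((patch**2 - mu) ** 2)
    return np.mean((patch - mu) ** 2)


class TestVarianceMap:
    def test_constant_phase_gives_zero(self):
        vmap = variance_map(np.zeros((16, 16)), m=5)
        np.testing.assert_allclose(vmap.values, 0.0, atol=1e-12)

    def test_worked_one_hot_window(self):
        """5x5 patch, phi=1 at center: V = (24*(1/25)^2 + (24/25)^2)/25 = 0.0384."""
        patch = np.zeros((5, 5))
        patch[2, 2] = 1.0
        assert variance_oracle(patch) == pytest.approx(0.038400)
        vmap = variance_map(np.pad(patch, 6), m=5)
        assert vmap.values[8, 8] == pytest.approx(0.038400)

    @pytest.mark.parametrize("mode", ["as-printed", "standard"])
    def test_interior_windows_match_direct_oracle(self, mode, rng):
        phi = rng.normal(size=(24, 24))
        vmap = variance_map(phi, m=5, mode=mode)
        for i, j in [(5, 5), (10, 17), (18, 3)]:
            window = phi[i - 2 : i + 3, j - 2 : j + 3]
            assert vmap.values[i, j] == pytest.approx(variance_oracle(window, mode))

    def test_nonnegative_for_arbitrary_input(self, rng):
        vmap = variance_map(rng.normal(size=(32, 32)) * 3, m=7)
        assert vmap.values.min() >= 0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            variance_map(np.zeros((16, 16)), m=4)
        with pytest.raises(ValueError):
            variance_map(np.zeros((16, 16)), m=17)


class TestThresholdMask:
    def test_all_zero_variance_gives_empty_mask(self):
        mask = threshold_mask(VarianceMap(np.zeros((8, 8)), window=5))
        assert not mask.values.any()

    def test_uniform_variance_above_tau_gives_full_mask(self):
        mask = threshold_mask(VarianceMap(np.full((8, 8), 2.0), window=5), fraction=0.5)
        assert mask.values.all()

    def test_strict_inequality_at_tau(self):
        v = np.array([[0.1, 0.6, 0.9]] * 3)
        mask = threshold_mask(VarianceMap(v, window=3), fraction=0.45)
        np.testing.assert_array_equal(mask.values[0], [0.0, 1.0, 1.0])
        # a pixel exactly at tau stays out
        v_tie = np.array([[0.5, 1.0]] * 2)
        mask_tie = threshold_mask(VarianceMap(v_tie, window=3), fraction=0.5)
        np.testing.assert_array_equal(mask_tie.values[0], [0.0, 1.0])

    def test_phase_max_mode_uses_phase_maximum(self):
        v = np.array([[0.3, 0.8]] * 2)
        phase = np.full((2, 2), 1.2)
        mask = threshold_mask(VarianceMap(v, window=3), phase, fraction=0.5, mode="phase-max")
        # tau = 0.6: only the 0.8 pixel survives
        np.testing.assert_array_equal(mask.values[0], [0.0, 1.0])

    def test_binarity_and_idempotence(self, rng):
        v = rng.random((16, 16))
        mask = threshold_mask(VarianceMap(v, window=5), fraction=0.5)
        assert set(np.unique(mask.values)) <= {0.0, 1.0}
        again = threshold_mask(VarianceMap(mask.values, window=5), fraction=0.5)
        np.testing.assert_array_equal(again.values, mask.values)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(VarianceMap(np.ones((4, 4)), window=3), fraction=1.5)


class TestSupportAndConstraints:
    def test_full_mask_no_blur_is_identity(self, rng):
        phi = PhaseMap(rng.normal(size=(16, 16)), wrapped=False)
        ones = SupportMask(np.ones((16, 16)), threshold=0.0, threshold_fraction=0.5)
        out = apply_support(phi, ones, blur_sigma=0.0)
        np.testing.assert_array_equal(out.values, phi.values)

    def test_zero_mask_zeroes_phase(self, rng):
        phi = PhaseMap(rng.normal(size=(16, 16)), wrapped=False)
        zeros = SupportMask(np.zeros((16, 16)), threshold=1.0, threshold_fraction=0.5)
        assert not apply_support(phi, zeros, blur_sigma=1.0).values.any()

    def test_blur_conserves_total(self, rng):
        phi = PhaseMap(np.abs(rng.normal(size=(32, 32))), wrapped=False)
        mask = SupportMask((rng.random((32, 32)) > 0.5).astype(float), 0.0, 0.5)
        masked_total = (phi.values * mask.values).sum()
        blurred = apply_support(phi, mask, blur_sigma=2.0)
        assert blurred.values.sum() == pytest.approx(masked_total, rel=1e-6)

    def test_phase_only_modulus_and_zero_convention(self, small_grid, rng):
        values = rng.normal(size=small_grid.shape) + 1j * rng.normal(size=small_grid.shape)
        values[0, 0] = 0.0
        values[1, 1] = 3.0 * np.exp(1j * np.pi / 4)
        out = phase_only(ComplexField(values, small_grid))
        np.testing.assert_allclose(np.abs(out.values), 1.0, atol=1e-12)
        assert out.values[0, 0] == 1.0 + 0.0j
        assert out.values[1, 1] == pytest.approx(np.exp(1j * np.pi / 4))

    def test_dc_filter_unit_and_scaled_reference(self, single_bead):
        _, holo = single_bead
        unit = ReferenceBeam(np.ones(holo.grid.shape, complex))
        np.testing.assert_array_equal(dc_filter(holo, unit).intensity, holo.intensity)
        twice = ReferenceBeam(np.full(holo.grid.shape, 2.0 + 0j))
        np.testing.assert_allclose(
            dc_filter(holo, twice).intensity, holo.intensity / 4.0
        )
        assert np.isfinite(dc_filter(holo, twice).intensity).all()

    def test_recombine_contracts(self, single_bead, rng):
        _, holo = single_bead
        grid = holo.grid
        real_positive = ComplexField(np.full(grid.shape, 2.5), grid)
        out = recombine(holo, real_positive)
        np.testing.assert_allclose(out.values.real, holo.intensity)
        np.testing.assert_allclose(out.values.imag, 0.0, atol=1e-12)
        fld = ComplexField(np.exp(1j * rng.uniform(-3, 3, grid.shape)), grid)
        out = recombine(holo, fld)
        np.testing.assert_allclose(np.abs(out.values), holo.intensity, atol=1e-12)
        nz = holo.intensity > 0
        np.testing.assert_allclose(
            np.angle(out.values)[nz], np.angle(fld.values)[nz], atol=1e-9
        )


class TestASM:
    def test_zero_phase_hologram_reconstructs_flat(self, bead_grid):
        holo = Hologram(np.ones(bead_grid.shape), bead_grid, Z_RECORD)
        result = reconstruct_asm(holo, bead_grid, Z_RECORD)
        assert np.abs(result.phase.values).max() < 1e-6

    def test_zero_distance_of_real_hologram_has_zero_phase(self, single_bead):
        _, holo = single_bead
        result = reconstruct_asm(holo, holo.grid, 0.0)
        assert np.abs(result.phase_wrapped.values).max() < 1e-12

    def test_bead_center_colocates_with_ground_truth(self, single_bead):
        obj, holo = single_bead
        result = reconstruct_asm(holo, holo.grid, Z_RECORD)
        w_rec = np.clip(result.phase.values, 0, None) ** 2
        w_true = obj.phase**2
        c_rec = ndimage.center_of_mass(w_rec)
        c_true = ndimage.center_of_mass(w_true)
        assert np.hypot(c_rec[0] - c_true[0], c_rec[1] - c_true[1]) < 1.0


class TestPCOF:
    def test_zero_phase_hologram_reconstructs_flat(self, bead_grid):
        holo = Hologram(np.ones(bead_grid.shape), bead_grid, Z_RECORD)
        result = pcof_reconstruct(holo, bead_grid, Z_RECORD)
        assert np.abs(result.phase.values).max() < 1e-3

    def test_single_pass_and_bounded_fft_usage(self, single_bead, monkeypatch):
        """PCOF is non-iterative: no iteration parameter, <= 4 propagations."""
        assert "n_iter" not in inspect.signature(pcof_reconstruct).parameters
        calls = []
        original = reconstruct_mod.propagate

        def counting(*args, **kwargs):
            calls.append(1)
            return original(*args, **kwargs)

        monkeypatch.setattr(reconstruct_mod, "propagate", counting)
        _, holo = single_bead
        pcof_reconstruct(holo, holo.grid, Z_RECORD)
        assert 1 <= len(calls) <= 4

    def test_background_ringing_below_asm(self, single_bead):
        """The support constraint must reduce twin-image ringing off-object."""
        obj, holo = single_bead
        asm = reconstruct_asm(holo, holo.grid, Z_RECORD)
        pcof = pcof_reconstruct(holo, holo.grid, Z_RECORD)
        off = ~ndimage.binary_dilation(obj.phase > 0, iterations=10)
        assert pcof.phase.values[off].std() < asm.phase.values[off].std()

    def test_parameter_record_is_complete(self, single_bead):
        _, holo = single_bead
        params = PCOFParams(window=7, threshold_fraction=0.4, blur_sigma=0.5)
        result = pcof_reconstruct(holo, holo.grid, Z_RECORD, params=params)
        assert result.params["window"] == 7
        assert result.params["threshold_fraction"] == 0.4
        assert result.params["z"] == Z_RECORD
        assert set(np.unique(result.diagnostics["support_mask"].values)) <= {0.0, 1.0}

    def test_invalid_distance_rejected(self, single_bead):
        _, holo = single_bead
        with pytest.raises(ValueError):
            pcof_reconstruct(holo, holo.grid, 0.0)


class TestItPR:
    def test_one_iteration_equals_manual_composition(self, single_bead):
        _, holo = single_bead
        grid = holo.grid
        result = itpr_reconstruct(holo, grid, Z_RECORD, n_iter=1)
        pre = preprocess_hologram(holo)
        u_obj = reconstruct_mod._backward(np.sqrt(pre.intensity), grid, Z_RECORD)
        phi = np.clip(
            reconstruct_mod.restoration.unwrap_phase(np.angle(u_obj.values)), 0, None
        )
        np.testing.assert_allclose(result.field.values, np.exp(1j * phi), atol=1e-10)

    def test_residual_non_increasing_on_noise_free_phantom(self, single_bead):
        _, holo = single_bead
        result = itpr_reconstruct(holo, holo.grid, Z_RECORD, n_iter=20)
        residuals = np.asarray(result.diagnostics["residuals"])
        assert len(residuals) == 20
        assert (np.diff(residuals) <= 1e-8).all()

    def test_zero_phase_hologram_residual_zero_at_first_iteration(self, bead_grid):
        holo = Hologram(np.ones(bead_grid.shape), bead_grid, Z_RECORD)
        result = itpr_reconstruct(holo, bead_grid, Z_RECORD, n_iter=1)
        assert result.diagnostics["residuals"][0] == pytest.approx(0.0, abs=1e-10)

    def test_invalid_iteration_count_rejected(self, single_bead):
        _, holo = single_bead
        with pytest.raises(ValueError):
            itpr_reconstruct(holo, holo.grid, Z_RECORD, n_iter=0)


class TestUnwrap:
    def test_smooth_map_unchanged(self):
        yy, xx = np.mgrid[0:32, 0:32]
        smooth = 0.02 * xx + 0.01 * yy  # stays well inside (-pi, pi)
        out = unwrap_phase(PhaseMap(smooth, wrapped=True))
        np.testing.assert_allclose(out.values, smooth, atol=1e-9)

    def test_recovers_wrapped_ramp_range(self):
        true_ramp = np.tile(0.4 * np.arange(100), (16, 1))
        wrapped = np.angle(np.exp(1j * true_ramp))
        out = unwrap_phase(PhaseMap(wrapped, wrapped=True))
        assert out.values.max() - out.values.min() == pytest.approx(39.6, abs=1e-6)

    def test_output_minus_input_in_two_pi_lattice(self, rng):
        phi = rng.uniform(-np.pi, np.pi, (24, 24))
        out = unwrap_phase(PhaseMap(phi, wrapped=True))
        delta = (out.values - phi) / (2 * np.pi)
        np.testing.assert_allclose(delta, np.round(delta), atol=1e-9 / (2 * np.pi))
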