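import dataclasses

import numpy as np
import pytest

from holodm import holosim, phantom, recon
from holodm.core import ComplexField, PhaseMap, radius_sq
from holodm.errors import ConfigError, MaskOverlapError, NoSidebandError

from conftest import SMALL_SHAPE, piston_removed, rms


def make_hologram(scene, seed=1, **cfg_kwargs):
    cfg_kwargs.setdefault("shape", scene.shape)
    cfg_kwargs.setdefault("frames_per_timepoint", 1)
    cfg = holosim.OpticalConfig(**cfg_kwargs)
    return holosim.acquire_timepoint(scene, cfg, 0.0, seed=seed)[0]


@pytest.fixture(scope="module")
def flat_scene():
    return phantom.Scene(cells=[], shape=SMALL_SHAPE)


class TestLocateSideband:
    def test_peak_within_one_bin_of_carrier(self, flat_scene):
        holo = make_hologram(flat_scene, carrier_cyc_per_px=(0.25, 0.25))
        sb = recon.locate_sideband(holo)
        ny, nx = holo.intensity.shape
        assert abs(sb.peak_cyc_per_px[0] - 0.25) <= 1.0 / nx
        assert abs(sb.peak_cyc_per_px[1] - 0.25) <= 1.0 / ny

    def test_constant_image_raises(self):
        with pytest.raises(NoSidebandError):
            recon.locate_sideband(np.full(SMALL_SHAPE, 3.0))

    def test_mirrored_carrier_maps_to_canonical_half_plane(self, flat_scene):
        holo = make_hologram(flat_scene, carrier_cyc_per_px=(-0.2, 0.1))
        sb = recon.locate_sideband(holo)
        ny, nx = holo.intensity.shape
        assert sb.peak_cyc_per_px[0] > 0
        assert abs(sb.peak_cyc_per_px[0] - 0.2) <= 1.0 / nx
        assert abs(sb.peak_cyc_per_px[1] + 0.1) <= 1.0 / ny


class TestExtractObjectWave:
    def test_flat_object_constant_phase(self, flat_scene, recon_params):
        holo = make_hologram(flat_scene)
        sb = recon.locate_sideband(holo)
        field = recon.extract_object_wave(holo, sb, recon_params)
        assert rms(piston_removed(field.phase)) < 1e-3

    def test_smooth_phantom_round_trip(self, recon_params):
        scene = phantom.random_scene(
            4, n_cells=8, shape=SMALL_SHAPE,
            radius_range_um=(8.0, 11.0), thickness_range_um=(2.0, 3.0),
            n_cell_range=(1.36, 1.375), margin_um=12.0,
        )
        truth = phantom.render_phase(scene, 0.532)
        assert truth.values.max() < np.pi  # wrap-free regime
        holo = make_hologram(scene)
        sb = recon.locate_sideband(holo)
        field = recon.extract_object_wave(holo, sb, recon_params)
        delta = piston_removed(recon.unwrap(field.phase).values - truth.values)
        assert rms(delta) < 0.01

    def test_subpixel_carrier_residual_tilt_below_one_fringe(
        self, flat_scene, recon_params
    ):
        holo = make_hologram(flat_scene, carrier_cyc_per_px=(0.2517, 0.2483))
        sb = recon.locate_sideband(holo)
        field = recon.extract_object_wave(holo, sb, recon_params)
        ph = recon.unwrap(field.phase).values
        assert ph.max() - ph.min() <= 2.0 * np.pi * 1.05  # <= one fringe across FOV

    def test_mask_overlapping_dc_rejected(self, flat_scene, recon_params):
        holo = make_hologram(flat_scene)
        sb = recon.SidebandInfo((0.25, 0.25), 0.05, 1.0)
        params = dataclasses.replace(recon_params, mask_radius_frac=0.999)
        bad = recon.SidebandInfo((0.01, 0.0), 0.005, 1.0)
        with pytest.raises(MaskOverlapError):
            # tiny carrier: even the default fraction cannot exclude DC by margin
            recon.extract_object_wave(holo, bad, params)
        # sane sideband passes
        recon.extract_object_wave(holo, sb, recon_params)

    def test_hard_disc_mask_also_works(self, recon_params):
        scene = phantom.random_scene(4, n_cells=6, shape=SMALL_SHAPE, margin_um=12.0)
        truth = phantom.render_phase(scene, 0.532)
        holo = make_hologram(scene)
        sb = recon.locate_sideband(holo)
        params = dataclasses.replace(recon_params, mask_shape="hard-disc")
        field = recon.extract_object_wave(holo, sb, params)
        delta = piston_removed(recon.unwrap(field.phase).values - truth.values)
        assert rms(delta) < 0.02


class TestCompensateSpherical:
    def test_zero_aberration_identity(self, flat_scene, recon_params):
        holo = make_hologram(flat_scene)
        sb = recon.locate_sideband(holo)
        field = recon.extract_object_wave(holo, sb, recon_params)
        out = recon.compensate_spherical(field, sb, recon_params)
        assert np.max(np.abs(np.angle(out.values * np.conj(field.values)))) < 1e-6

    def test_injected_quadratic_removed(self, flat_scene, recon_params):
        a = 3e-4
        holo = make_hologram(flat_scene, aberration_coeff_rad_per_px2=a)
        sb = recon.locate_sideband(holo)
        field = recon.extract_object_wave(holo, sb, recon_params)
        out = recon.compensate_spherical(field, sb, recon_params)
        resid = recon.unwrap(out.phase).values
        assert piston_removed(resid).std() < 0.02

    def test_coefficient_estimate_accuracy(self, flat_scene, recon_params):
        a = 2e-4
        holo = make_hologram(flat_scene, aberration_coeff_rad_per_px2=a)
        sb = recon.locate_sideband(holo)
        field = recon.extract_object_wave(holo, sb, recon_params)
        a_hat = recon.estimate_quadratic_coeff(field, sb)
        assert a_hat == pytest.approx(a, rel=0.01)

    def test_aberrated_phantom_mass_within_3pct(self, recon_params, dm_params, bg_params):
        from holodm import background, drymass

        scene = phantom.random_scene(
            6, n_cells=10, shape=SMALL_SHAPE,
            radius_range_um=(7.0, 10.0), margin_um=12.0,
        )

        def pipeline_mass(**kwargs):
            cfg = holosim.OpticalConfig(
                shape=SMALL_SHAPE, frames_per_timepoint=1, **kwargs
            )
            holos = holosim.acquire_timepoint(scene, cfg, 0.0, seed=2)
            pm = recon.reconstruct_stack(holos, recon_params, conjugate=True)
            pm = background.rolling_ball_subtract(pm, bg_params)
            return drymass.phase_map_dry_mass(pm, dm_params)

        clean = pipeline_mass()
        aberrated = pipeline_mass(aberration_coeff_rad_per_px2=2e-4)
        assert aberrated == pytest.approx(clean, rel=0.03)

    def test_beyond_nyquist_bound_warns_and_noop(self, recon_params):
        values = np.exp(1j * 1.2e-2 * radius_sq(SMALL_SHAPE))
        field = ComplexField(values, 0.879)
        sb = recon.SidebandInfo((0.25, 0.25), 0.17, 1.0)
        with pytest.warns(UserWarning):
            out = recon.compensate_spherical(field, sb, recon_params, coeff=1.2e-2)
        assert np.array_equal(out.values, field.values)


class TestRefocus:
    def test_z_zero_identity(self, recon_params):
        rng = np.random.default_rng(0)
        field = ComplexField(
            rng.standard_normal(SMALL_SHAPE) + 1j * rng.standard_normal(SMALL_SHAPE),
            0.879,
        )
        out = recon.refocus(field, 0.0, recon_params)
        assert np.array_equal(out.values, field.values)

    def test_plane_wave_eigenfunction(self, recon_params):
        field = ComplexField(np.full(SMALL_SHAPE, 0.8 + 0.0j), 0.879)
        out = recon.refocus(field, 37.0, recon_params)
        # same field up to one global phase factor
        ratio = out.values / field.values
        assert np.allclose(ratio, ratio[0, 0], atol=1e-9)
        assert abs(abs(ratio[0, 0]) - 1.0) < 1e-9

    def test_inverse_propagation_exact(self, recon_params):
        rng = np.random.default_rng(1)
        field = ComplexField(
            rng.standard_normal(SMALL_SHAPE) + 1j * rng.standard_normal(SMALL_SHAPE),
            0.879,
        )
        back = recon.refocus(recon.refocus(field, 40.0, recon_params), -40.0, recon_params)
        assert np.max(np.abs(back.values - field.values)) < 1e-9

    def test_energy_conservation(self, recon_params):
        rng = np.random.default_rng(2)
        field = ComplexField(
            rng.standard_normal(SMALL_SHAPE) + 1j * rng.standard_normal(SMALL_SHAPE),
            0.879,
        )
        out = recon.refocus(field, 55.0, recon_params)
        e0 = np.sum(np.abs(field.values) ** 2)
        e1 = np.sum(np.abs(out.values) ** 2)
        assert e1 == pytest.approx(e0, rel=1e-6)

    def test_defocused_hologram_refocused_round_trip(self, recon_params):
        scene = phantom.random_scene(
            5, n_cells=8, shape=SMALL_SHAPE, radius_range_um=(8.0, 11.0),
            margin_um=12.0,
        )
        truth = phantom.render_phase(scene, 0.532)
        holo = make_hologram(scene, defocus_um=40.0)
        params = dataclasses.replace(recon_params, refocus_z_um=-40.0)
        pm = recon.reconstruct_stack([holo], params, conjugate=True)
        delta = piston_removed(pm.values - truth.values)
        assert rms(delta) < 0.02


class TestUnwrap:
    def test_no_wraps_identity(self):
        # smooth wrap-free field (white noise is not a coherent phase field)
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(0)
        data = gaussian_filter(rng.standard_normal((64, 64)), 4.0)
        data *= 2.0 / np.max(np.abs(data))
        out = recon.unwrap(data).values
        k = round(float((out - data).mean()) / (2 * np.pi))
        assert np.allclose(out - 2 * np.pi * k, data, atol=1e-9)

    def test_wrapped_ramp_reconstructed(self):
        truth = np.broadcast_to(np.linspace(0.0, 6 * np.pi, 256), (64, 256)).copy()
        wrapped = np.angle(np.exp(1j * truth))
        out = recon.unwrap(wrapped).values
        k = round(float((out - truth).mean()) / (2 * np.pi))
        assert np.max(np.abs(out - 2 * np.pi * k - truth)) < 1e-6

    def test_congruence_mod_2pi(self):
        rng = np.random.default_rng(3)
        wrapped = rng.uniform(-np.pi, np.pi, (64, 64))
        out = recon.unwrap(wrapped).values
        assert np.allclose(
            np.angle(np.exp(1j * (out - wrapped))), 0.0, atol=1e-9
        )

    def test_wrapping_cell_peak_recovered(self, recon_params):
        # peak phase ~7 rad wraps once through the interferometric chain
        d = 7.0 * 0.532 / (2 * np.pi * 0.04)
        cell = phantom.PhantomCell((112.0, 84.0), 22.0, d, 1.377)
        scene = phantom.Scene(cells=[cell], n_medium=1.337, shape=SMALL_SHAPE)
        truth = phantom.render_phase(scene, 0.532)
        assert truth.values.max() > 2 * np.pi
        holo = make_hologram(scene)
        pm = recon.reconstruct_stack([holo], recon_params, conjugate=True)
        delta = pm.values - truth.values
        k = round(float(np.median(delta)) / (2 * np.pi))
        assert abs(pm.values.max() - 2 * np.pi * k - truth.values.max()) < 0.05


class TestAveragePhases:
    def test_identical_maps(self):
        m = PhaseMap(np.ones((32, 32)), 1.0)
        out = recon.average_phases([m] * 15)
        assert np.array_equal(out.values, m.values)

    def test_mean_of_offset_pair(self):
        base = np.random.default_rng(0).uniform(size=(32, 32))
        a = PhaseMap(base, 1.0)
        b = PhaseMap(base + 0.6, 1.0)
        assert np.allclose(recon.average_phases([a, b]).values, base + 0.3)

    def test_noise_reduction_sqrt_n(self):
        rng = np.random.default_rng(7)
        sigma = 0.2
        truth = rng.uniform(size=(384, 512))
        maps = [
            PhaseMap(truth + sigma * rng.standard_normal(truth.shape), 0.879)
            for _ in range(15)
        ]
        resid = recon.average_phases(maps).values - truth
        assert resid.std() == pytest.approx(sigma / np.sqrt(15), rel=0.15)

    def test_geometry_mismatch(self):
        with pytest.raises(ConfigError):
            recon.average_phases(
                [PhaseMap(np.ones((32, 32)), 1.0), PhaseMap(np.ones((32, 16)), 1.0)]
            )

    def test_empty_list(self):
        with pytest.raises(ConfigError):
            recon.average_phases([])


class TestPipelineInvariants:
    def test_end_to_end_oracle(self, small_ground_truth, small_reconstruction):
        assert small_ground_truth.values.max() < np.pi
        delta = piston_removed(
            small_reconstruction.values - small_ground_truth.values
        )
        assert rms(delta) < 0.01

    def test_linearity(self, recon_params):
        scene = phantom.random_scene(
            8, n_cells=6, shape=SMALL_SHAPE, thickness_range_um=(1.0, 1.5),
            margin_um=12.0,
        )
        doubled = phantom.Scene(
            cells=[
                dataclasses.replace(c, max_thickness_um=2 * c.max_thickness_um)
                for c in scene.cells
            ],
            n_medium=scene.n_medium,
            shape=scene.shape,
            pixel_pitch_um=scene.pixel_pitch_um,
        )
        rec1 = recon.reconstruct_stack([make_hologram(scene)], recon_params, conjugate=True)
        rec2 = recon.reconstruct_stack([make_hologram(doubled)], recon_params, conjugate=True)
        delta = piston_removed(rec2.values - 2.0 * rec1.values)
        signal = piston_removed(rec2.values)
        assert rms(delta) < 0.01 * max(rms(signal), 1.0)

    def test_tilt_invariance(self, recon_params):
        scene = phantom.random_scene(9, n_cells=6, shape=SMALL_SHAPE, margin_um=12.0)
        rec_a = recon.reconstruct_stack(
            [make_hologram(scene, carrier_cyc_per_px=(0.25, 0.25))],
            recon_params,
            conjugate=True,
        )
        rec_b = recon.reconstruct_stack(
            [make_hologram(scene, carrier_cyc_per_px=(0.28125, 0.21875))],
            recon_params,
            conjugate=True,
        )
        assert rms(piston_removed(rec_a.values - rec_b.values)) < 0.01

    def test_auto_conjugate_sign(self, small_scene, small_optical, recon_params):
        holos = holosim.acquire_timepoint(small_scene, small_optical, 0.0, seed=1)
        auto = recon.reconstruct_stack(holos, recon_params, conjugate="auto")
        manual = recon.reconstruct_stack(holos, recon_params, conjugate=True)
        assert np.allclose(auto.values, manual.values)
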