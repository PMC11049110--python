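"""QPI reconstruction: carrier detection, demodulation, unwrapping,
refocusing and stack averaging, checked against the forward model."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from sklearn.base import clone

from holotox.holography import NoiseSpec, synthesize_hologram_stack
from holotox.optics import OpticalConfig
from holotox.reconstruction import (
    ComplexField,
    HologramReconstructor,
    NoSidebandError,
    _soft_disk_mask,
    average_phase_stack,
    demodulate_to_phase,
    locate_carrier,
    reconstruct_stack,
    refocus_autofocus,
    unwrap_phase,
)
from holotox.propagation import propagate_angular_spectrum
from holotox.scenes import generate_phase_scene


class TestLocateCarrier:
    def test_recovers_synthetic_carrier(self, optics_default, scene_default):
        stack = synthesize_hologram_stack(
            scene_default, optics_default, NoiseSpec.off(), seed=0
        )
        est = locate_carrier(stack.frames[0])
        n = max(optics_default.shape)
        assert abs(est[0] - 0.25) < 1.0 / (2 * n)
        assert abs(est[1] - 0.15) < 1.0 / (2 * n)

    def test_pure_dc_image_raises(self):
        with pytest.raises(NoSidebandError):
            locate_carrier(np.ones((64, 64)))

    def test_returns_half_plane_representative(self, optics_small, scene_small):
        """A real hologram has Hermitian sidebands at +-f; fx > 0 is returned."""
        stack = synthesize_hologram_stack(
            scene_small, optics_small, NoiseSpec.off(), seed=0
        )
        est = locate_carrier(stack.frames[0])
        assert est[0] > 0


class TestDemodulate:
    def test_in_focus_phase_rmse_under_0_05(self, optics_default, scene_default):
        stack = synthesize_hologram_stack(
            scene_default, optics_default, NoiseSpec.off(), seed=1
        )
        carrier = locate_carrier(stack.frames[0])
        _, wrapped = demodulate_to_phase(stack.frames[0], carrier, config=optics_default)
        from holotox.reconstruction import remove_background_plane

        phase = remove_background_plane(unwrap_phase(wrapped))
        b = 16
        rmse = np.sqrt(
            np.mean((phase[b:-b, b:-b] - scene_default.phase_map[b:-b, b:-b]) ** 2)
        )
        assert rmse < 0.05

    def test_zero_phase_scene_reconstructs_to_zero(self, optics_small):
        scene = generate_phase_scene(optics_small, n_cells=0, seed=0)
        stack = synthesize_hologram_stack(scene, optics_small, NoiseSpec.off(), seed=0)
        carrier = locate_carrier(stack.frames[0])
        _, wrapped = demodulate_to_phase(stack.frames[0], carrier, config=optics_small)
        assert abs(float(np.mean(wrapped))) < 0.01

    def test_linearity_in_scene_phase(self, optics_small, scene_small):
        """Doubling the object phase doubles the reconstruction."""
        from holotox.scenes import PhaseScene

        half = PhaseScene(
            phase_map=0.5 * scene_small.phase_map,
            pixel_area_um2=scene_small.pixel_area_um2,
            true_total_dry_mass_pg=0.5 * scene_small.true_total_dry_mass_pg,
            cell_count=scene_small.cell_count,
        )
        recon = {}
        for name, sc in (("half", half), ("full", scene_small)):
            stack = synthesize_hologram_stack(sc, optics_small, NoiseSpec.off(), seed=2)
            qpi = reconstruct_stack(stack)
            recon[name] = qpi.phase
        b = 8
        diff = 2.0 * recon["half"][b:-b, b:-b] - recon["full"][b:-b, b:-b]
        assert np.sqrt(np.mean(diff**2)) < 0.02

    def test_filter_overlapping_dc_raises(self, optics_small, scene_small):
        stack = synthesize_hologram_stack(scene_small, optics_small, NoiseSpec.off(), seed=0)
        cmag = optics_small.carrier_magnitude
        with pytest.raises(ValueError, match="overlaps the DC"):
            demodulate_to_phase(
                stack.frames[0], optics_small.carrier_frequency, filter_radius=1.1 * cmag
            )

    def test_spectral_filtering_never_increases_power(self, rng):
        image = rng.standard_normal((64, 64))
        spec = np.fft.fft2(image)
        mask = _soft_disk_mask((64, 64), 0.2)
        assert np.sum(np.abs(spec * mask) ** 2) <= np.sum(np.abs(spec) ** 2)


class TestUnwrap:
    def test_ramp_beyond_2pi_recovered(self):
        ramp = np.tile(np.linspace(0, 6 * np.pi, 128), (32, 1))
        wrapped = np.angle(np.exp(1j * ramp))
        un = unwrap_phase(wrapped)
        offset = un[0, 0] - ramp[0, 0]
        assert offset == pytest.approx(2 * np.pi * round(offset / (2 * np.pi)), abs=1e-9)
        assert np.allclose(un - offset, ramp, atol=1e-6)

    def test_wrap_free_input_is_identity_up_to_2pi(self, rng):
        smooth = gaussian_filter(rng.standard_normal((64, 64)), 8)
        smooth *= 0.4 / smooth.std()
        un = unwrap_phase(np.angle(np.exp(1j * smooth)))
        resid = un - smooth
        k = np.median(resid) / (2 * np.pi)
        assert np.allclose(resid, 2 * np.pi * round(k), atol=1e-9)

    def test_tall_cell_peak_recovered(self):
        """A 5-rad cell wraps; unwrapping restores the peak."""
        yy, xx = np.mgrid[0:128, 0:128]
        r = np.hypot(yy - 64, xx - 64)
        phi = np.where(r < 30, 5.0 * np.cos(np.pi * r / 60) ** 2, 0.0)
        un = unwrap_phase(np.angle(np.exp(1j * phi)))
        un -= np.median(un[r > 40])
        assert abs(un.max() - 5.0) < 0.05


class TestRefocus:
    def _field(self, optics, scene, defocus):
        stack = synthesize_hologram_stack(
            scene, optics, NoiseSpec.off(), seed=1, defocus_um=defocus
        )
        carrier = locate_carrier(stack.frames[0])
        f, _ = demodulate_to_phase(stack.frames[0], carrier, config=optics)
        return f

    def test_recovers_introduced_defocus(self, optics_default, scene_default):
        f = self._field(optics_default, scene_default, defocus=40.0)
        _, dist, _ = refocus_autofocus(f, (-100.0, 100.0), steps=41)
        step = 200.0 / 40
        assert abs(dist - (-40.0)) <= step

    def test_zero_distance_is_identity(self, optics_small, scene_small):
        f = self._field(optics_small, scene_small, defocus=0.0)
        out = propagate_angular_spectrum(
            f.values, 0.0, f.wavelength_um, f.pixel_pitch_x_um, f.pixel_pitch_y_um
        )
        assert np.array_equal(out, f.values)

    def test_propagation_round_trip_unitary(self, optics_small, scene_small):
        f = self._field(optics_small, scene_small, defocus=0.0)
        fwd = propagate_angular_spectrum(
            f.values, 37.0, f.wavelength_um, f.pixel_pitch_x_um, f.pixel_pitch_y_um
        )
        back = propagate_angular_spectrum(
            fwd, -37.0, f.wavelength_um, f.pixel_pitch_x_um, f.pixel_pitch_y_um
        )
        assert np.abs(back - f.values).max() / np.abs(f.values).max() < 1e-6

    def test_too_few_steps_raises(self, optics_small, scene_small):
        f = self._field(optics_small, scene_small, defocus=0.0)
        with pytest.raises(ValueError):
            refocus_autofocus(f, (-10.0, 10.0), steps=2)

    def test_constant_field_ties_flagged_smallest_distance(self):
        f = ComplexField(
            values=np.ones((32, 32), dtype=complex),
            pixel_pitch_x_um=1.0,
            pixel_pitch_y_um=1.0,
            wavelength_um=0.532,
        )
        _, dist, tie = refocus_autofocus(f, (-10.0, 10.0), steps=5)
        assert tie
        assert dist == 0.0


class TestAveraging:
    def test_single_frame_identity(self):
        frame = np.zeros((32, 32))
        frame[10:14, 10:14] = 1.0
        qpi = average_phase_stack([frame])
        resid = qpi.phase - frame
        assert resid.std() == pytest.approx(0.0, abs=1e-12)  # constant offset only
        assert qpi.n_frames_averaged == 1

    def test_2pi_offsets_removed(self, rng):
        """Frames differing by a 2 pi piston average without offset bias."""
        base = gaussian_filter(rng.standard_normal((64, 64)), 6)
        qpi = average_phase_stack([base, base + 2 * np.pi])
        resid = qpi.phase - base
        assert resid.std() == pytest.approx(0.0, abs=1e-9)

    def test_speckle_reduced_by_sqrt_n(self):
        """10-frame averaging of independent speckle shrinks std ~ sqrt(10)."""
        ratios = []
        for s in range(50):
            r = np.random.default_rng(s)
            frames = []
            for _ in range(10):
                n = gaussian_filter(r.standard_normal((128, 128)), 4, mode="wrap")
                frames.append(0.1 * (n - n.mean()) / n.std())
            qpi = average_phase_stack(frames)
            ratios.append(np.std(frames[0]) / np.std(qpi.phase))
        mean_ratio = float(np.mean(ratios))
        assert abs(mean_ratio - np.sqrt(10)) / np.sqrt(10) < 0.2

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            average_phase_stack(np.empty((0, 8, 8)))


class TestReconstructorEstimator:
    def test_sklearn_contract(self, optics_small, scene_small):
        stack = synthesize_hologram_stack(scene_small, optics_small, NoiseSpec.off(), seed=0)
        est = HologramReconstructor(config=optics_small)
        cloned = clone(est)
        assert cloned.get_params()["config"] == optics_small
        phase = est.fit(stack.frames).transform(stack.frames)
        assert phase.shape == optics_small.shape
        assert hasattr(est, "carrier_")
        b = 8
        rmse = np.sqrt(
            np.mean((phase[b:-b, b:-b] - scene_small.phase_map[b:-b, b:-b]) ** 2)
        )
        assert rmse < 0.1  # 128 px grid: coarser spectral resolution than 512

    def test_transform_before_fit_raises(self, optics_small):
        with pytest.raises(RuntimeError):
            HologramReconstructor(config=optics_small).transform(np.zeros((1, 128, 128)))
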