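"""Plate simulation identities, layouts, and file round trips."""

import numpy as np
import pandas as pd
import pytest

from holotox import io
from holotox.assays import ldh_release_percent, ldh_slopes_table, wst8_viability
from holotox.holography import NoiseSpec, synthesize_hologram_stack
from holotox.layout import PlateLayout, Well, WellRole, make_dose_layout
from holotox.plates_sim import PlateNoise, simulate_absorbance_plate
from holotox.scenes import generate_phase_scene
from holotox.truth import DoseEffectTruth, Endpoint


@pytest.fixture(scope="module")
def truths():
    return (
        DoseEffectTruth(ec50_true=10.0, endpoint=Endpoint.viability),
        DoseEffectTruth(ec50_true=30.0, endpoint=Endpoint.death),
    )


@pytest.fixture(scope="module")
def layout():
    return make_dose_layout(np.geomspace(1.0, 512.0, 6))


class TestPlateSimulation:
    def test_negative_controls_normalize_to_exactly_100_viability(self, layout, truths):
        wst8, _ = simulate_absorbance_plate(
            layout, *truths, noise=PlateNoise.off(), seed=0
        )
        out = wst8_viability(wst8)
        neg = out[out["role"] == "negative_control"]["viability_pct"]
        assert (neg == 100.0).all()

    def test_positive_controls_normalize_to_exactly_100_release(self, layout, truths):
        _, ldh = simulate_absorbance_plate(layout, *truths, noise=PlateNoise.off(), seed=0)
        slopes = ldh_slopes_table(ldh)
        out = ldh_release_percent(slopes)
        pos = out[out["role"] == "positive_control"]["release_pct"]
        np.testing.assert_allclose(pos, 100.0, atol=1e-9)
        neg = out[out["role"] == "negative_control"]["release_pct"]
        np.testing.assert_allclose(neg, 0.0, atol=1e-9)

    def test_half_death_gives_50_percent_release(self, truths):
        """A well whose true death fraction is 0.5 reads back as 50%."""
        viability, death = truths
        layout = make_dose_layout([death.ec50_true])  # response(ec50) = 0.5
        _, ldh = simulate_absorbance_plate(
            layout, viability, death, noise=PlateNoise.off(), seed=0
        )
        out = ldh_release_percent(ldh_slopes_table(ldh))
        sample = out[out["role"] == "sample"]["release_pct"]
        np.testing.assert_allclose(sample, 50.0, atol=1e-6)

    def test_noise_free_responses_monotone_in_dose(self, layout, truths):
        wst8, ldh = simulate_absorbance_plate(
            layout, *truths, noise=PlateNoise.off(), seed=0
        )
        v = wst8_viability(wst8)
        per_dose = (
            v[v["role"] == "sample"].groupby("concentration")["viability_pct"].mean()
        )
        assert np.all(np.diff(per_dose.to_numpy()) <= 0)
        r = ldh_release_percent(ldh_slopes_table(ldh))
        per_dose = (
            r[r["role"] == "sample"].groupby("concentration")["release_pct"].mean()
        )
        assert np.all(np.diff(per_dose.to_numpy()) >= 0)

    def test_determinism(self, layout, truths):
        a = simulate_absorbance_plate(layout, *truths, seed=9)
        b = simulate_absorbance_plate(layout, *truths, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_plateau_option_keeps_slope_recoverable(self, layout, truths):
        _, ldh = simulate_absorbance_plate(
            layout, *truths, noise=PlateNoise.off(), seed=0, ldh_plateau_start_min=18.0
        )
        slopes = ldh_slopes_table(ldh)
        pos = slopes[slopes["role"] == "positive_control"]
        assert (pos["linear_end"] <= 18.0).all()
        out = ldh_release_percent(slopes)
        np.testing.assert_allclose(
            out[out["role"] == "positive_control"]["release_pct"], 100.0, atol=1e-6
        )

    def test_missing_positive_control_raises(self, truths):
        layout = make_dose_layout([1.0, 2.0, 4.0, 8.0], n_positive=0)
        with pytest.raises(ValueError, match="positive_control"):
            simulate_absorbance_plate(layout, *truths, seed=0)


class TestLayout:
    def test_requires_negative_and_background(self):
        with pytest.raises(ValueError, match="negative_control"):
            PlateLayout(wells=[Well(well_id="A1", role=WellRole.background)])
        with pytest.raises(ValueError, match="background"):
            PlateLayout(wells=[Well(well_id="A1", role=WellRole.negative_control)])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PlateLayout(
                wells=[
                    Well(well_id="A1", role=WellRole.background),
                    Well(well_id="A1", role=WellRole.negative_control),
                ]
            )

    def test_frame_round_trip(self, layout):
        df = layout.to_frame()
        back = PlateLayout.from_frame(df)
        assert back == layout

    def test_yaml_round_trip(self, layout, tmp_path):
        path = tmp_path / "layout.yaml"
        io.layout_to_yaml(layout, path)
        back = io.layout_from_yaml(path)
        assert back == layout

    def test_zero_dose_sample_wells_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            make_dose_layout([0.0, 1.0])


class TestImageIO:
    def test_hologram_stack_round_trip(self, optics_small, scene_small, tmp_path):
        stack = synthesize_hologram_stack(scene_small, optics_small, NoiseSpec.off(), seed=0)
        path = tmp_path / "stack.tif"
        saturated = io.save_hologram_stack(stack, path)
        assert saturated == 0
        back = io.load_hologram_stack(path)
        assert back.config == optics_small
        # 16-bit quantization: worst-case error is half an LSB of full scale
        assert np.abs(back.frames - stack.frames).max() <= 0.5 / 65535

    def test_saturation_warning_and_count(self, optics_small, scene_small, tmp_path):
        stack = synthesize_hologram_stack(scene_small, optics_small, NoiseSpec.off(), seed=0)
        stack.frames[0, :4, :4] = 2.0  # overexposed corner
        with pytest.warns(UserWarning, match="saturated"):
            n = io.save_hologram_stack(stack, tmp_path / "sat.tif")
        assert n == 16

    def test_phase_tiff_round_trip(self, tmp_path):
        from holotox.reconstruction import QPIImage

        qpi = QPIImage(
            phase=np.linspace(0, 1, 64).reshape(8, 8),
            pixel_area_um2=0.83,
            n_frames_averaged=10,
            provenance={"carrier_cpp": [0.25, 0.15]},
        )
        path = tmp_path / "phase.tif"
        io.save_phase_tiff(qpi, path)
        back = io.load_phase_tiff(path)
        np.testing.assert_allclose(back.phase, qpi.phase, atol=1e-7)
        assert back.pixel_area_um2 == qpi.pixel_area_um2
        assert back.n_frames_averaged == 10

    def test_missing_sidecar_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "orphan.tif", np.zeros((8, 8), dtype=np.uint16))
        with pytest.raises(FileNotFoundError):
            io.load_hologram_stack(tmp_path / "orphan.tif")


class TestPlateCSV:
    def test_wst8_round_trip(self, layout, truths, tmp_path):
        wst8, _ = simulate_absorbance_plate(layout, *truths, seed=0)
        path = tmp_path / "wst8.csv"
        io.write_plate_csv(wst8, path)
        back = io.read_wst8_csv(path)
        pd.testing.assert_frame_equal(back, wst8)

    def test_ldh_round_trip_and_validation(self, layout, truths, tmp_path):
        _, ldh = simulate_absorbance_plate(layout, *truths, seed=0)
        path = tmp_path / "ldh.csv"
        io.write_plate_csv(ldh, path)
        back = io.read_ldh_csv(path)
        pd.testing.assert_frame_equal(back, ldh)
        # duplicate time stamps named in the error
        bad = ldh.copy()
        bad.loc[1, "minute"] = bad.loc[0, "minute"]
        io.write_plate_csv(bad, path)
        with pytest.raises(ValueError, match="duplicate time"):
            io.read_ldh_csv(path)

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"well_id": ["A1"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            io.read_wst8_csv(path)
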