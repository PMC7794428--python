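import numpy as np
import pytest
from scipy import stats

from coralcasa import (
    FertParams,
    FieldGeometry,
    MotilityMixture,
    OpticsSpec,
    link_detections,
    render_frames,
    segment_stack,
    simulate_tracks,
    synth_fert_dataset,
)
from coralcasa.settings import CasaSettings
from coralcasa.simulator import CalibrationError

from conftest import make_truth


def all_static_mixture(**kwargs) -> MotilityMixture:
    return MotilityMixture(
        fraction_static=1.0,
        fraction_slow=0.0,
        fraction_motile=0.0,
        fraction_progressive=0.0,
        **kwargs,
    )


class TestSimulateTracks:
    def test_all_static_cells_respect_displacement_bound(self):
        truth = simulate_tracks(all_static_mixture(seed=7))
        assert truth.n_frames == 45
        assert len(truth.cells) > 0
        for cell in truth.cells:
            assert cell.max_displacement_um < 0.8 * cell.head_diameter_um

    def test_poisson_cell_count_mean_and_variance(self):
        # expected count: 2e7 cells/mL x (640x480x20 µm^3 = 6.144e-6 mL)
        expected = 2.0e7 * 640 * 480 * 20 * 1e-12
        assert expected == pytest.approx(122.88)
        mixture = MotilityMixture(concentration_cells_ml=2.0e7)
        # two-frame captures: the placed count is drawn before any motion
        counts = np.array(
            [
                len(simulate_tracks(mixture, capture_duration_s=2 / 60.0, seed=s).cells)
                for s in range(500)
            ]
        )
        se = np.sqrt(expected / 500)
        assert abs(counts.mean() - expected) < 3 * se
        # Poisson placement: variance/mean ratio near 1
        assert 0.7 < counts.var(ddof=1) / counts.mean() < 1.3

    def test_seed_determinism(self):
        mixture = MotilityMixture()
        a = simulate_tracks(mixture, seed=42)
        b = simulate_tracks(mixture, seed=42)
        assert len(a.cells) == len(b.cells)
        for ca, cb in zip(a.cells, b.cells):
            assert ca.motility_class == cb.motility_class
            assert ca.head_area_um2 == cb.head_area_um2
            np.testing.assert_array_equal(ca.positions, cb.positions)

    def test_n_frames_rounding(self):
        truth = simulate_tracks(MotilityMixture(seed=0), capture_duration_s=0.75,
                                frame_rate_hz=60.0)
        assert truth.n_frames == 45

    def test_every_step_finite_and_tracks_truncated_inside_field(self):
        mixture = MotilityMixture(seed=5, drift_velocity_um_s=(40.0, 0.0))
        truth = simulate_tracks(mixture, seed=5)
        geom = truth.geometry
        for cell in truth.cells:
            assert np.isfinite(cell.positions).all()
            assert (cell.positions[:, 0] >= 0).all()
            assert (cell.positions[:, 0] <= geom.width_um).all()
            assert (cell.positions[:, 1] >= 0).all()
            assert (cell.positions[:, 1] <= geom.height_um).all()
            assert len(cell.frames) == len(cell.positions)

    def test_zero_area_field_rejected(self):
        with pytest.raises(ValueError):
            FieldGeometry(width_um=0.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            simulate_tracks(MotilityMixture(seed=0), capture_duration_s=-1.0)


class TestMixtureValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MotilityMixture(fraction_static=0.5, fraction_slow=0.5,
                            fraction_motile=0.5, fraction_progressive=0.0)

    @pytest.mark.parametrize(
        "cls,rng",
        [
            ("slow", (5.0, 25.0)),      # crosses the 20 µm/s bound
            ("motile", (15.0, 70.0)),   # dips below 20
            ("motile", (30.0, 90.0)),   # exceeds 80
            ("progressive", (80.0, 120.0)),  # 80 itself is motile
        ],
    )
    def test_speed_ranges_must_sit_inside_bins(self, cls, rng):
        speeds = dict(MotilityMixture().speed_range_um_s)
        speeds[cls] = rng
        with pytest.raises(ValueError, match="classification bin"):
            MotilityMixture(speed_range_um_s=speeds)

    def test_concentration_must_be_positive(self):
        with pytest.raises(ValueError, match="concentration"):
            MotilityMixture(concentration_cells_ml=0.0)


class TestRenderFrames:
    def test_single_static_cell_one_component_every_frame(self, static_truth_one_cell):
        stack = render_frames(
            static_truth_one_cell, OpticsSpec(noise_sd=0.0, bloom_count=0)
        )
        assert stack.frames.shape == (45, 480, 640)
        from scipy import ndimage

        for frame in stack.frames:
            _, n = ndimage.label(frame > 0.2)
            assert n == 1

    def test_blooms_are_static_and_saturated(self, static_truth_one_cell):
        optics = OpticsSpec(noise_sd=0.0, bloom_count=2, seed=11)
        stack = render_frames(static_truth_one_cell, optics)
        from scipy import ndimage

        reference = None
        for frame in stack.frames:
            saturated = frame >= optics.saturation
            labels, n = ndimage.label(saturated)
            assert n == 2
            centroids = sorted(ndimage.center_of_mass(saturated, labels, [1, 2]))
            if reference is None:
                reference = centroids
            else:
                assert centroids == reference

    def test_rendered_then_redetected_recovers_track_count(self, settings):
        # three swimmers spaced far beyond 2 x cell_travel_max at all times
        n = 45
        t = np.arange(n)
        paths = [
            np.column_stack([50 + 2.0 * t, np.full(n, 60.0)]),
            np.column_stack([300 + 1.5 * t, 200 + 1.5 * t]),
            np.column_stack([np.full(n, 500.0), 400 - 2.0 * t]),
        ]
        truth = make_truth([("progressive", 15.0, p) for p in paths])
        stack = render_frames(truth, OpticsSpec(noise_sd=0.0))
        detections = segment_stack(stack, settings)
        tracks = link_detections(detections, settings.cell_travel_max_um)
        assert len(tracks) == len(truth.cells)

    def test_calibration_too_coarse_raises(self, static_truth_one_cell):
        with pytest.raises(CalibrationError):
            render_frames(static_truth_one_cell, OpticsSpec(microns_per_pixel=4.0))

    def test_render_determinism(self, static_truth_one_cell):
        optics = OpticsSpec(noise_sd=0.05, bloom_count=1, seed=3)
        a = render_frames(static_truth_one_cell, optics)
        b = render_frames(static_truth_one_cell, optics)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_amplitude_below_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            OpticsSpec(spot_amplitude=0.05, background=0.1)


class TestSynthFertDataset:
    def test_noiseless_positive_slope_gives_r_one(self):
        # huge egg counts make the cleavage-count quantisation negligible
        params = FertParams(intercept=0.0, slope=20.0, noise_sd=0.0,
                            n_records=30, ratio_range=(1.5, 4.5),
                            egg_range=(100_000, 100_001), seed=1)
        records = synth_fert_dataset(params)
        log_ratio = np.log10([r.ratio_cells_per_egg for r in records])
        rates = [r.fertilisation_rate_pct for r in records]
        r, _ = stats.pearsonr(log_ratio, rates)
        assert r == pytest.approx(1.0, abs=1e-5)

    def test_zero_slope_gives_null_correlation(self):
        params = FertParams(intercept=50.0, slope=0.0, noise_sd=5.0,
                            n_records=1000, seed=2)
        records = synth_fert_dataset(params)
        log_ratio = np.log10([r.ratio_cells_per_egg for r in records])
        rates = [r.fertilisation_rate_pct for r in records]
        r, _ = stats.pearsonr(log_ratio, rates)
        assert abs(r) < 0.1

    def test_seed_determinism(self):
        params = FertParams(seed=9)
        a = synth_fert_dataset(params)
        b = synth_fert_dataset(params)
        assert a == b

    def test_success_clipped_to_0_100(self):
        params = FertParams(intercept=90.0, slope=20.0, noise_sd=30.0,
                            n_records=200, seed=3)
        for record in synth_fert_dataset(params):
            assert 0.0 <= record.fertilisation_rate_pct <= 100.0
            assert record.n_cleaved + record.n_uncleaved == record.n_eggs

    def test_empty_ratio_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            FertParams(ratio_range=(3.0, 3.0))

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="n_records"):
            FertParams(n_records=2)
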