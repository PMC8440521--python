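"""Forward-model rendering: photometry, noise model, dataset generation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from fusionmode import ImagingParams, KineticParams, ReporterModel
from fusionmode.kinetics import EventKinetics, simulate_event_kinetics
from fusionmode.params import ParameterError
from fusionmode.render import (ChannelSpec, default_channels, disk_mask,
                               generate_dataset, generate_membrane_scene,
                               render_movie)

LIGAND = [ChannelSpec("ligand", ReporterModel(kind="pH_insensitive"), role="ligand")]


def _static_vesicle(imaging, z=0.0, n_frames=None):
    """Hand-built kinetics: one dequenched stationary vesicle at depth z."""
    n = n_frames or imaging.n_frames
    t = np.arange(n) * imaging.frame_interval
    c = (imaging.field_size[0] // 2 + 0.5) * imaging.pixel_size
    return EventKinetics(
        mode="KS", arrival_time=0.0, fusion_time=0.0, pore_close_time=None,
        xy_um=(c, c),
        times=t, lumen_pH=np.full(n, 7.4), z=np.full(n, z),
        spread_sigma=np.zeros(n), tethered=np.zeros(n, bool),
        present=np.ones(n, bool), departed=False)


@pytest.fixture()
def imaging():
    return ImagingParams(field_size=(64, 64), n_frames=4, seed=0)


class TestPhotometry:
    def test_total_flux_equals_gain_times_photons(self, imaging, kinetics):
        stacks, _ = render_movie([_static_vesicle(imaging)], LIGAND, imaging,
                                 kinetics, noise=False)
        frame = stacks["ligand"].data[0]
        excess = frame.sum() - imaging.background_photons * frame.size
        expected = imaging.camera_gain * imaging.photons_per_vesicle
        assert excess == pytest.approx(expected, rel=1e-9)

    def test_evanescent_attenuation_at_depth(self, imaging, kinetics):
        def total(z):
            ev = _static_vesicle(imaging, z=z)
            stacks, _ = render_movie([ev], LIGAND, imaging, kinetics, noise=False)
            f = stacks["ligand"].data[0]
            return f.sum() - imaging.background_photons * f.size

        ratio = total(imaging.penetration_depth) / total(0.0)
        assert ratio == pytest.approx(np.exp(-1.0), rel=1e-9)
        # log-intensity vs z is linear with slope -1/d
        zs = np.array([0.0, 0.05, 0.1, 0.2, 0.3])
        logs = np.log([total(z) for z in zs])
        slope = stats.linregress(zs, logs).slope
        assert slope == pytest.approx(-1.0 / imaging.penetration_depth, rel=1e-9)

    def test_gain_linearity(self, imaging, kinetics):
        def excess(gain):
            img = dataclasses.replace(imaging, camera_gain=gain)
            stacks, _ = render_movie([_static_vesicle(img)], LIGAND, img,
                                     kinetics, noise=False)
            f = stacks["ligand"].data[0]
            return f.sum() - gain * imaging.background_photons * f.size

        assert excess(2.0) == pytest.approx(2 * excess(1.0), rel=1e-12)

    def test_full_fusion_conserves_ligand_photons(self, kinetics, rng):
        # diffusion spreads cargo but conserves mass until it reaches the edge
        imaging = ImagingParams(field_size=(96, 96), n_frames=40, seed=0)
        ev = simulate_event_kinetics(kinetics, "FF", 20.0, rng, fusion_time=2.0,
                                     xy_um=(48.5 * 0.18, 48.5 * 0.18))
        stacks, _ = render_movie([ev], LIGAND, imaging, kinetics, noise=False)
        data = stacks["ligand"].data
        bg = imaging.background_photons * data[0].size
        totals = data.reshape(imaging.n_frames, -1).sum(axis=1) - bg
        post = np.arange(imaging.n_frames) * imaging.frame_interval >= ev.fusion_time
        np.testing.assert_allclose(totals[post], imaging.photons_per_vesicle,
                                   rtol=1e-6)

    def test_empty_event_list_gives_background_movie(self, imaging, kinetics):
        stacks, truth = render_movie([], LIGAND, imaging, kinetics, noise=False)
        assert np.all(stacks["ligand"].data == imaging.background_photons)
        assert truth.empty


class TestNoiseModel:
    def test_poisson_variance_equals_mean(self, kinetics):
        imaging = ImagingParams(field_size=(32, 32), n_frames=400, seed=3,
                                camera_gain=1.0, read_noise_sd=0.0)
        stacks, _ = render_movie([], [ChannelSpec("reporter", ReporterModel())],
                                 imaging, kinetics, noise=True)
        data = stacks["reporter"].astype_float()
        mean = data.mean()
        var = data.var()
        # Poisson: var == mean, within Monte-Carlo error of ~sqrt(2/n)
        n = data.size
        assert var / mean == pytest.approx(1.0, abs=5 * np.sqrt(2.0 / n))

    def test_fixed_seed_is_bit_identical(self, kinetics, rng):
        imaging = ImagingParams(field_size=(48, 48), n_frames=20, seed=9)
        ev = simulate_event_kinetics(kinetics, "KS", 10.0,
                                     np.random.default_rng(1), fusion_time=3.0,
                                     xy_um=(24.5 * 0.18, 24.5 * 0.18))
        a, _ = render_movie([ev], default_channels(), imaging, kinetics)
        b, _ = render_movie([ev], default_channels(), imaging, kinetics)
        for label in a:
            np.testing.assert_array_equal(a[label].data, b[label].data)

    def test_counts_clipped_to_bit_depth(self, kinetics):
        imaging = ImagingParams(field_size=(32, 32), n_frames=2, seed=0,
                                photons_per_vesicle=1e9)
        ev = _static_vesicle(imaging, n_frames=2)
        stacks, _ = render_movie([ev], LIGAND, imaging, kinetics, noise=True)
        assert stacks["ligand"].data.max() == imaging.max_count


class TestGenerateDataset:
    def test_deterministic_for_fixed_master_seed(self, kinetics):
        imaging = ImagingParams(field_size=(96, 96), n_frames=60, seed=4)
        kw = dict(noise=True, fusion_frame_range=(25, 35))
        a = generate_dataset(2, 3, kinetics, default_channels(), imaging, "high", **kw)
        b = generate_dataset(2, 3, kinetics, default_channels(), imaging, "high", **kw)
        for ca, cb in zip(a, b):
            assert ca.ground_truth.equals(cb.ground_truth)
            for label in ca.movies:
                np.testing.assert_array_equal(ca.movies[label].data,
                                              cb.movies[label].data)

    def test_pure_ff_probabilities(self):
        params = KineticParams(mode_probabilities=(1.0, 0.0, 0.0))
        imaging = ImagingParams(field_size=(96, 96), n_frames=60, seed=4)
        cells = generate_dataset(3, 4, params, LIGAND, imaging, "high",
                                 noise=False, fusion_frame_range=(25, 35))
        for cell in cells:
            assert (cell.ground_truth["mode"] == "FF").all()

    def test_mode_counts_within_binomial_99ci(self, kinetics):
        imaging = ImagingParams(field_size=(192, 192), n_frames=60, seed=11)
        cells = generate_dataset(10, 20, kinetics, LIGAND, imaging, "high",
                                 noise=False, fusion_frame_range=(25, 35))
        modes = np.concatenate([c.ground_truth["mode"].to_numpy() for c in cells])
        n = len(modes)
        for mode, p in zip(("FF", "KR", "KS"), kinetics.mode_probabilities):
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= (modes == mode).sum() <= hi

    def test_ground_truth_matches_rendered_events(self, kinetics):
        imaging = ImagingParams(field_size=(96, 96), n_frames=60, seed=2)
        cells = generate_dataset(1, 3, kinetics, LIGAND, imaging, "high",
                                 noise=False, fusion_frame_range=(25, 35))
        cell = cells[0]
        assert len(cell.ground_truth) == len(cell.events) == 3
        for row, ev in zip(cell.ground_truth.itertuples(), cell.events):
            assert row.mode == ev.mode
            assert row.onset_frame == ev.onset_frame(imaging.frame_interval)
            assert row.dwell_s == pytest.approx(ev.dwell)

    def test_field_too_small_raises(self, kinetics):
        imaging = ImagingParams(field_size=(32, 32), n_frames=60, seed=0)
        with pytest.raises(ParameterError):
            generate_dataset(1, 20, kinetics, LIGAND, imaging, "high",
                             fusion_frame_range=(25, 35))


class TestMembraneScene:
    def test_identity_script_static_masks(self):
        imaging = ImagingParams(field_size=(64, 64), n_frames=5, seed=0)
        init = disk_mask((64, 64), (32, 32), 20)
        _, masks = generate_membrane_scene(init, None, imaging, noise=False)
        for t in range(5):
            np.testing.assert_array_equal(masks[t], init)

    def test_grown_disk_area_matches_pixel_enumeration(self):
        imaging = ImagingParams(field_size=(160, 160), n_frames=2, seed=0)
        r0, r1 = 50, 60
        script = lambda t, m: disk_mask((160, 160), (80, 80), r0 if t == 0 else r1)
        _, masks = generate_membrane_scene(disk_mask((160, 160), (80, 80), r0),
                                           script, imaging, noise=False)
        # brute-force annulus count on the same grid
        yy, xx = np.mgrid[0:160, 0:160]
        d2 = (yy + 0.5 - 80) ** 2 + (xx + 0.5 - 80) ** 2
        annulus = ((d2 <= r1**2) & (d2 > r0**2)).sum()
        assert masks[1].sum() - masks[0].sum() == annulus

    def test_one_sided_growth_confined_to_half_plane(self):
        imaging = ImagingParams(field_size=(128, 128), n_frames=3, seed=0)

        def script(t, m):
            grown = disk_mask((128, 128), (64, 64), 30 + 5 * t)
            grown[:, :64] = m[:, :64]        # left half frozen
            return grown | m

        init = disk_mask((128, 128), (64, 64), 30)
        _, masks = generate_membrane_scene(init, script, imaging, noise=False)
        diff = masks[-1].astype(int) - masks[0].astype(int)
        assert (diff[:, :64] == 0).all()
        assert (diff[:, 64:] == 1).any()

    def test_footprint_reaching_border_raises(self):
        imaging = ImagingParams(field_size=(64, 64), n_frames=2, seed=0)
        with pytest.raises(ParameterError):
            generate_membrane_scene(disk_mask((64, 64), (32, 32), 40), None,
                                    imaging)
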