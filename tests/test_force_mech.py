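import numpy as np
import pytest

from envmech.afm_image import HeightMap
from envmech.force_mech import (
    ForceCurve,
    MechSeries,
    NoContactError,
    analyze_timeseries,
    baseline_correct,
    find_contact,
    fit_hertz,
    height_from_profile,
    hertz_force,
    plateau_detect,
    process_qi_map,
    relative_change,
    to_indentation,
)
from envmech.geometry import make_geometry
from envmech.synthetic_scene import (
    MechTruth,
    QIParams,
    simulate_force_curve,
    simulate_qi_map,
    simulate_timeseries,
)


def _curve(z, force, k=0.08):
    return ForceCurve(z=np.asarray(z, float), force=np.asarray(force, float), k=k)


class TestHertzForce:
    def test_closed_form_value(self):
        # oracle: independent evaluation in SI units
        E, nu, R, delta = 50e3, 0.5, 65e-9, 100e-9
        expected_pN = (4 / 3) * (E / (1 - nu**2)) * np.sqrt(R) * delta**1.5 * 1e12
        assert hertz_force(100.0, 50.0, 65.0, 0.5) == pytest.approx(expected_pN, rel=1e-12)

    def test_zero_modulus_zero_force(self):
        assert hertz_force(123.0, 0.0, 65.0) == 0.0

    def test_negative_indentation_clipped(self):
        assert hertz_force(-5.0, 100.0, 65.0) == 0.0


class TestBaseline:
    def test_constant_offset_removed(self):
        z = np.linspace(1000, 0, 100)
        out = baseline_correct(_curve(z, np.full(100, 50.0)))
        assert np.allclose(out.force, 0.0)

    def test_noisy_offset_tail_mean(self, rng):
        z = np.linspace(1000, 0, 1000)
        out = baseline_correct(_curve(z, 50.0 + rng.normal(0, 10, 1000)))
        # standard-error oracle: tail mean within 3 * 10/sqrt(100)
        assert abs(out.force[:100].mean()) < 3 * 10 / np.sqrt(100)

    def test_idempotent(self):
        z = np.linspace(1000, 0, 100)
        once = baseline_correct(_curve(z, np.linspace(0, 5, 100)))
        twice = baseline_correct(once)
        assert np.allclose(once.force, twice.force)

    def test_short_tail_rejected(self):
        z = np.linspace(10, 0, 10)
        with pytest.raises(ValueError):
            baseline_correct(_curve(z, np.zeros(10)), tail_fraction=0.1)


class TestFindContact:
    def test_noiseless_within_one_sample(self):
        mech = MechTruth(E_true=50.0, noise_sd=0.0, contact_z=300.0)
        c = baseline_correct(simulate_force_curve(mech, 1200, 1024, with_noise=False))
        dz = 1200 / 1023
        assert abs(find_contact(c) - 300.0) <= dz

    def test_all_zero_force_raises(self):
        z = np.linspace(1000, 0, 100)
        with pytest.raises(NoContactError):
            find_contact(_curve(z, np.zeros(100)))

    def test_noisy_median_error_below_10nm(self):
        errors = []
        for seed in range(200):
            mech = MechTruth(E_true=50.0, noise_sd=10.0, contact_z=300.0)
            c = baseline_correct(simulate_force_curve(mech, 1200, 1024, seed=seed))
            errors.append(find_contact(c) - 300.0)
        assert np.median(np.abs(errors)) < 10.0


class TestToIndentation:
    def test_rigid_surface_zero_indentation(self):
        k = 0.08
        z = np.linspace(500, -50, 200)
        force = np.where(z < 100.0, (100.0 - z) * k * 1e3, 0.0)  # slope k in pN/nm
        ind = to_indentation(_curve(z, force, k=k), contact_z=100.0)
        assert np.abs(ind.delta).max() < 1e-9

    def test_zero_force_tracks_piezo(self):
        z = np.linspace(500, -100, 100)
        ind = to_indentation(_curve(z, np.zeros(100)), contact_z=100.0)
        expected = np.clip(100.0 - z, 0, None)
        assert np.allclose(ind.delta, expected)

    def test_round_trip_against_generator(self):
        mech = MechTruth(E_true=50.0, noise_sd=0.0, contact_z=300.0)
        c = simulate_force_curve(mech, 1200, 1024, with_noise=False)
        ind = to_indentation(c, contact_z=300.0)
        # oracle: invert the generator's forward map analytically
        expected = hertz_force(ind.delta, 50.0, 65.0, 0.5)
        assert np.allclose(expected, ind.force, atol=0.05)


class TestFitHertz:
    def _clean_indentation(self, E=50.0):
        mech = MechTruth(E_true=E, noise_sd=0.0, contact_z=300.0)
        c = baseline_correct(simulate_force_curve(mech, 1200, 1024, with_noise=False))
        return to_indentation(c, find_contact(c))

    def test_noiseless_recovery(self):
        model = fit_hertz(self._clean_indentation(50.0))
        assert model.E == pytest.approx(50.0, rel=1e-3)

    def test_linearity_in_modulus(self):
        ind = self._clean_indentation(50.0)
        doubled = type(ind)(
            delta=ind.delta, force=2 * ind.force, contact_z=ind.contact_z,
            tip_position=ind.tip_position,
        )
        m1 = fit_hertz(ind, refine_contact=False)
        m2 = fit_hertz(doubled, refine_contact=False)
        assert m2.E == pytest.approx(2 * m1.E, rel=1e-9)
        assert m2.residual_rms == pytest.approx(2 * m1.residual_rms, abs=1e-6)

    def test_noisy_recovery_median_error(self):
        ratios = []
        for seed in range(200):
            mech = MechTruth(E_true=100.0, noise_sd=10.0, contact_z=300.0)
            c = baseline_correct(simulate_force_curve(mech, 1200, 1024, seed=seed))
            ratios.append(fit_hertz(to_indentation(c, find_contact(c))).E / 100.0)
        assert np.median(np.abs(np.array(ratios) - 1)) < 0.05

    @pytest.mark.parametrize("E", [20.0, 50.0, 100.0, 300.0])
    def test_recovery_unbiased_across_stiffness(self, E):
        ratios = []
        for seed in range(100):
            mech = MechTruth(E_true=E, noise_sd=10.0, contact_z=300.0)
            c = baseline_correct(simulate_force_curve(mech, 1200, 1024, seed=seed))
            ratios.append(fit_hertz(to_indentation(c, find_contact(c))).E / E)
        assert 0.95 <= np.median(ratios) <= 1.05

    def test_too_few_samples_rejected(self):
        ind = self._clean_indentation(50.0)
        starved = type(ind)(
            delta=ind.delta[:5], force=ind.force[:5], contact_z=ind.contact_z,
            tip_position=ind.tip_position[:5],
        )
        with pytest.raises(ValueError):
            fit_hertz(starved)


@pytest.fixture(scope="module")
def noiseless_cell_map():
    geom = make_geometry(2000, 400, 0, (1000, 1000))
    p = QIParams(scan_size_nm=(2000, 2000), noise_sd=0.0)
    return simulate_qi_map(geom, 80.0, grid_shape=(24, 24), qi_params=p, seed=1)


class TestQiMapProcessing:
    def test_height_and_modulus_recovery(self, noiseless_cell_map):
        qimap, truth = noiseless_cell_map
        h0, e_map, failed = process_qi_map(qimap)
        on_cell = truth["height"] > 100
        assert np.nanmax(h0) == pytest.approx(truth["height"].max(), abs=2.0)
        assert abs(np.nanmean((h0 - truth["height"])[on_cell])) < 2.0
        e_cell = e_map[on_cell & np.isfinite(e_map)]
        assert np.allclose(e_cell, 80.0, rtol=0.01)

    def test_substrate_flat_and_rigid_fit_flagged(self):
        p = QIParams(scan_size_nm=(1500, 1500), noise_sd=5.0)
        qimap, _ = simulate_qi_map(None, 1e6, grid_shape=(8, 8), qi_params=p, seed=3)
        h0, e_map, failed = process_qi_map(qimap)
        assert np.nanstd(h0) < 5.0  # flat within noise
        assert np.isnan(e_map).all()  # no compliant contact anywhere

    def test_deterministic(self):
        geom = make_geometry(2000, 400, 0, (1000, 1000))
        p = QIParams(scan_size_nm=(2000, 2000))
        qimap, _ = simulate_qi_map(geom, 80.0, grid_shape=(12, 12), qi_params=p, seed=2)
        a = process_qi_map(qimap)
        b = process_qi_map(qimap)
        assert np.array_equal(np.nan_to_num(a[0]), np.nan_to_num(b[0]))
        assert np.array_equal(np.nan_to_num(a[1]), np.nan_to_num(b[1]))

    def test_majority_failure_raises(self):
        z = np.linspace(1200, 0, 100)
        flat = [[_curve(z, np.zeros(100)) for _ in range(4)] for _ in range(4)]
        from envmech.force_mech import QIMap

        with pytest.raises(RuntimeError):
            process_qi_map(QIMap(curves=flat, pixel_size=50.0))


class TestHeightFromProfile:
    def test_cell_diameter_recovered(self):
        geom = make_geometry(2000, 400, 0, (1000, 1000))
        p = QIParams(scan_size_nm=(2000, 2000), noise_sd=0.0)
        qimap, _ = simulate_qi_map(geom, 80.0, grid_shape=(24, 24), qi_params=p, seed=1)
        h0, _, _ = process_qi_map(qimap)
        hm = HeightMap(values=np.nan_to_num(h0), pixel_size=qimap.pixel_size)
        assert height_from_profile(hm) == pytest.approx(800.0, abs=5.0)

    def test_substrate_only_line_rejected(self):
        hm = HeightMap(values=np.zeros((16, 16)), pixel_size=50.0)
        with pytest.raises(ValueError):
            height_from_profile(hm)


class TestSeries:
    def _series(self, heights, e_values, times=None, sytox=None):
        n = len(heights)
        return MechSeries(
            times=np.arange(n, dtype=float) if times is None else times,
            heights=np.asarray(heights, float),
            E_values=np.asarray(e_values, float),
            sytox_flags=np.zeros(n, bool) if sytox is None else sytox,
        )

    def test_relative_change_simple(self):
        s = self._series([100, 105, 107], [50, 60, 75])
        dh, de = relative_change(s)
        assert dh == pytest.approx(0.07)
        assert de == pytest.approx(0.5)

    def test_relative_change_needs_two_frames(self):
        with pytest.raises(ValueError):
            relative_change(self._series([1.0], [1.0]))

    def test_plateau_on_ramp_then_flat(self):
        e = np.concatenate([np.linspace(100, 150, 6), np.full(4, 150.0)])
        s = self._series(np.full(10, 800.0), e)
        is_plateau, bp = plateau_detect(s)
        assert is_plateau
        assert abs(bp - 5) <= 1  # oracle: known breakpoint of the generated ramp

    def test_pure_ramp_no_plateau(self):
        s = self._series(np.full(10, 800.0), np.linspace(100, 200, 10))
        assert plateau_detect(s)[0] is False

    def test_pure_flat_plateau_at_start(self):
        s = self._series(np.full(10, 800.0), np.full(10, 100.0))
        assert plateau_detect(s) == (True, 0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            plateau_detect(self._series(np.ones(4), np.ones(4)))


class TestSwellingRecovery:
    @pytest.mark.parametrize("fraction", [0.0, 0.05, 0.10])
    def test_programmed_swelling_recovered(self, fraction):
        """Height-change estimator recovers the programmed swelling within
        one percentage point (median over seeds)."""
        estimates = []
        for seed in range(5):
            mech = MechTruth(
                E_true=100.0, swelling_fraction=fraction, permeation_time=4,
                noise_sd=10.0,
            )
            frames, _ = simulate_timeseries(mech, n_frames=6, seed=seed, grid_shape=(12, 12))
            series = analyze_timeseries(frames)
            estimates.append(relative_change(series)[0])
        assert abs(np.median(estimates) - fraction) < 0.01

    def test_sytox_flags_follow_permeation(self):
        mech = MechTruth(E_true=100.0, swelling_fraction=0.07, permeation_time=3)
        frames, _ = simulate_timeseries(mech, n_frames=6, seed=0, grid_shape=(8, 8))
        flags = [f for _, f in frames]
        assert flags == [False, False, False, True, True, True]
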