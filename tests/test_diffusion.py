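"""MSD computation, D fitting, confinement metrics and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sptpalm.diffusion import (
    area_explored_per_step,
    classify_trajectory,
    compute_msd,
    ensemble_msd,
    fit_diffusion_coefficient,
)
from sptpalm.mapping import MaskImage
from sptpalm.simulate import simulate_trajectories
from sptpalm.track import Trajectory
from tests.conftest import brute_force_msd

PIXEL_NM = 16000.0 / 150.0


def traj(points_um, dt=1.0):
    pts = np.asarray(points_um, dtype=float) * 1000.0
    return Trajectory(0, np.arange(len(pts)), pts[:, 0], pts[:, 1],
                      np.zeros(len(pts)), dt_s=dt)


class TestMSD:
    def test_stationary_is_zero(self):
        c = compute_msd(traj([[1, 2]] * 8))
        assert np.all(c.msd_um2 == 0)

    def test_ballistic_quadratic(self):
        # collinear constant steps of s: MSD(n) = (n*s)^2 exactly
        s = 0.3
        c = compute_msd(traj([[i * s, 0] for i in range(8)]))
        assert np.allclose(c.msd_um2, (c.lag_index * s) ** 2)

    def test_worked_example(self):
        c = compute_msd(traj([[0, 0], [1, 0], [1, 1], [2, 1]]))
        assert np.allclose(c.msd_um2, [1.0, 2.0, 5.0])
        assert np.array_equal(c.n_pairs, [3, 2, 1])
        assert np.allclose(c.lag_time_s, [1.0, 2.0, 3.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(3, 50))
    def test_matches_brute_force(self, seed, n_points):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 0.5, size=(n_points, 2))
        t = traj(pts, dt=0.02)
        c = compute_msd(t)
        want = brute_force_msd(pts[:, 0], pts[:, 1], 0.02, n_points - 1)
        assert np.allclose(c.msd_um2, want, rtol=1e-12, atol=0)

    def test_lag_bounds_enforced(self):
        t = traj([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValueError):
            compute_msd(t, n_max=3)
        with pytest.raises(ValueError):
            compute_msd(traj([[0, 0]] * 1))

    def test_gapped_trajectory_rejected(self):
        t = Trajectory(0, [0, 1, 3], np.zeros(3), np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            compute_msd(t)


class TestFit:
    def test_exact_linear_recovery(self):
        # MSD(t) = 4*0.1*t + 4*(0.02)^2 -> D = 0.1, sigma_x = 20 nm, r2 = 1
        lags = np.arange(1, 7)
        dt = 0.02
        from sptpalm.diffusion import MSDCurve

        c = MSDCurve(lags, lags * dt, 4 * 0.1 * lags * dt + 4 * 0.02**2, 10 - lags)
        fit = fit_diffusion_coefficient(c)
        assert fit.D_um2s == pytest.approx(0.1, rel=1e-9)
        assert fit.sigma_x_nm == pytest.approx(20.0, rel=1e-9)
        assert fit.fit_r2 == pytest.approx(1.0)

    def test_noise_floor_intercept(self):
        # stationary molecule + 20 nm localization noise: D ~ 0 and the
        # intercept recovers 4*sigma^2 = 0.0016 um^2
        trajs = simulate_trajectories(500, 30, 0.0, 0.02, sigma_loc_nm=20.0, seed=17)
        fits = [fit_diffusion_coefficient(compute_msd(t)) for t in trajs]
        d_med = np.median([f.D_um2s for f in fits])
        intercepts = [4 * (f.sigma_x_nm / 1000.0) ** 2 for f in fits]
        assert abs(d_med) < 0.005
        assert abs(np.median(intercepts) - 0.0016) / 0.0016 < 0.25

    def test_free_brownian_recovery(self):
        trajs = simulate_trajectories(500, 30, 0.09, 0.02, sigma_loc_nm=20.0, seed=18)
        d_med = np.median([fit_diffusion_coefficient(compute_msd(t)).D_um2s for t in trajs])
        assert abs(d_med - 0.09) / 0.09 < 0.15

    def test_mean_intercept_matches_noise_term(self):
        # for free Brownian motion the fitted intercept estimates 4*sigma_loc^2
        trajs = simulate_trajectories(500, 30, 0.09, 0.02, sigma_loc_nm=20.0, seed=19)
        raw = []
        for t in trajs:
            c = compute_msd(t)
            sel = np.isin(c.lag_index, (2, 3, 4, 5))
            raw.append(np.polyfit(c.lag_time_s[sel], c.msd_um2[sel], 1)[1])
        assert abs(np.mean(raw) - 0.0016) / 0.0016 < 0.25

    def test_negative_intercept_flagged(self):
        from sptpalm.diffusion import MSDCurve

        lags = np.arange(1, 6)
        c = MSDCurve(lags, lags * 0.02, 4 * 0.1 * lags * 0.02 - 0.001, 10 - lags)
        fit = fit_diffusion_coefficient(c)
        assert fit.sigma_x_nm == 0.0
        assert "negative_intercept" in fit.flags

    def test_too_few_lags(self):
        c = compute_msd(traj([[0, 0], [1, 0], [2, 0], [3, 0]]))  # 3 lags
        with pytest.raises(ValueError):
            fit_diffusion_coefficient(c)


class TestAreaExplored:
    def test_unit_square(self):
        # hull area 1 px^2 over 3 steps (shoelace oracle: 1.0)
        p = PIXEL_NM
        t = Trajectory(0, np.arange(4), np.array([0, p, p, 0.0]), np.array([0, 0, p, p]),
                       np.zeros(4))
        assert area_explored_per_step(t, p) == pytest.approx(1.0 / 3.0)

    def test_collinear_zero(self):
        t = Trajectory(0, np.arange(5), np.linspace(0, 400, 5), np.zeros(5), np.zeros(5))
        assert area_explored_per_step(t, PIXEL_NM) == 0.0

    def test_too_few_points(self):
        t = Trajectory(0, np.arange(2), np.zeros(2), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            area_explored_per_step(t, PIXEL_NM)

    def test_monotone_in_confinement_radius(self):
        meds = []
        for R in (160.0, 80.0, 40.0):
            trajs = simulate_trajectories(200, 20, 0.09, 0.02,
                                          confinement_radius_nm=R, seed=int(R))
            meds.append(np.median([area_explored_per_step(t, PIXEL_NM) for t in trajs]))
        assert meds[0] > meds[1] > meds[2]


class TestClassify:
    def _mask(self, full=False):
        data = np.zeros((100, 100), bool)
        if full:
            data[:, :50] = True  # x < 2500 nm
        return MaskImage(data if full else data, 50.0)

    def _traj(self, xs):
        xs = np.asarray(xs, float)
        return Trajectory(0, np.arange(len(xs)), xs, np.full(len(xs), 100.0),
                          np.zeros(len(xs)))

    def test_majority_rule(self):
        mask = self._mask(full=True)
        t = self._traj([100] * 6 + [4000] * 4)  # 6/10 inside
        syn, clu = classify_trajectory(t, None, mask)
        assert clu == "trapped"
        t2 = self._traj([100] * 4 + [4000] * 6)
        assert classify_trajectory(t2, None, mask)[1] == "free"

    def test_outside_mask_extra_synaptic(self):
        mask = self._mask(full=True)
        t = self._traj([4000] * 10)
        assert classify_trajectory(t, mask, None)[0] == "extra-synaptic"

    def test_missing_mask_unassigned(self):
        t = self._traj([100] * 5)
        assert classify_trajectory(t, None, None) == ("unassigned", "unassigned")

    def test_invalid_overlap_fraction(self):
        with pytest.raises(ValueError):
            classify_trajectory(self._traj([1.0] * 3), None, None, overlap_fraction=0.0)


class TestEnsemble:
    def test_identical_curves(self):
        trajs = simulate_trajectories(1, 12, 0.05, 0.02, seed=2)
        c = compute_msd(trajs[0])
        out = ensemble_msd({"g": [c, c, c]})
        assert np.allclose(out["g"]["mean_msd_um2"], c.msd_um2)
        assert np.allclose(out["g"]["sem_msd_um2"], 0.0)

    def test_small_group_omitted_with_warning(self):
        trajs = simulate_trajectories(1, 12, 0.05, 0.02, seed=2)
        with pytest.warns(UserWarning):
            out = ensemble_msd({"solo": [compute_msd(trajs[0])]})
        assert out == {}

    def test_free_group_slope(self):
        trajs = simulate_trajectories(400, 30, 0.09, 0.02, seed=21)
        out = ensemble_msd({"free": [compute_msd(t) for t in trajs]})["free"]
        sel = out["lag_index"].isin([2, 3, 4, 5])
        slope = np.polyfit(out.loc[sel, "lag_time_s"], out.loc[sel, "mean_msd_um2"], 1)[0]
        assert abs(slope - 4 * 0.09) / (4 * 0.09) < 0.15

    def test_trapped_below_free_and_plateau(self):
        free = simulate_trajectories(300, 40, 0.09, 0.02, seed=22)
        trapped = simulate_trajectories(300, 40, 0.04, 0.02,
                                        confinement_radius_nm=52.5, seed=23)
        out = ensemble_msd({
            "free": [compute_msd(t) for t in free],
            "trapped": [compute_msd(t) for t in trapped],
        })
        n = min(len(out["free"]), len(out["trapped"]))
        assert np.all(out["trapped"]["mean_msd_um2"].to_numpy()[:n]
                      < out["free"]["mean_msd_um2"].to_numpy()[:n])
        plateau = out["trapped"].loc[out["trapped"]["lag_index"] == 20, "mean_msd_um2"].iloc[0]
        assert abs(plateau * 1e6 - 52.5**2) / 52.5**2 < 0.25
        d_free = np.median([fit_diffusion_coefficient(compute_msd(t)).D_um2s for t in free])
        d_trap = np.median([fit_diffusion_coefficient(compute_msd(t)).D_um2s for t in trapped])
        assert d_trap < d_free
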