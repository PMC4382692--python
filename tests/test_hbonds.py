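"""Hydrogen-bond detection geometry, correlation functions against a
brute-force oracle and two-state closed forms, relaxation times, water MSD."""

import numpy as np
import pytest

from aquadyn import synthetic as syn
from aquadyn.hbonds import (
    CorrelationFunction,
    HBSeries,
    Topology,
    Trajectory,
    continuous_correlation,
    detect_hbonds,
    fit_exponential_decay,
    hb_timeseries,
    intermittent_correlation,
    rate_series,
    relaxation_time,
    water_msd,
)


# ---------------------------------------------------------------------------
# brute-force oracle (independent of the implementation)
# ---------------------------------------------------------------------------

def brute_force_correlations(h: np.ndarray):
    """Direct enumeration over all pairs and time origins.

    For each lag the numerator and the <h(0)> normalization accumulate over
    the same origin set; H(t) requires the bond intact at every intermediate
    frame.
    """
    h = np.asarray(h, dtype=bool)
    P, n = h.shape
    S = np.zeros(n)
    C = np.zeros(n)
    for tau in range(n):
        num_s = num_c = den = 0
        for p in range(P):
            for t0 in range(n - tau):
                if h[p, t0]:
                    den += 1
                    if h[p, t0 + tau]:
                        num_c += 1
                    if all(h[p, t0:t0 + tau + 1]):
                        num_s += 1
        S[tau] = num_s / den if den else 0.0
        C[tau] = num_c / den if den else 0.0
    return S, C


def series(h, dt=1.0):
    return HBSeries(h=np.atleast_2d(np.asarray(h, dtype=bool)), dt=dt)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def donor_acceptor_frame(d_a=2.8, angle_deg=180.0):
    """O-H...O geometry: donor O at origin, H on +x, acceptor placed to give
    the requested D-H-A angle and D-A distance."""
    oh = 0.98
    pos = np.zeros((3, 3))
    pos[1, 0] = oh
    # place acceptor: solve triangle with vertex at H
    theta = np.deg2rad(180.0 - angle_deg)    # deviation from collinear
    # distance H-A from the law of cosines in triangle D-H-A
    # |DA|^2 = |DH|^2 + |HA|^2 - 2 |DH||HA| cos(angle at H)
    cos_a = np.cos(np.deg2rad(angle_deg))
    ha = oh * cos_a + np.sqrt(d_a ** 2 - oh ** 2 * (1 - cos_a ** 2))
    pos[2] = pos[1] + ha * np.array([np.cos(theta), np.sin(theta), 0.0])
    return pos


@pytest.fixture
def water_pair_topology():
    return Topology(labels=["O", "H", "O"], donors=[(0, 1)], acceptors=[2],
                    water_oxygens=[0, 2], groups=["water"] * 3)


class TestDetectHbonds:
    @pytest.mark.parametrize("d_a,angle,expected", [
        (2.8, 180.0, True),
        (3.6, 180.0, False),      # distance cut
        (2.8, 149.0, False),      # angle cut
        (3.49, 151.0, True),      # both just inside
    ])
    def test_distance_angle_criterion(self, water_pair_topology, d_a, angle,
                                      expected):
        pos = donor_acceptor_frame(d_a, angle)
        pairs, bonded = detect_hbonds(pos, water_pair_topology)
        assert pairs == [(0, 2)]
        assert bonded[0] == expected
        # verify the constructed geometry is what it claims
        assert np.linalg.norm(pos[2] - pos[0]) == pytest.approx(d_a, abs=1e-9)
        v1, v2 = pos[0] - pos[1], pos[2] - pos[1]
        got = np.degrees(np.arccos(v1 @ v2 /
                                   (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert got == pytest.approx(angle, abs=1e-6)

    def test_minimum_image_across_boundary(self, water_pair_topology):
        box = np.array([10.0, 10.0, 10.0])
        pos = donor_acceptor_frame(2.8, 180.0)
        shifted = pos.copy()
        shifted[2, 0] -= box[0]          # acceptor wrapped to the other side
        _, bonded = detect_hbonds(shifted, water_pair_topology, box=box)
        assert bonded[0]
        _, unwrapped = detect_hbonds(shifted, water_pair_topology, box=None)
        assert not unwrapped[0]

    def test_overlapping_atoms_warn(self, water_pair_topology):
        pos = donor_acceptor_frame(2.8, 180.0)
        pos[2] = pos[0] + np.array([0.3, 0.0, 0.0])
        with pytest.warns(UserWarning):
            detect_hbonds(pos, water_pair_topology)

    def test_timeseries_follows_prescribed_states(self):
        states = np.array([1, 0, 1, 1, 0, 0, 1], dtype=bool)
        traj, topo = syn.trajectory_from_bond_states(states)
        hb = hb_timeseries(traj, topo)
        assert hb.n_pairs == 1
        np.testing.assert_array_equal(hb.h[0], states)

    def test_markov_states_roundtrip_through_geometry(self):
        spec = syn.MarkovHBSpec(k_off=0.2, k_on=0.1, n_pairs=1, n_frames=40,
                                dt=1.0, seed=9)
        markov, _ = syn.generate_hb_markov_series(spec)
        traj, topo = syn.trajectory_from_bond_states(markov.h[0])
        hb = hb_timeseries(traj, topo)
        np.testing.assert_array_equal(hb.h[0], markov.h[0])


class TestCorrelationFunctions:
    def test_always_bonded_stays_at_one(self):
        s = series(np.ones(20, dtype=bool))
        assert np.allclose(continuous_correlation(s).values, 1.0)
        assert np.allclose(intermittent_correlation(s).values, 1.0)

    def test_alternating_bond_breaks_immediately(self):
        s = series([1, 0] * 6)
        S = continuous_correlation(s)
        assert S.values[0] == 1.0
        assert S.values[1] == 0.0

    def test_period_two_intermittent_recurrence(self):
        s = series([1, 0] * 6)
        C = intermittent_correlation(s)
        even = C.values[0:10:2]
        odd = C.values[1:10:2]
        assert np.allclose(even, 1.0)
        assert np.allclose(odd, 0.0)

    @pytest.mark.parametrize("pattern", [
        [1, 1, 1, 0],
        [0, 1, 1, 1],
        [1, 0, 0, 1, 1, 1],
        [1, 1, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1],
    ])
    def test_single_pair_matches_brute_force(self, pattern):
        s = series(pattern)
        S_oracle, C_oracle = brute_force_correlations(s.h)
        np.testing.assert_allclose(continuous_correlation(s).values, S_oracle,
                                   atol=1e-14)
        np.testing.assert_allclose(intermittent_correlation(s).values,
                                   C_oracle, atol=1e-14)

    def test_random_multi_pair_matches_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            P = rng.integers(1, 5)
            n = rng.integers(2, 13)
            h = rng.random((P, n)) < 0.6
            if h.sum() == 0:
                continue
            S_oracle, C_oracle = brute_force_correlations(h)
            s = HBSeries(h=h, dt=1.0)
            np.testing.assert_allclose(continuous_correlation(s).values,
                                       S_oracle, atol=1e-12)
            np.testing.assert_allclose(intermittent_correlation(s).values,
                                       C_oracle, atol=1e-12)

    def test_intermittent_dominates_continuous(self):
        rng = np.random.default_rng(3)
        h = rng.random((6, 60)) < 0.5
        s = HBSeries(h=h, dt=1.0)
        S = continuous_correlation(s).values
        C = intermittent_correlation(s).values
        assert np.all(C >= S - 1e-12)
        assert np.all((0 <= S) & (S <= 1)) and np.all((0 <= C) & (C <= 1))

    def test_continuous_is_monotone_on_single_pair(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            h = rng.random(40) < 0.5
            if not h.any():
                continue
            S = continuous_correlation(series(h)).values
            assert np.all(np.diff(S) <= 1e-12)

    def test_invariant_under_pair_reordering_and_duplication(self):
        rng = np.random.default_rng(8)
        h = rng.random((4, 30)) < 0.5
        s = HBSeries(h=h, dt=1.0)
        permuted = HBSeries(h=h[[2, 0, 3, 1]], dt=1.0)
        doubled = HBSeries(h=np.vstack([h, h]), dt=1.0)
        base = intermittent_correlation(s).values
        np.testing.assert_allclose(intermittent_correlation(permuted).values,
                                   base, atol=1e-12)
        np.testing.assert_allclose(intermittent_correlation(doubled).values,
                                   base, atol=1e-12)
        base_s = continuous_correlation(s).values
        np.testing.assert_allclose(continuous_correlation(doubled).values,
                                   base_s, atol=1e-12)

    def test_empty_series_fails(self):
        with pytest.raises(ValueError):
            continuous_correlation(series(np.zeros(10, dtype=bool)))

    def test_markov_survival_matches_exponential(self):
        spec = syn.MarkovHBSpec(k_off=0.1, k_on=0.02, n_pairs=300,
                                n_frames=2000, dt=1.0, seed=2)
        s, oracle = syn.generate_hb_markov_series(spec)
        S = continuous_correlation(s, max_lag=40)
        fit = fit_exponential_decay(S, baseline=False)
        assert fit["rate"] == pytest.approx(spec.k_off, rel=0.05)

    def test_markov_intermittent_matches_closed_form(self):
        spec = syn.MarkovHBSpec(k_off=0.1, k_on=0.02, n_pairs=400,
                                n_frames=3000, dt=1.0, seed=6)
        s, oracle = syn.generate_hb_markov_series(spec)
        max_lag = 400
        C = intermittent_correlation(s, max_lag=max_lag)
        # Monte-Carlo error bars: the same pooled estimator applied to
        # independent groups of pairs gives i.i.d. replicates per lag
        groups = np.array([
            intermittent_correlation(
                HBSeries(h=s.h[g::20], dt=spec.dt), max_lag=max_lag).values
            for g in range(20)])
        sem = groups.std(axis=0, ddof=1) / np.sqrt(groups.shape[0])
        expected = oracle.intermittent(C.lags)
        check = slice(1, None)
        assert np.all(np.abs(groups.mean(axis=0)[check] - expected[check])
                      <= 3 * sem[check] + 1e-3)
        # and the full pooled estimate agrees with the group mean
        assert np.all(np.abs(C.values[check] - groups.mean(axis=0)[check])
                      <= 3 * sem[check] + 1e-3)


class TestRelaxationTime:
    def test_pure_exponential_crossing(self):
        t = np.arange(0.0, 400.0, 0.5)
        corr = CorrelationFunction(lags=t, values=np.exp(-t / 50.0),
                                   counts=np.full(t.size, 1000))
        res = relaxation_time(corr)
        assert res.method == "direct-crossing"
        assert res.tau == pytest.approx(50.0, rel=1e-3)

    def test_truncated_kww_extrapolates(self):
        t = np.arange(0.0, 40.0 + 0.5, 0.5)
        corr = CorrelationFunction(lags=t,
                                   values=np.exp(-np.sqrt(t / 100.0)),
                                   counts=np.full(t.size, 1000))
        res = relaxation_time(corr, window_max=4000.0)
        assert res.method == "stretched-extrapolation"
        # closed-form 1/e crossing of exp(-(t/100)^0.5) is t = 100
        assert res.tau == pytest.approx(100.0, rel=0.05)

    def test_constant_correlation_fails(self):
        t = np.arange(0.0, 100.0, 1.0)
        corr = CorrelationFunction(lags=t, values=np.ones(t.size),
                                   counts=np.full(t.size, 10))
        with pytest.raises(RuntimeError):
            relaxation_time(corr)


class TestWaterMSD:
    def test_static_positions_give_zero(self):
        traj = Trajectory(positions=np.zeros((50, 4, 3)) + 1.5, dt=1.0)
        assert water_msd(traj, [0, 1, 2, 3], lag=10.0) == 0.0

    def test_uniform_drift_is_ballistic(self):
        v = np.array([0.01, -0.02, 0.005])
        t = np.arange(200)[:, None, None]
        traj = Trajectory(positions=np.zeros((200, 3, 3)) + v * t, dt=1.0)
        msd = water_msd(traj, [0, 1, 2], lag=100.0)
        assert msd == pytest.approx(np.sum((v * 100.0) ** 2), rel=1e-12)

    def test_brownian_walk_obeys_einstein_relation(self):
        rng = np.random.default_rng(12)
        D, dt, n = 0.01, 1.0, 400
        steps = np.sqrt(2 * D * dt) * rng.standard_normal((n, 300, 3))
        pos = np.cumsum(steps, axis=0)
        traj = Trajectory(positions=pos, dt=dt)
        msd = water_msd(traj, None, lag=100.0)
        assert msd == pytest.approx(6 * D * 100.0, rel=0.05)

    def test_invariant_under_global_rotation_and_translation(self):
        rng = np.random.default_rng(4)
        pos = np.cumsum(rng.standard_normal((60, 10, 3)), axis=0)
        traj = Trajectory(positions=pos, dt=1.0)
        base = water_msd(traj, None, lag=20.0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = Trajectory(positions=pos @ R.T + np.array([5.0, -3.0, 2.0]),
                           dt=1.0)
        assert water_msd(moved, None, lag=20.0) == pytest.approx(base, rel=1e-12)

    def test_lag_beyond_span_fails(self):
        traj = Trajectory(positions=np.zeros((10, 2, 3)), dt=1.0)
        with pytest.raises(ValueError):
            water_msd(traj, [0], lag=20.0)


class TestRateSeries:
    def test_rates_are_reciprocal_times(self):
        table = rate_series([{"T": 300.0, "tau_hbc": 50.0, "tau_hbi": 200.0,
                              "msd_100ps": 3.2}])
        assert table.loc[0, "rate_hbc"] == pytest.approx(0.02)
        assert table.loc[0, "rate_hbi"] == pytest.approx(0.005)

    def test_missing_fields_become_nan(self):
        table = rate_series([{"T": 220.0}])
        assert np.isnan(table.loc[0, "rate_hbc"])
        assert np.isnan(table.loc[0, "msd_100ps"])

    def test_arrhenius_series_slope_recovered(self):
        temps = np.array([220.0, 240.0, 260.0, 280.0, 300.0])
        Ea_over_k = 2000.0     # kelvin
        taus = 5.0 * np.exp(Ea_over_k / temps)
        table = rate_series([{"T": T, "tau_hbc": tau}
                             for T, tau in zip(temps, taus)])
        slope = np.polyfit(1.0 / temps, np.log(table["rate_hbc"]), 1)[0]
        assert slope == pytest.approx(-Ea_over_k, rel=0.05)
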