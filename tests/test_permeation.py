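"""Event counting, turnover arithmetic and the two permeability estimators."""

import numpy as np
import pandas as pd
import pytest

from poreflux import (
    ChannelGeometry,
    PermeationEventTable,
    SingleFileModelSpec,
    TrajectorySet,
    benchmark_trajectory_path,
    collective_coordinate,
    detect_events,
    diffusional_permeability,
    make_benchmark_trajectory,
    osmotic_permeability,
    read_trajectory,
    simulate_free_diffusers,
    simulate_single_file,
    turnover_rate,
)
from poreflux.constants import NS_PER_S, VW_CM3
from poreflux.exceptions import ValidationError

from _hopping_oracle import run_oracle


def _path_traj(zs, dt=0.1):
    rec = pd.DataFrame(
        {"frame": np.arange(len(zs)), "id": 0, "x": 0.0, "y": 0.0,
         "z": np.asarray(zs, float)}
    )
    return TrajectorySet(times=dt * np.arange(len(zs)), records=rec)


GEOM = ChannelGeometry(z_lumen=(-0.7, 0.7), z_event_bounds=(-0.75, 0.75))


class TestDetectEvents:
    def test_canonical_crossing_counts_once_upward(self):
        ev = detect_events(_path_traj([-1.0, 0.0, 1.0]), GEOM)
        assert len(ev) == 1
        assert ev.events["direction"].iloc[0] == 1

    def test_bounce_to_entry_side_records_nothing(self):
        ev = detect_events(_path_traj([-1.0, 0.0, -1.0]), GEOM)
        assert len(ev) == 0

    def test_downward_crossing_direction(self):
        ev = detect_events(_path_traj([1.0, 0.0, -1.0]), GEOM)
        assert len(ev) == 1
        assert ev.events["direction"].iloc[0] == -1

    def test_frame_gap_resets_state(self):
        # the molecule disappears mid-crossing; no event
        rec = pd.DataFrame(
            {"frame": [0, 1, 4, 5], "id": 0, "x": 0.0, "y": 0.0,
             "z": [-1.0, 0.0, 0.0, 1.0]}
        )
        traj = TrajectorySet(times=0.1 * np.arange(6), records=rec)
        assert len(detect_events(traj, GEOM)) == 0

    def test_direct_jump_without_inlumen_frame_not_counted(self):
        ev = detect_events(_path_traj([-1.0, 1.0, -1.0]), GEOM)
        assert len(ev) == 0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            detect_events(_path_traj([0.0, 0.0]),
                          ChannelGeometry(z_lumen=(-0.7, 0.7),
                                          z_event_bounds=(0.75, -0.75)))

    def test_benchmark_fixture_reproduces_published_turnover(self):
        traj = read_trajectory(benchmark_trajectory_path())
        geom = ChannelGeometry(z_lumen=(-0.7, 0.7), z_event_bounds=(-0.75, 0.75),
                               n_monomers=3)
        ev = detect_events(traj, geom)
        assert len(ev) == 257
        per_ns, per_s = turnover_rate(ev)
        assert round(per_ns, 2) == 0.43
        assert per_s == pytest.approx(4.3e8, rel=0.01)

    def test_event_count_invariant_under_frame_subsampling(self):
        """Crossings spanning >= 4 frames survive subsampling by 2."""
        traj = make_benchmark_trajectory(n_events=40, duration=100.0)
        geom = ChannelGeometry(z_lumen=(-0.7, 0.7), z_event_bounds=(-0.75, 0.75))
        full = detect_events(traj, geom)
        sub_rec = traj.records[traj.records["frame"] % 2 == 0].copy()
        sub_rec["frame"] //= 2
        sub = TrajectorySet(times=traj.times[::2], records=sub_rec)
        assert len(detect_events(sub, geom)) == len(full)


class TestTurnoverAndPd:
    def _table(self, n, duration, n_monomers):
        ev = pd.DataFrame(
            {"id": np.arange(n), "t_enter": np.zeros(n),
             "t_exit": np.ones(n), "direction": 1}
        )
        return PermeationEventTable(events=ev, duration=duration,
                                    n_monomers=n_monomers)

    def test_published_event_arithmetic(self):
        per_ns, per_s = turnover_rate(self._table(257, 200.0, 3))
        assert round(per_ns, 2) == 0.43
        assert per_s == pytest.approx(4.2833e8, rel=1e-4)

    def test_empty_table_gives_zero(self):
        per_ns, per_s = turnover_rate(self._table(0, 10.0, 1))
        assert per_ns == 0 and per_s == 0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValidationError):
            turnover_rate(self._table(1, 0.0, 1))

    def test_pd_formula_arithmetic(self):
        # q0 = 1e9 events/s  ->  pd = vw * q0
        tab = self._table(2, 1.0, 1)  # 2 events / (2 * 1 ns) = 1 event/ns
        res = diffusional_permeability(tab, vw=2.99e-23)
        assert res.q0 == pytest.approx(1.0)
        assert res.pd == pytest.approx(2.99e-14)

    def test_no_flux_means_zero_pd(self):
        res = diffusional_permeability(self._table(0, 5.0, 1))
        assert res.pd == 0.0

    def test_pd_matches_bruteforce_crossing_oracle(self):
        """Hopping-run pd within 3 SE of an independent re-simulation."""
        spec = SingleFileModelSpec(duration=120.0, seed=31, pmf=0.0)
        traj = simulate_single_file(spec)
        geom = ChannelGeometry(z_lumen=spec.pore_z_bounds, n_monomers=1)
        ev = detect_events(traj, geom)
        res = diffusional_permeability(ev)

        n_steps = 120000  # 240 ns of oracle chain
        _, crossings = run_oracle(
            n_steps, spec.n_sites, [0.0] * spec.n_sites,
            spec.hop_rate * spec.timestep, spec.activity, spec.buffer_mean,
            spec.buffer_relax_rate * spec.timestep, seed=5,
        )
        oracle_q0 = crossings / (2.0 * n_steps * spec.timestep)
        oracle_pd = VW_CM3 * oracle_q0 * NS_PER_S
        oracle_se = VW_CM3 * np.sqrt(crossings) / (2.0 * n_steps * spec.timestep) * NS_PER_S
        se = np.hypot(res.pd_se, oracle_se)
        assert abs(res.pd - oracle_pd) < 3 * se

    def test_poisson_se_covers_oracle_rate(self):
        """~95% of short replicates cover the long-run rate within 1.96 SE."""
        spec_long = SingleFileModelSpec(duration=400.0, seed=1, pmf=0.0)
        traj = simulate_single_file(spec_long)
        geom = ChannelGeometry(z_lumen=spec_long.pore_z_bounds, n_monomers=1)
        ref = diffusional_permeability(detect_events(traj, geom)).pd
        covered = 0
        n_rep = 100
        for seed in range(n_rep):
            spec = SingleFileModelSpec(duration=20.0, seed=1000 + seed, pmf=0.0)
            t = simulate_single_file(spec)
            r = diffusional_permeability(detect_events(t, geom))
            if abs(r.pd - ref) <= 1.96 * r.pd_se:
                covered += 1
        # binomial fluctuation allowance around the nominal 95%
        assert covered >= 90


class TestCollectiveCoordinate:
    def test_static_trajectory_stays_zero(self):
        rec = pd.DataFrame(
            {"frame": np.repeat(np.arange(50), 3), "id": np.tile(np.arange(3), 50),
             "x": 0.0, "y": 0.0, "z": np.tile([-0.3, 0.0, 0.4], 50)}
        )
        traj = TrajectorySet(times=0.1 * np.arange(50), records=rec)
        cc = collective_coordinate(traj, GEOM)
        assert np.allclose(cc.n, 0.0)

    def test_single_full_traversal_accumulates_unity(self):
        zs = np.linspace(-0.9, 0.9, 41)
        cc = collective_coordinate(_path_traj(zs), GEOM)
        assert cc.n[-1] == pytest.approx(1.0, abs=0.06)

    def test_msd_slope_matches_independent_diffusers(self):
        """MSD of n(t) is linear with slope 2 M D / L^2 (analytic oracle)."""
        M, D, L = 10, 0.01, 1.4
        traj = simulate_free_diffusers(M, D, L, 0.005, 40000, seed=2)
        geom = ChannelGeometry(z_lumen=(-L / 2, L / 2))
        cc = collective_coordinate(traj, geom)
        lags = np.array([2, 5, 10, 20])
        msd = np.array([np.mean((cc.n[l:] - cc.n[:-l]) ** 2) for l in lags])
        slope = np.polyfit(lags * 0.005, msd, 1)[0]
        assert slope == pytest.approx(2 * M * D / L**2, rel=0.1)

    def test_pf_of_frozen_system_is_zero(self):
        rec = pd.DataFrame(
            {"frame": np.arange(1000), "id": 0, "x": 0.0, "y": 0.0, "z": 0.0}
        )
        traj = TrajectorySet(times=0.01 * np.arange(1000), records=rec)
        cc = collective_coordinate(traj, GEOM)
        res = osmotic_permeability(cc)
        assert res.pf == 0.0

    def test_pf_matches_analytic_for_independent_diffusers(self):
        M, D, L = 10, 0.01, 1.4
        traj = simulate_free_diffusers(M, D, L, 0.005, 40000, seed=3)
        geom = ChannelGeometry(z_lumen=(-L / 2, L / 2))
        cc = collective_coordinate(traj, geom)
        res = osmotic_permeability(cc)
        assert res.pf == pytest.approx(VW_CM3 * M * D / L**2 * NS_PER_S, rel=0.1)

    def test_window_validation(self):
        traj = simulate_free_diffusers(2, 0.01, 1.4, 0.01, 500, seed=1)
        cc = collective_coordinate(traj, ChannelGeometry(z_lumen=(-0.7, 0.7)))
        with pytest.raises(ValidationError):
            osmotic_permeability(cc, fit_window=(2, 200))
        with pytest.raises(ValidationError):
            osmotic_permeability(cc, fit_window=(0, 10))


class TestEstimatorInvariances:
    def test_translation_and_time_reversal_invariance(self, hopping_traj):
        spec, traj = hopping_traj
        geom = ChannelGeometry(z_lumen=spec.pore_z_bounds, n_monomers=1)
        base_ev = detect_events(traj, geom)
        base_pd = diffusional_permeability(base_ev).pd
        base_pf = osmotic_permeability(collective_coordinate(traj, geom)).pf

        shifted = TrajectorySet(
            times=traj.times.copy(),
            records=traj.records.assign(z=traj.records["z"] + 2.0),
        )
        geom_shift = ChannelGeometry(
            z_lumen=(spec.pore_z_bounds[0] + 2.0, spec.pore_z_bounds[1] + 2.0),
            n_monomers=1,
        )
        assert diffusional_permeability(
            detect_events(shifted, geom_shift)).pd == pytest.approx(base_pd)
        assert osmotic_permeability(
            collective_coordinate(shifted, geom_shift)).pf == pytest.approx(base_pf)

        nf = traj.n_frames
        rev = traj.records.assign(frame=nf - 1 - traj.records["frame"])
        reversed_traj = TrajectorySet(times=traj.times.copy(), records=rev)
        assert diffusional_permeability(
            detect_events(reversed_traj, geom)).pd == pytest.approx(base_pd)
        assert osmotic_permeability(
            collective_coordinate(reversed_traj, geom)).pf == pytest.approx(
                base_pf, rel=1e-6)

    def test_pf_at_least_pd_on_single_file_runs(self, hopping_traj, brownian_traj):
        for spec, traj in (hopping_traj, brownian_traj):
            geom = ChannelGeometry(z_lumen=spec.pore_z_bounds, n_monomers=1)
            pf = osmotic_permeability(collective_coordinate(traj, geom)).pf
            pd_ = diffusional_permeability(detect_events(traj, geom)).pd
            assert pf >= pd_
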