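"""Axial density / PMF inversion, dipole order parameter, hydrogen bonds,
occupancy and crossing statistics."""

import numpy as np
import pandas as pd
import pytest

from poreflux import (
    AxialProfile,
    ChannelGeometry,
    HBondCriterion,
    TrajectorySet,
    axial_density,
    barrier_height,
    detect_events,
    dipole_order_parameter,
    occupancy_and_crossing,
    pmf_from_density,
    sample_boltzmann_trajectory,
)
from poreflux.constants import KB_KCAL_MOL_K
from poreflux.exceptions import ValidationError
from poreflux.profiles import PartnerSites, WaterFrame, hbond_profile, water_hbond_counts


def _uniform_slab_traj(density, z_range=(-0.7, 0.7), n_frames=400, seed=0):
    """Ideal-gas slab at a given 3D density inside a 0.4 x 0.4 nm column."""
    rng = np.random.default_rng(seed)
    lo, hi = z_range
    vol = 0.4 * 0.4 * (hi - lo)
    rows = []
    for f in range(n_frames):
        n = rng.poisson(density * vol)
        rows.append(
            pd.DataFrame(
                {"frame": f, "id": np.arange(n), "x": 0.0, "y": 0.0,
                 "z": lo + (hi - lo) * rng.random(n)}
            )
        )
    rec = pd.concat(rows, ignore_index=True)
    return TrajectorySet(times=np.arange(n_frames, dtype=float), records=rec)


GEOM = ChannelGeometry(z_lumen=(-0.7, 0.7), cross_section=(0.4, 0.4))


class TestAxialDensity:
    def test_bulk_slab_normalises_to_unity(self):
        traj = _uniform_slab_traj(33.37, seed=1)
        prof = axial_density(traj, GEOM, bin_width=0.1)
        assert np.nanmax(np.abs(prof.values - 1.0)) < 4 * np.nanmax(prof.sd)
        assert abs(np.nanmean(prof.values) - 1.0) < 0.02

    def test_half_density_scales_linearly(self):
        traj = _uniform_slab_traj(33.37 / 2, seed=2)
        prof = axial_density(traj, GEOM, bin_width=0.1)
        assert abs(np.nanmean(prof.values) - 0.5) < 0.02

    def test_boltzmann_samples_match_quadrature(self):
        """Binned n(z) tracks exp(-U/kT) integrated over each bin."""
        zt = np.linspace(-0.7, 0.7, 201)
        Ut = 1.2 * np.sin(2 * np.pi * zt / 0.9) ** 2
        traj = sample_boltzmann_trajectory(
            np.column_stack([zt, Ut]), 300.0, 400000, seed=3
        )
        prof = axial_density(traj, GEOM, bin_width=0.05)
        kT = KB_KCAL_MOL_K * 300.0
        # quadrature of the Boltzmann weight over each bin
        expect = []
        for lo, hi in zip(prof.bin_edges[:-1], prof.bin_edges[1:]):
            zs = np.linspace(lo, hi, 50)
            expect.append(np.trapezoid(np.exp(-np.interp(zs, zt, Ut) / kT), zs) / (hi - lo))
        expect = np.array(expect)
        ratio = prof.values / expect
        ratio /= ratio.mean()
        assert np.max(np.abs(ratio - 1.0)) < 0.05

    def test_validation(self):
        traj = _uniform_slab_traj(5.0, n_frames=5)
        with pytest.raises(ValidationError):
            axial_density(traj, GEOM, bin_width=-0.1)
        with pytest.raises(ValidationError):
            axial_density(traj, GEOM, z_range=(0.5, 0.5))


class TestPMF:
    def test_uniform_density_gives_zero_pmf(self):
        edges = np.linspace(-0.5, 0.5, 11)
        prof = AxialProfile(bin_edges=edges, values=np.ones(10),
                            counts=np.full(10, 1000), sd=np.zeros(10),
                            kind="density")
        pmf = pmf_from_density(prof, temperature=300.0)
        assert np.allclose(pmf.values, 0.0)

    def test_closed_form_kT_at_300K(self):
        edges = np.linspace(0, 0.2, 3)
        vals = np.array([1.0, np.exp(-1.0)])
        prof = AxialProfile(bin_edges=edges, values=vals,
                            counts=np.array([100, 100]), sd=np.zeros(2),
                            kind="density")
        pmf = pmf_from_density(prof, temperature=300.0)
        assert pmf.values[1] == pytest.approx(0.5962, abs=2e-4)

    def test_zero_count_bins_masked_not_imputed(self):
        edges = np.linspace(0, 0.3, 4)
        prof = AxialProfile(bin_edges=edges, values=np.array([1.0, 0.0, 0.5]),
                            counts=np.array([50, 0, 25]), sd=np.zeros(3),
                            kind="density")
        pmf = pmf_from_density(prof)
        assert np.isnan(pmf.values[1])
        assert np.isfinite(pmf.values[[0, 2]]).all()

    def test_double_well_recovered_within_tolerance(self):
        """Boltzmann inversion recovers an imposed double well to 0.1 kcal/mol."""
        zt = np.linspace(-0.7, 0.7, 301)
        Ut = 2.0 * ((zt / 0.45) ** 2 - 1.0) ** 2  # double well, barrier 2 kcal/mol
        traj = sample_boltzmann_trajectory(
            np.column_stack([zt, Ut]), 300.0, 600000, seed=4
        )
        dens = axial_density(traj, GEOM, bin_width=0.05)
        pmf = pmf_from_density(dens, temperature=300.0)
        well = pmf.counts >= 1000
        expect = np.interp(pmf.centers, zt, Ut)
        expect = expect - expect[well].min()
        w = pmf.values - np.nanmin(pmf.values[well])
        assert np.nanmax(np.abs(w[well] - expect[well])) < 0.1

    def test_barrier_heights_on_constructed_profiles(self):
        z = np.linspace(-0.75, 0.75, 31)
        edges = np.linspace(-0.775, 0.775, 32)
        for barrier in (2.5, 5.0):
            vals = barrier * np.exp(-(z / 0.2) ** 2)  # central peak, flat vestibules
            prof = AxialProfile(bin_edges=edges, values=vals,
                                counts=np.full(31, 100), sd=np.zeros(31),
                                kind="pmf")
            got = barrier_height(prof, region=(-0.4, 0.4),
                                 reference_region=(-0.75, -0.5))
            assert got == pytest.approx(barrier, abs=1e-4)

    def test_constant_profile_has_zero_barrier(self):
        edges = np.linspace(-0.5, 0.5, 11)
        prof = AxialProfile(bin_edges=edges, values=np.full(10, 1.3),
                            counts=np.full(10, 10), sd=np.zeros(10), kind="pmf")
        assert barrier_height(prof, region=(-0.3, 0.3)) == 0.0

    def test_masked_region_rejected(self):
        edges = np.linspace(-0.5, 0.5, 11)
        vals = np.full(10, np.nan)
        prof = AxialProfile(bin_edges=edges, values=vals,
                            counts=np.zeros(10), sd=np.zeros(10), kind="pmf")
        with pytest.raises(ValidationError):
            barrier_height(prof, region=(-0.3, 0.3))


def _dipole_traj(uz_fn, n=20000, seed=0):
    rng = np.random.default_rng(seed)
    z = -0.7 + 1.4 * rng.random(n)
    uz = uz_fn(z, rng)
    phi = 2 * np.pi * rng.random(n)
    s = np.sqrt(np.maximum(0, 1 - uz**2))
    rec = pd.DataFrame(
        {"frame": np.repeat(np.arange(n // 100), 100), "id": np.tile(np.arange(100), n // 100),
         "x": 0.0, "y": 0.0, "z": z,
         "ux": s * np.cos(phi), "uy": s * np.sin(phi), "uz": uz}
    )
    return TrajectorySet(times=np.arange(n // 100, dtype=float), records=rec)


class TestOrderParameter:
    def test_aligned_dipoles_give_unity(self):
        traj = _dipole_traj(lambda z, rng: np.ones_like(z))
        prof = dipole_order_parameter(traj, GEOM, bin_width=0.1)
        assert np.allclose(prof.values[np.isfinite(prof.values)], 1.0)

    def test_isotropic_dipoles_average_to_zero(self):
        traj = _dipole_traj(lambda z, rng: 2 * rng.random(z.size) - 1, seed=5)
        prof = dipole_order_parameter(traj, GEOM, bin_width=0.1)
        ok = prof.counts > 0
        se = prof.sd[ok] / np.sqrt(prof.counts[ok])
        assert np.all(np.abs(prof.values[ok]) < 3.5 * se)

    def test_imposed_flip_changes_sign_across_centre(self, brownian_traj):
        """Synthetic reorienting dipole field: opposite signs in the two
        halves of the pore, near zero in the vestibules."""
        _, traj = brownian_traj
        prof = dipole_order_parameter(traj, GEOM, bin_width=0.1,
                                      z_range=(-0.7, 0.7))
        mids = prof.centers
        lower = prof.values[(mids > -0.4) & (mids < -0.15)]
        upper = prof.values[(mids > 0.15) & (mids < 0.4)]
        assert np.nanmean(lower) < -0.2
        assert np.nanmean(upper) > 0.2
        vest = prof.values[np.abs(mids) > 0.55]
        assert np.nanmax(np.abs(vest)) < 0.15

    def test_sign_flips_under_global_inversion(self):
        traj = _dipole_traj(lambda z, rng: np.tanh(z / 0.1), seed=6)
        prof = dipole_order_parameter(traj, GEOM, bin_width=0.1)
        flipped_rec = traj.records.assign(
            ux=-traj.records["ux"], uy=-traj.records["uy"], uz=-traj.records["uz"]
        )
        flipped = TrajectorySet(times=traj.times, records=flipped_rec)
        prof2 = dipole_order_parameter(flipped, GEOM, bin_width=0.1)
        np.testing.assert_allclose(prof2.values, -prof.values, atol=1e-12)

    def test_bounded_in_minus_one_one(self, brownian_traj):
        _, traj = brownian_traj
        prof = dipole_order_parameter(traj, GEOM, bin_width=0.05)
        ok = np.isfinite(prof.values)
        assert np.all(prof.values[ok] >= -1.0) and np.all(prof.values[ok] <= 1.0)

    def test_missing_dipoles_rejected(self):
        traj = _uniform_slab_traj(5.0, n_frames=5)
        with pytest.raises(ValidationError):
            dipole_order_parameter(traj, GEOM)


def _random_waters(n, box, seed):
    rng = np.random.default_rng(seed)
    o = box * rng.random((n, 3))
    # two hydrogens at 0.1 nm, tetrahedral-ish random orientation
    h1d = rng.normal(size=(n, 3))
    h1d /= np.linalg.norm(h1d, axis=1)[:, None]
    h2d = rng.normal(size=(n, 3))
    h2d /= np.linalg.norm(h2d, axis=1)[:, None]
    return WaterFrame(o=o, h1=o + 0.1 * h1d, h2=o + 0.1 * h2d)


def _oracle_pair_counts(waters, criterion):
    """Exhaustive all-pairs water-water H-bond participation counts."""
    n = waters.o.shape[0]
    counts = np.zeros(n)
    for i in range(n):
        for h in (waters.h1[i], waters.h2[i]):
            for j in range(n):
                if i == j:
                    continue
                d = np.linalg.norm(waters.o[i] - waters.o[j])
                if d > criterion.max_DA_distance:
                    continue
                v1 = waters.o[i] - h
                v2 = waters.o[j] - h
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if 180.0 - ang <= criterion.max_angle:
                    counts[i] += 1
                    counts[j] += 1
    return counts


class TestHydrogenBonds:
    def test_ideal_collinear_pair_bonds_once_each(self):
        o = np.array([[0.0, 0.0, 0.0], [0.28, 0.0, 0.0]])
        h1 = np.array([[0.1, 0.0, 0.0], [0.38, 0.0, 0.0]])  # first donates to second
        h2 = np.array([[-0.03, 0.095, 0.0], [0.25, 0.095, 0.0]])
        ww, _ = water_hbond_counts(WaterFrame(o=o, h1=h1, h2=h2))
        assert ww.tolist() == [1.0, 1.0]

    def test_pair_beyond_cutoff_has_no_bond(self):
        o = np.array([[0.0, 0.0, 0.0], [0.40, 0.0, 0.0]])
        h1 = np.array([[0.1, 0.0, 0.0], [0.5, 0.0, 0.0]])
        h2 = np.array([[-0.1, 0.0, 0.0], [0.3, 0.0, 0.0]])
        ww, _ = water_hbond_counts(WaterFrame(o=o, h1=h1, h2=h2))
        assert np.all(ww == 0)

    def test_bent_geometry_rejected_by_angle(self):
        o = np.array([[0.0, 0.0, 0.0], [0.28, 0.0, 0.0]])
        # hydrogen pointing perpendicular: D-H...A far from linear
        h1 = np.array([[0.0, 0.1, 0.0], [0.28, 0.1, 0.0]])
        h2 = np.array([[0.0, -0.1, 0.0], [0.28, -0.1, 0.0]])
        ww, _ = water_hbond_counts(WaterFrame(o=o, h1=h1, h2=h2))
        assert np.all(ww == 0)

    def test_counts_match_exhaustive_oracle(self):
        crit = HBondCriterion()
        waters = _random_waters(100, box=1.2, seed=9)
        ww, _ = water_hbond_counts(waters, criterion=crit)
        oracle = _oracle_pair_counts(waters, crit)
        np.testing.assert_array_equal(ww, oracle)

    def test_water_partner_counts(self):
        o = np.array([[0.0, 0.0, 0.0]])
        h1 = np.array([[0.1, 0.0, 0.0]])
        h2 = np.array([[-0.1, 0.0, 0.0]])
        partners = PartnerSites(
            donor_heavy=np.array([[0.0, 0.28, 0.0]]),
            donor_h=np.array([[0.0, 0.18, 0.0]]),
            acceptors=np.array([[0.28, 0.0, 0.0]]),
        )
        ww, wp = water_hbond_counts(WaterFrame(o=o, h1=h1, h2=h2), partners=partners)
        assert ww[0] == 0
        assert wp[0] == 2.0  # donates via h1 to acceptor, accepts from partner donor

    def test_profile_binning(self):
        crit = HBondCriterion()
        frames = [_random_waters(60, box=0.7, seed=s) for s in range(3)]
        # place the box around the lumen span
        for fr in frames:
            fr.o[:, 2] -= 0.35
            fr.h1[:, 2] -= 0.35
            fr.h2[:, 2] -= 0.35
        prof_ww, prof_wp = hbond_profile(frames, GEOM, criterion=crit, bin_width=0.35)
        assert prof_ww.kind == "hbond_ww"
        total_obs = sum((np.abs(fr.o[:, 2]) <= 0.7).sum() for fr in frames)
        assert prof_ww.counts.sum() == total_obs
        assert np.all(prof_wp.values[prof_wp.counts > 0] == 0)  # no partners given

    def test_criterion_validation(self):
        with pytest.raises(ValidationError):
            HBondCriterion(max_DA_distance=-0.1)
        with pytest.raises(ValidationError):
            HBondCriterion(max_angle=120.0)


class TestExports:
    def test_profile_table_and_plot(self, tmp_path):
        traj = _uniform_slab_traj(33.37, n_frames=50, seed=3)
        prof = axial_density(traj, GEOM, bin_width=0.1)
        prof.to_table(tmp_path / "density.tsv")
        header = (tmp_path / "density.tsv").read_text().splitlines()[0]
        assert header.split("\t") == ["z_mid", "value", "sd", "count"]
        from poreflux.profiles import plot_profiles

        plot_profiles([prof], tmp_path / "prof.png")
        assert (tmp_path / "prof.png").stat().st_size > 0


class TestOccupancyAndCrossing:
    def test_permanently_inside_molecule_counts_one(self):
        rec = pd.DataFrame(
            {"frame": np.arange(100), "id": 0, "x": 0.0, "y": 0.0, "z": 0.1}
        )
        traj = TrajectorySet(times=0.1 * np.arange(100), records=rec)
        occ, crossing = occupancy_and_crossing(traj, GEOM, None)
        assert occ == pytest.approx(1.0)
        assert np.isnan(crossing)

    def test_no_events_reports_missing_crossing_time(self):
        rec = pd.DataFrame(
            {"frame": np.arange(30), "id": 0, "x": 0.0, "y": 0.0, "z": -1.0}
        )
        traj = TrajectorySet(times=0.1 * np.arange(30), records=rec)
        ev = detect_events(traj, GEOM)
        occ, crossing = occupancy_and_crossing(traj, GEOM, ev)
        assert occ == 0.0
        assert np.isnan(crossing)

    def test_hopping_occupancy_within_3se_of_oracle(self, hopping_traj):
        from _hopping_oracle import run_oracle

        spec, traj = hopping_traj
        geom = ChannelGeometry(z_lumen=spec.pore_z_bounds, n_monomers=1)
        occ, _ = occupancy_and_crossing(traj, geom, None)
        U = list(spec.potential(
            spec.pore_z_bounds[0]
            + (spec.pore_z_bounds[1] - spec.pore_z_bounds[0]) / spec.n_sites
            * (np.arange(spec.n_sites) + 0.5)) / spec.kT)
        samples, _ = run_oracle(
            60000, spec.n_sites, U, spec.hop_rate * spec.timestep, spec.activity,
            spec.buffer_mean, spec.buffer_relax_rate * spec.timestep, seed=13,
            record_every=5,
        )
        burn = len(samples) // 10
        oracle = np.asarray(samples[burn:], float)
        blocks = np.array_split(oracle, 10)
        se = np.std([b.mean() for b in blocks], ddof=1) / np.sqrt(10)
        assert abs(occ - oracle.mean()) < 3 * max(se, 0.02)
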