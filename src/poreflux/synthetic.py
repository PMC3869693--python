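"""Ground-truth-known synthetic data: single-file pore trajectories and
stopped-flow relaxation traces.

Two interchangeable single-file dynamics are provided:

* a discrete **vacancy-hopping** lattice chain (``variant="hopping"``) whose
  update rules are simple enough to re-implement by brute force, making it
  the oracle-friendly variant; and
* a continuous **overdamped Brownian** chain with hard-core no-passing
  (``variant="brownian"``), which exercises the binning/PMF machinery with
  off-lattice coordinates and optional dipole vectors.

Both couple the pore to ideal-gas reservoir slabs beyond the two pore ends
(grand-canonical birth/death at fixed mean population) and expose the same
:class:`~poreflux.types.TrajectorySet`.

Default parameters emulate the study conditions of a UT-B-like single-file
pore: a 1.4 nm lumen (7 sites), a mildly attractive in-pore potential and a
bulk-water reservoir giving a mean luminal occupancy near 5 waters, and a
hop rate placing complete-translocation rates at a few tenths per ns with
crossing times of order 0.5 ns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_TRACE_TEMPERATURE_K,
    KB_KCAL_MOL_K,
    R_KCAL_MOL_K,
    TIP3P_BULK_DENSITY_NM3,
)
from .exceptions import ValidationError
from .types import StoppedFlowTrace, TrajectorySet


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class SingleFileModelSpec:
    """Parameters of the synthetic single-file pore.

    ``n_sites`` applies to the hopping variant (site spacing = lumen length
    / n_sites); the Brownian variant uses the continuous span directly.
    ``pmf`` is either a constant (kcal/mol, applied inside the pore) or a
    tabulated (z, U) array covering the pore bounds.  ``reservoir_density``
    is in molecules/nm^3; the dimensionless reservoir activity is
    reservoir_density / 33.37, so bulk water corresponds to activity 1.
    """

    variant: str = "hopping"
    n_sites: int = 7
    pore_z_bounds: tuple = (-0.7, 0.7)
    hop_rate: float = 200.0  # attempt rate per particle, 1/ns (hopping)
    diffusion: float = 0.5  # nm^2/ns (brownian)
    pmf: object = -0.6  # kcal/mol, constant or (n,2) table
    reservoir_density: float = TIP3P_BULK_DENSITY_NM3
    particle_radius: float = 0.1  # nm, hard core (brownian)
    timestep: float = 0.002  # ns
    duration: float = 200.0  # ns (after burn-in)
    seed: int = 0
    temperature: float = 300.0  # K
    buffer_len: float = 0.3  # nm, reservoir slab beyond each pore end
    buffer_mean: float = 4.0  # mean particles per slab
    buffer_relax_rate: float | None = None  # 1/ns; default 2 (hopping) / 60 (brownian)
    burn_in_fraction: float = 0.1
    save_every: int | None = None  # record every this many steps; default 5 / 1
    dipole_kappa: Callable | None = None  # z -> orientation concentration

    def __post_init__(self) -> None:
        lo, hi = self.pore_z_bounds
        if not lo < hi:
            raise ValidationError("pore_z_bounds must be ordered")
        if self.timestep <= 0:
            raise ValidationError("timestep must be positive")
        if self.duration < 0:
            raise ValidationError("duration must be non-negative")
        if self.variant == "hopping" and self.hop_rate <= 0:
            raise ValidationError("hop_rate must be positive")
        if self.variant == "brownian" and self.diffusion <= 0:
            raise ValidationError("diffusion constant must be positive")
        if self.reservoir_density <= 0:
            raise ValidationError("reservoir_density must be positive")
        if self.buffer_relax_rate is None:
            # the Brownian reservoir must replenish much faster than the
            # channel conducts (b * rate >> D / L) or it throttles the
            # collective current fluctuations
            self.buffer_relax_rate = 60.0 if self.variant == "brownian" else 2.0
        if self.save_every is None:
            self.save_every = 1 if self.variant == "brownian" else 5
        self.potential(np.array(self.pore_z_bounds))  # validate pmf coverage

    @property
    def kT(self) -> float:
        return KB_KCAL_MOL_K * self.temperature

    @property
    def activity(self) -> float:
        return self.reservoir_density / TIP3P_BULK_DENSITY_NM3

    def potential(self, z) -> np.ndarray:
        """U(z) in kcal/mol; zero outside the pore bounds.

        A constant ``pmf`` is ramped linearly to zero over 0.1 nm at each
        pore mouth so the Brownian integrator never steps across a
        discontinuity; a tabulated pmf is interpolated as given.
        """
        z = np.atleast_1d(np.asarray(z, float))
        lo, hi = self.pore_z_bounds
        inside = (z >= lo) & (z <= hi)
        if np.isscalar(self.pmf) or np.ndim(self.pmf) == 0:
            w = 0.1
            ramp = np.clip((z - lo) / w, 0.0, 1.0) * np.clip((hi - z) / w, 0.0, 1.0)
            U = np.where(inside, float(self.pmf) * ramp, 0.0)
        else:
            tab = np.asarray(self.pmf, float)
            if tab.ndim != 2 or tab.shape[1] != 2:
                raise ValidationError("tabulated pmf must be an (n,2) array of (z, U)")
            if tab[0, 0] > lo or tab[-1, 0] < hi:
                raise ValidationError("pmf table does not cover the pore bounds")
            U = np.where(inside, np.interp(z, tab[:, 0], tab[:, 1]), 0.0)
        return U


@dataclass
class StoppedFlowSpec:
    """Mono-/bi-exponential relaxation trace parameters (rates in 1/s)."""

    rates: Sequence[float] = (6.15,)
    amplitudes: Sequence[float] = (1.0,)
    baseline: float = 0.0
    noise_sd: float = 0.0
    dt: float = 1e-3  # s
    duration: float = 1.0  # s
    temperature: float = DEFAULT_TRACE_TEMPERATURE_K
    direction: str = "shrink"
    seed: int = 0

    def __post_init__(self) -> None:
        self.rates = tuple(float(r) for r in np.atleast_1d(self.rates))
        self.amplitudes = tuple(float(a) for a in np.atleast_1d(self.amplitudes))
        if any(r <= 0 for r in self.rates):
            raise ValidationError("rates must be positive")
        if len(self.amplitudes) != len(self.rates):
            raise ValidationError("one amplitude per rate is required")
        if self.dt <= 0 or self.duration <= 0:
            raise ValidationError("sampling grid must have positive step and duration")
        if self.duration < 5.0 / min(self.rates):
            raise ValidationError("duration must cover at least 5 / min(rates)")


@dataclass
class ArrheniusSeriesSpec:
    """Rates following k(T) = A exp(-Ea / (R T)) with multiplicative noise."""

    Ea: float = 5.1  # kcal/mol
    prefactor: float = 1.0e5  # 1/s
    temperatures: Sequence[float] = (278.15, 283.15, 288.15, 293.15, 298.15, 303.15)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.temperatures = tuple(float(t) for t in np.atleast_1d(self.temperatures))
        if len(self.temperatures) == 0:
            raise ValidationError("temperature list must not be empty")
        if len(set(self.temperatures)) < 2:
            raise ValidationError("at least 2 distinct temperatures are required")
        if self.Ea < 0:
            raise ValidationError("Ea must be non-negative")


# ---------------------------------------------------------------------------
# single-file simulators
# ---------------------------------------------------------------------------

def simulate_single_file(spec: SingleFileModelSpec) -> TrajectorySet:
    """Run the requested single-file variant and return the trajectory.

    The first ``burn_in_fraction`` of the run is simulated in addition to
    ``duration`` and discarded, so the returned frames are drawn from the
    stationary regime; frame times restart at 0.  ``duration = 0`` returns
    a single frame holding the initial configuration.
    """
    if spec.variant == "hopping":
        return _simulate_hopping(spec)
    if spec.variant == "brownian":
        return _simulate_brownian(spec)
    raise ValidationError(f"unknown single-file variant {spec.variant!r}")


def _initial_frame_state(spec: SingleFileModelSpec, rng):
    """Initial (ids, z) drawn near the product-measure occupancy."""
    lo, hi = spec.pore_z_bounds
    if spec.variant == "hopping":
        spacing = (hi - lo) / spec.n_sites
        site_z = lo + spacing * (np.arange(spec.n_sites) + 0.5)
    else:
        site_z = np.linspace(lo + 0.1, hi - 0.1, max(2, spec.n_sites))
    U = spec.potential(site_z) / spec.kT
    w = spec.activity * np.exp(-U)
    occupied = rng.random(site_z.size) < w / (1.0 + w)
    zs = list(site_z[occupied])
    nb = max(1, int(spec.buffer_mean))
    zs += list(lo - spec.buffer_len * rng.random(nb))
    zs += list(hi + spec.buffer_len * rng.random(nb))
    z = np.asarray(zs, float)
    return np.arange(z.size, dtype=np.int64), z


def _initial_frame(spec: SingleFileModelSpec) -> TrajectorySet:
    rng = np.random.default_rng(spec.seed)
    ids, z = _initial_frame_state(spec, rng)
    rec = pd.DataFrame({"frame": 0, "id": ids, "x": 0.0, "y": 0.0, "z": z})
    return TrajectorySet(times=np.array([0.0]), records=rec)


def _simulate_hopping(spec: SingleFileModelSpec) -> TrajectorySet:
    from ._hopping import run_hopping

    if spec.duration == 0:
        return _initial_frame(spec)
    lo, hi = spec.pore_z_bounds
    n = spec.n_sites
    spacing = (hi - lo) / n
    site_z = lo + spacing * (np.arange(n) + 0.5)
    U = spec.potential(site_z) / spec.kT
    q = spec.hop_rate * spec.timestep
    if q > 0.6:
        raise ValidationError(
            "hop_rate * timestep > 0.6; reduce the timestep for valid attempt probabilities"
        )
    total_ns = spec.duration * (1.0 + spec.burn_in_fraction)
    n_steps = int(round(total_ns / spec.timestep))
    burn_steps = int(round(spec.duration * spec.burn_in_fraction / spec.timestep))
    burn_frames = (burn_steps + spec.save_every - 1) // spec.save_every
    death_p = min(0.5, spec.buffer_relax_rate * spec.timestep)
    cap = max(16, int(4 * spec.buffer_mean))
    n_saved = n_steps // spec.save_every + 1
    max_rec = n_saved * (n + 2 * cap)
    rec_frame = np.empty(max_rec, np.int64)
    rec_id = np.empty(max_rec, np.int64)
    rec_z = np.empty(max_rec, np.float64)
    n_rec, n_frames = run_hopping(
        n_steps, spec.save_every, n, U, q, spec.activity,
        spec.buffer_mean, death_p, cap, int(spec.seed) % (2**31 - 1),
        site_z, lo, hi, spec.buffer_len,
        rec_frame, rec_id, rec_z,
    )
    frames = rec_frame[:n_rec]
    keep = frames >= burn_frames
    frames = frames[keep] - burn_frames
    rec = pd.DataFrame(
        {
            "frame": frames,
            "id": rec_id[:n_rec][keep],
            "x": 0.0,
            "y": 0.0,
            "z": rec_z[:n_rec][keep],
        }
    )
    frame_dt = spec.timestep * spec.save_every
    times = frame_dt * np.arange(n_frames - burn_frames)
    return TrajectorySet(times=times, records=rec)


def _sample_dipoles(rng, kappa: np.ndarray) -> np.ndarray:
    """Unit vectors with p(u) ~ exp(kappa * u_z); kappa may vary per sample."""
    kappa = np.asarray(kappa, float)
    u = rng.random(kappa.size)
    c = np.empty(kappa.size)
    small = np.abs(kappa) < 1e-8
    c[small] = 2.0 * u[small] - 1.0
    k = kappa[~small]
    c[~small] = np.log(np.exp(-k) + u[~small] * (np.exp(k) - np.exp(-k))) / k
    c = np.clip(c, -1.0, 1.0)
    phi = 2.0 * np.pi * rng.random(kappa.size)
    s = np.sqrt(np.maximum(0.0, 1.0 - c**2))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), c])


def reorienting_dipole_field(kappa0: float = 2.5, switch_width: float = 0.1,
                             vestibule: float = 0.45) -> Callable:
    """kappa(z) imposing opposite preferred dipole orientations in the two
    pore halves and free rotation (kappa ~ 0) outside ``|z| > vestibule``."""

    def kappa(z):
        z = np.asarray(z, float)
        k = kappa0 * np.tanh(z / switch_width)
        return np.where(np.abs(z) > vestibule, 0.0, k)

    return kappa


def _simulate_brownian(spec: SingleFileModelSpec) -> TrajectorySet:
    """Overdamped Brownian single file with hard cores.

    Particles evolve as independent overdamped walkers in the tabulated
    potential; the hard-core no-passing constraint is enforced by restoring
    the z-order of the pore-region particles after every step (for identical
    particles, order restoration is statistically equivalent to elastic
    hard-core collisions).  Reservoir slabs beyond the pore ends are kept
    well-mixed: slab positions are resampled uniformly every step before
    the Brownian move, so re-entries from the reservoir are memoryless, as
    they would be from a three-dimensional bulk; the slabs also undergo
    grand-canonical birth/death at mean population ``buffer_mean``.  Outer
    slab edges are reflecting.
    """
    if spec.duration == 0:
        return _initial_frame(spec)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.pore_z_bounds
    r = spec.particle_radius
    D, dt, kT = spec.diffusion, spec.timestep, spec.kT
    z_min, z_max = lo - spec.buffer_len, hi + spec.buffer_len
    sigma = np.sqrt(2.0 * D * dt)
    zg = np.linspace(z_min, z_max, 1024)
    Fg = -np.gradient(spec.potential(zg), zg)  # kcal/mol/nm

    total_ns = spec.duration * (1.0 + spec.burn_in_fraction)
    n_steps = int(round(total_ns / dt))
    burn_steps = int(round(spec.duration * spec.burn_in_fraction / dt))
    death_p = min(0.5, spec.buffer_relax_rate * dt)
    birth_p = spec.buffer_mean * death_p

    ids, z = _initial_frame_state(spec, rng)
    next_id = int(ids.max()) + 1 if ids.size else 0

    rows_frame, rows_id, rows_z = [], [], []
    frame = 0
    for step in range(n_steps):
        if z.size:
            # well-mixed reservoirs: resample slab positions before stepping
            in_bot = (z >= z_min) & (z < lo)
            in_top = (z > hi) & (z <= z_max)
            z = np.where(in_bot, z_min + (lo - z_min) * rng.random(z.size), z)
            z = np.where(in_top, hi + (z_max - hi) * rng.random(z.size), z)
            old_z = z
            prop = (
                old_z
                + (D / kT) * np.interp(old_z, zg, Fg) * dt
                + sigma * rng.standard_normal(old_z.size)
            )
            prop = np.where(prop < z_min, 2 * z_min - prop, prop)
            prop = np.where(prop > z_max, 2 * z_max - prop, prop)
            # no-passing: among particles in the pore span (before or after
            # the move), hand the sorted proposed positions back in the order
            # of the previous positions
            dom = ((old_z > lo - r) & (old_z < hi + r)) | ((prop > lo - r) & (prop < hi + r))
            if dom.sum() > 1:
                idx = np.flatnonzero(dom)
                order = np.argsort(old_z[idx], kind="stable")
                prop[idx[order]] = np.sort(prop[idx])
            z = prop
        # record before the grand-canonical update so a particle that has
        # just exited is always observed in the slab at least once
        if step % spec.save_every == 0:
            rows_frame.append(np.full(z.size, frame, dtype=np.int64))
            rows_id.append(ids.copy())
            rows_z.append(z.copy())
            frame += 1
        # grand-canonical slabs
        for s_lo, s_hi in ((z_min, lo), (hi, z_max)):
            in_slab = (z >= s_lo) & (z < s_hi)
            kill = in_slab & (rng.random(z.size) < death_p) if z.size else in_slab
            if z.size and kill.any():
                z, ids = z[~kill], ids[~kill]
            if rng.random() < birth_p:
                z = np.append(z, s_lo + (s_hi - s_lo) * rng.random())
                ids = np.append(ids, next_id)
                next_id += 1

    frames = np.concatenate(rows_frame) if rows_frame else np.array([], dtype=np.int64)
    all_id = np.concatenate(rows_id) if rows_id else np.array([], dtype=np.int64)
    all_z = np.concatenate(rows_z) if rows_z else np.array([])
    burn_frames = (burn_steps + spec.save_every - 1) // spec.save_every
    keep = frames >= burn_frames
    frames = frames[keep] - burn_frames
    all_id, all_z = all_id[keep], all_z[keep]
    rec = pd.DataFrame(
        {
            "frame": frames,
            "id": all_id,
            "x": 0.05 * rng.standard_normal(all_z.size),
            "y": 0.05 * rng.standard_normal(all_z.size),
            "z": all_z,
        }
    )
    if spec.dipole_kappa is not None:
        u = _sample_dipoles(rng, np.asarray(spec.dipole_kappa(all_z), float))
        rec["ux"], rec["uy"], rec["uz"] = u[:, 0], u[:, 1], u[:, 2]
    frame_dt = dt * spec.save_every
    times = frame_dt * np.arange(frame - burn_frames)
    return TrajectorySet(times=times, records=rec)


def simulate_free_diffusers(
    n_particles: int,
    diffusion: float,
    length: float,
    timestep: float,
    n_steps: int,
    seed: int = 0,
    boundary: str = "reflect",
) -> TrajectorySet:
    """Independent Brownian particles on a segment of the pore axis.

    With reflecting walls the particles stay confined to
    ``[-length/2, length/2]``; this is the analytic reference system for the
    collective-diffusion estimator (D_n = n D / L^2 at lags short against
    the wall-collision time).
    """
    rng = np.random.default_rng(seed)
    steps = np.sqrt(2 * diffusion * timestep) * rng.standard_normal((n_steps, n_particles))
    z0 = length * rng.random(n_particles)
    z = np.vstack([z0, z0 + np.cumsum(steps, axis=0)])
    if boundary == "reflect":
        z = np.abs(np.mod(z, 2 * length) - length)
        z = length - z  # fold into [0, L]
    elif boundary == "periodic":
        z = np.mod(z, length)
    else:
        raise ValidationError("boundary must be 'reflect' or 'periodic'")
    z = z - length / 2.0
    n_frames = n_steps + 1
    rec = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), n_particles),
            "id": np.tile(np.arange(n_particles), n_frames),
            "x": 0.0,
            "y": 0.0,
            "z": z.ravel(),
        }
    )
    return TrajectorySet(times=timestep * np.arange(n_frames), records=rec)


def sample_boltzmann_trajectory(
    pmf_table,
    temperature: float,
    n_samples: int,
    seed: int = 0,
    particles_per_frame: int = 100,
    z_range: tuple | None = None,
) -> TrajectorySet:
    """i.i.d. positions drawn from exp(-U(z)/kT) by rejection sampling.

    Packs the samples into frames of ``particles_per_frame`` molecules, so
    the density/PMF estimators can consume them like a trajectory.
    """
    tab = np.asarray(pmf_table, float)
    if tab.ndim != 2 or tab.shape[1] != 2:
        raise ValidationError("pmf_table must be an (n,2) array of (z, U)")
    rng = np.random.default_rng(seed)
    kT = KB_KCAL_MOL_K * temperature
    z_lo, z_hi = (tab[0, 0], tab[-1, 0]) if z_range is None else z_range
    Umin = tab[:, 1].min()
    out = np.empty(n_samples)
    filled = 0
    while filled < n_samples:
        m = max(1024, 2 * (n_samples - filled))
        zc = z_lo + (z_hi - z_lo) * rng.random(m)
        w = np.exp(-(np.interp(zc, tab[:, 0], tab[:, 1]) - Umin) / kT)
        acc = zc[rng.random(m) < w]
        take = min(acc.size, n_samples - filled)
        out[filled : filled + take] = acc[:take]
        filled += take
    n_frames = int(np.ceil(n_samples / particles_per_frame))
    pad = n_frames * particles_per_frame - n_samples
    if pad:
        out = np.concatenate([out, out[:pad]])
        n_samples = out.size
    rec = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), particles_per_frame),
            "id": np.tile(np.arange(particles_per_frame), n_frames),
            "x": 0.0,
            "y": 0.0,
            "z": out,
        }
    )
    return TrajectorySet(times=np.arange(n_frames, dtype=float), records=rec)


# ---------------------------------------------------------------------------
# stopped-flow and Arrhenius generators
# ---------------------------------------------------------------------------

def generate_stoppedflow_trace(spec: StoppedFlowSpec) -> StoppedFlowTrace:
    """signal(t) = baseline + sum_i A_i exp(-k_i t) + Gaussian noise."""
    n = int(round(spec.duration / spec.dt)) + 1
    if n < 2:
        raise ValidationError("sampling grid is empty")
    t = spec.dt * np.arange(n)
    y = np.full(n, spec.baseline, dtype=float)
    for k, A in zip(spec.rates, spec.amplitudes):
        y += A * np.exp(-k * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + spec.noise_sd * rng.standard_normal(n)
    meta = {
        "true_rates": ",".join(f"{k:.6g}" for k in spec.rates),
        "direction": spec.direction,
    }
    return StoppedFlowTrace(
        times=t,
        signal=y,
        temperature=spec.temperature,
        condition={"shrink": "osmotic", "swell": "osmotic", "exchange": "D2O-exchange"}.get(
            spec.direction, spec.direction
        ),
        metadata=meta,
    )


def generate_arrhenius_series(spec: ArrheniusSeriesSpec) -> list:
    """[(T, rate)] with rate = A exp(-Ea/(R T)) * exp(noise_cv * N(0,1))."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for T in spec.temperatures:
        k = spec.prefactor * np.exp(-spec.Ea / (R_KCAL_MOL_K * T))
        if spec.noise_cv > 0:
            k *= np.exp(spec.noise_cv * rng.standard_normal())
        out.append((T, float(k)))
    return out


# ---------------------------------------------------------------------------
# benchmark fixture
# ---------------------------------------------------------------------------

def benchmark_trajectory_path() -> str:
    """Path of the packaged 257-event / 200 ns benchmark trajectory.

    The file was produced by :func:`make_benchmark_trajectory` with its
    default arguments and anchors the event counter's turnover arithmetic
    (0.43 events/monomer/ns over 3 monomers).
    """
    from importlib.resources import files

    return str(files("poreflux").joinpath("data/benchmark_257.tsv"))

def make_benchmark_trajectory(
    n_events: int = 257,
    duration: float = 200.0,
    frame_dt: float = 0.1,
    seed: int = 7,
) -> TrajectorySet:
    """Deterministic trajectory holding exactly ``n_events`` complete
    translocations spread over ``duration`` ns.

    Each event is one molecule appearing in a vestibule, crossing the
    +/-0.75 nm event planes through the lumen over ~0.6 ns, and leaving on
    the far side; directions alternate in a fixed pattern.  The trajectory
    regression-tests the event counter's turnover arithmetic.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / frame_dt)) + 1
    # two frames beyond each event plane so the count survives frame
    # subsampling by 2
    path = np.array([-0.9, -0.8, -0.5, -0.18, 0.18, 0.5, 0.8, 0.9])
    rows = []
    for i in range(n_events):
        t_start = (i + 0.5) * duration / (n_events + 1)
        f0 = int(round(t_start / frame_dt))
        f0 = min(f0, n_frames - len(path) - 1)
        direction = 1 if (i % 3) else -1
        zs = path * direction
        for j, zv in enumerate(zs):
            rows.append((f0 + j, i, 0.0, 0.0, zv + 0.01 * rng.standard_normal()))
    rec = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "z"])
    rec = rec.astype({"frame": int, "id": int})
    return TrajectorySet(times=frame_dt * np.arange(n_frames), records=rec)
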