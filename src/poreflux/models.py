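"""Model/Results objects: the statsmodels-shaped surface of the package.

Three fitted models cover the three kinds of data the package analyses:

* :class:`ExponentialDecayModel` -- a stopped-flow relaxation trace;
  ``fit()`` estimates the rate constant(s), amplitudes and baseline.
* :class:`ArrheniusModel` -- a (temperature, rate) series; ``fit()``
  estimates the activation energy and prefactor.
* :class:`ChannelTransportModel` -- an equilibrium pore trajectory;
  ``fit()`` estimates p_f (collective diffusion), p_d (event counting),
  occupancy, crossing time and turnover.

Each Results object carries estimates, standard errors and a ``summary()``
table; profile extraction hangs off :class:`ChannelTransportResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinetics, permeation, profiles
from .constants import VW_CM3
from .exceptions import ValidationError
from .types import (
    CellParams,
    ChannelGeometry,
    FitResult,
    PermeabilityRecord,
    StoppedFlowTrace,
    TrajectorySet,
)


def _rule(width=58):
    return "-" * width


# ---------------------------------------------------------------------------
# exponential relaxation
# ---------------------------------------------------------------------------

class ExponentialDecayModel:
    """Mono- or bi-exponential relaxation model for a stopped-flow trace."""

    def __init__(self, times, signal, temperature: float | None = None):
        self.times = np.asarray(times, float)
        self.signal = np.asarray(signal, float)
        self.temperature = temperature

    @classmethod
    def from_trace(cls, trace: StoppedFlowTrace) -> "ExponentialDecayModel":
        return cls(trace.times, trace.signal, temperature=trace.temperature)

    def fit(self, n_exponentials: int = 1) -> "ExponentialDecayResults":
        res = kinetics.fit_exponential((self.times, self.signal), n_exponentials)
        return ExponentialDecayResults(model=self, fit=res)

    def predict(self, params: FitResult, times=None) -> np.ndarray:
        t = self.times if times is None else np.asarray(times, float)
        y = np.full_like(t, params.baseline, dtype=float)
        for A, k in zip(params.amplitudes, params.rates):
            y += A * np.exp(-k * t)
        return y


@dataclass
class ExponentialDecayResults:
    model: ExponentialDecayModel
    fit: FitResult

    @property
    def k(self) -> float:
        return self.fit.k

    @property
    def k_se(self) -> float:
        return float(self.fit.rate_se[0])

    def permeability(self, params: CellParams, kind: str = "Pf",
                     species: str | None = None) -> PermeabilityRecord:
        if kind == "Pf":
            return kinetics.osmotic_Pf(self.k, params, k_se=self.k_se)
        if kind == "Pd":
            return kinetics.diffusional_Pd(self.k, params, k_se=self.k_se)
        if kind == "P":
            return kinetics.solute_permeability(self.k, params, species or "NH3",
                                                k_se=self.k_se)
        raise ValidationError(f"unknown permeability kind {kind!r}")

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Exponential relaxation fit",
            _rule(),
            f"n_exponentials      {f.n_exponentials}",
        ]
        for i, (k, kse, A, Ase) in enumerate(
            zip(f.rates, f.rate_se, f.amplitudes, f.amplitude_se), 1
        ):
            lines.append(f"k{i} (1/s)            {k:.6g} +/- {kse:.3g}")
            lines.append(f"A{i}                  {A:.6g} +/- {Ase:.3g}")
        lines += [
            f"baseline            {f.baseline:.6g} +/- {f.baseline_se:.3g}",
            f"residual RMS        {f.residual_rms:.3g}",
        ]
        if f.degenerate:
            lines.append("warning: phases degenerate (rate ratio < 3)")
        lines.append(_rule())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Arrhenius
# ---------------------------------------------------------------------------

class ArrheniusModel:
    """ln k = ln A - Ea / (R T) regression over a temperature series."""

    def __init__(self, temperatures, rates):
        self.temperatures = np.asarray(temperatures, float)
        self.rates = np.asarray(rates, float)
        if self.temperatures.shape != self.rates.shape:
            raise ValidationError("temperatures and rates must align")

    @classmethod
    def from_series(cls, series) -> "ArrheniusModel":
        arr = np.asarray(list(series), float)
        return cls(arr[:, 0], arr[:, 1])

    def fit(self) -> "ArrheniusResults":
        Ea, A, se = kinetics.arrhenius_Ea(zip(self.temperatures, self.rates))
        return ArrheniusResults(model=self, Ea=Ea, prefactor=A, Ea_se=se)


@dataclass
class ArrheniusResults:
    model: ArrheniusModel
    Ea: float  # kcal/mol
    prefactor: float  # 1/s
    Ea_se: float

    def predict(self, temperatures) -> np.ndarray:
        from .constants import R_KCAL_MOL_K

        T = np.asarray(temperatures, float)
        return self.prefactor * np.exp(-self.Ea / (R_KCAL_MOL_K * T))

    def summary(self) -> str:
        return "\n".join(
            [
                "Arrhenius fit",
                _rule(),
                f"Ea (kcal/mol)       {self.Ea:.4g} +/- {self.Ea_se:.2g}",
                f"prefactor (1/s)     {self.prefactor:.4g}",
                f"n temperatures      {len(self.model.temperatures)}",
                _rule(),
            ]
        )


# ---------------------------------------------------------------------------
# channel transport
# ---------------------------------------------------------------------------

class ChannelTransportModel:
    """Equilibrium water-transport model of a pore trajectory.

    Wraps the event-counting p_d estimator and the collective-diffusion
    p_f estimator over a :class:`TrajectorySet` plus
    :class:`ChannelGeometry`; profiles are available from the results.
    """

    def __init__(self, traj: TrajectorySet, geom: ChannelGeometry):
        self.traj = traj
        self.geom = geom

    def fit(self, vw: float = VW_CM3, fit_window: tuple = (2, 20)) -> "ChannelTransportResults":
        events = permeation.detect_events(self.traj, self.geom)
        pd_part = permeation.diffusional_permeability(events, vw=vw)
        cc = permeation.collective_coordinate(self.traj, self.geom)
        pf_part = permeation.osmotic_permeability(cc, vw=vw, fit_window=fit_window)
        occ, crossing = profiles.occupancy_and_crossing(self.traj, self.geom, events)
        return ChannelTransportResults(
            model=self,
            events=events,
            collective=cc,
            pf=pf_part.pf,
            pf_se=pf_part.pf_se,
            pd=pd_part.pd,
            pd_se=pd_part.pd_se,
            D_n=pf_part.D_n,
            q0=pd_part.q0,
            vw=vw,
            occupancy=occ,
            crossing_time=crossing,
        )


@dataclass
class ChannelTransportResults:
    model: ChannelTransportModel
    events: object
    collective: object
    pf: float
    pf_se: float
    pd: float
    pd_se: float
    D_n: float
    q0: float
    vw: float
    occupancy: float
    crossing_time: float
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def single_file_N(self) -> float:
        return self.pf / self.pd - 1.0 if self.pd > 0 else float("nan")

    @property
    def turnover(self) -> tuple:
        return permeation.turnover_rate(self.events)

    def density_profile(self, bin_width: float = 0.05, z_range=None, **kw):
        return profiles.axial_density(
            self.model.traj, self.model.geom, bin_width=bin_width, z_range=z_range, **kw
        )

    def pmf_profile(self, temperature: float = 300.0, bin_width: float = 0.05,
                    z_range=None, reference_region=None):
        dens = self.density_profile(bin_width=bin_width, z_range=z_range)
        return profiles.pmf_from_density(
            dens, temperature=temperature, reference_region=reference_region
        )

    def order_profile(self, bin_width: float = 0.05, z_range=None):
        return profiles.dipole_order_parameter(
            self.model.traj, self.model.geom, bin_width=bin_width, z_range=z_range
        )

    def summary(self) -> str:
        per_ns, per_s = self.turnover
        lines = [
            "Channel water transport (per monomer)",
            _rule(),
            f"events (complete)   {len(self.events)}",
            f"duration (ns)       {self.events.duration:.4g}",
            f"turnover            {per_ns:.3g} /monomer/ns  ({per_s:.3g} /channel/s)",
            f"p_f (cm^3/s)        {self.pf:.4g} +/- {self.pf_se:.2g}",
            f"p_d (cm^3/s)        {self.pd:.4g} +/- {self.pd_se:.2g}",
            f"p_f/p_d - 1         {self.single_file_N:.3g}",
            f"occupancy           {self.occupancy:.3g}",
            f"crossing time (ns)  {self.crossing_time:.3g}",
            _rule(),
        ]
        return "\n".join(lines)
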