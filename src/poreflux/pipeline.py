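"""End-to-end orchestration: simulate -> analyze -> report.

A :class:`RunConfig` (built directly or loaded from YAML) drives one of
four modes:

* ``simulate`` -- generate a synthetic single-file trajectory and write it;
* ``analyze-trajectory`` -- run the transport estimators and profiles on a
  trajectory file;
* ``analyze-traces`` -- fit stopped-flow traces and convert to
  permeabilities (plus an Arrhenius fit when several temperatures appear);
* ``full`` -- simulate, analyze the result, and analyze a set of generated
  relaxation traces, producing one combined report.

Identical (config, seed) pairs produce byte-identical ``report.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from . import kinetics, permeation, profiles, synthetic
from .exceptions import PorefluxError, ValidationError
from .models import ArrheniusModel, ChannelTransportModel, ExponentialDecayModel
from .types import CellParams, ChannelGeometry

logger = logging.getLogger(__name__)

MODES = ("simulate", "analyze-trajectory", "analyze-traces", "full")


@dataclass
class RunConfig:
    mode: str = "full"
    seed: int = 0
    output_dir: str = "poreflux_out"
    trajectory: str | None = None  # input path for analyze-trajectory
    traces: list = field(default_factory=list)  # input paths for analyze-traces
    simulate: dict = field(default_factory=dict)  # SingleFileModelSpec overrides
    geometry: dict = field(default_factory=dict)  # ChannelGeometry overrides
    cell: dict = field(default_factory=dict)  # CellParams overrides
    estimators: dict = field(default_factory=dict)  # bin_width, fit_window, temperature
    n_exponentials: int = 1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}")
        if self.mode == "analyze-trajectory" and not self.trajectory:
            raise ValidationError("analyze-trajectory mode requires a trajectory path")
        if self.mode == "analyze-traces" and not self.traces:
            raise ValidationError("analyze-traces mode requires trace paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def build_geometry(self) -> ChannelGeometry:
        kw = dict(self.geometry)
        for key in ("z_lumen", "z_event_bounds"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        return ChannelGeometry(**kw)

    def build_cell(self) -> CellParams:
        base = CellParams.rbc_reference()
        if not self.cell:
            return base
        kw = {
            "v_over_s": base.v_over_s,
            "surface_area": base.surface_area,
            "c_out": base.c_out,
            "copy_numbers": dict(base.copy_numbers),
            "temperature": base.temperature,
        }
        kw.update(self.cell)
        return CellParams(**kw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    logger.info("stage: %s", name)


def run(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns the report dict.

    Any stage failure is re-raised as :class:`PorefluxError` naming the
    stage and the offending input.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"mode": config.mode, "seed": config.seed}
    geom = config.build_geometry()
    est = config.estimators
    traj = None

    if config.mode in ("simulate", "full"):
        _stage("simulate")
        try:
            spec = synthetic.SingleFileModelSpec(seed=config.seed, **config.simulate)
            traj = synthetic.simulate_single_file(spec)
        except Exception as exc:
            raise PorefluxError(f"stage simulate failed: {exc}") from exc
        traj_path = out / "trajectory.tsv"
        pio.write_trajectory(traj, traj_path, fmt="table")
        report["simulate"] = {
            "variant": spec.variant,
            "duration_ns": spec.duration,
            "n_frames": traj.n_frames,
            "trajectory": traj_path.name,  # relative to output_dir
        }

    if config.mode == "analyze-trajectory":
        _stage("read-trajectory")
        try:
            traj = pio.read_trajectory(config.trajectory)
        except Exception as exc:
            raise PorefluxError(
                f"stage read-trajectory failed on {config.trajectory}: {exc}"
            ) from exc
        logger.info("input %s sha256=%s", config.trajectory, _sha256(config.trajectory))

    if config.mode in ("analyze-trajectory", "full"):
        _stage("analyze-trajectory")
        try:
            res = ChannelTransportModel(traj, geom).fit(
                fit_window=tuple(est.get("fit_window", (2, 20)))
            )
        except Exception as exc:
            raise PorefluxError(f"stage analyze-trajectory failed: {exc}") from exc
        res.events.to_csv(out / "events.tsv")
        per_ns, per_s = res.turnover
        report["trajectory"] = {
            "n_events": len(res.events),
            "turnover_per_monomer_ns": per_ns,
            "turnover_per_channel_s": per_s,
            "pf_cm3_s": res.pf,
            "pf_se": res.pf_se,
            "pd_cm3_s": res.pd,
            "pd_se": res.pd_se,
            "pf_over_pd_minus_1": res.single_file_N,
            "occupancy": res.occupancy,
            "crossing_time_ns": res.crossing_time,
        }
        try:
            bw = est.get("bin_width", 0.05)
            dens = res.density_profile(bin_width=bw, z_range=est.get("profile_range"))
            dens.to_table(out / "density.tsv")
            pmf = profiles.pmf_from_density(
                dens, temperature=est.get("temperature", 300.0)
            )
            pmf.to_table(out / "pmf.tsv")
            if traj.has_dipoles:
                res.order_profile(bin_width=bw).to_table(out / "order.tsv")
        except Exception as exc:
            raise PorefluxError(f"stage profiles failed: {exc}") from exc

    if config.mode in ("analyze-traces", "full"):
        _stage("analyze-traces")
        cell = config.build_cell()
        trace_results = []
        if config.mode == "full":
            # generated control-style traces: osmotic + exchange at the
            # reference control rates
            for cond, k in (("osmotic", 6.15), ("D2O-exchange", 42.51)):
                spec = synthetic.StoppedFlowSpec(
                    rates=(k,), amplitudes=(1.0,), noise_sd=0.01,
                    duration=max(1.0, 6.0 / k), dt=min(1e-3, 0.2 / k),
                    direction="shrink" if cond == "osmotic" else "exchange",
                    seed=config.seed + 101,
                )
                trace = synthetic.generate_stoppedflow_trace(spec)
                trace_results.append((cond, trace))
        else:
            for path in config.traces:
                try:
                    trace = pio.read_trace(path)
                except Exception as exc:
                    raise PorefluxError(
                        f"stage analyze-traces failed on {path}: {exc}"
                    ) from exc
                logger.info("input %s sha256=%s", path, _sha256(path))
                trace_results.append((trace.condition, trace))
        fits = []
        for cond, trace in trace_results:
            try:
                fres = ExponentialDecayModel.from_trace(trace).fit(config.n_exponentials)
            except Exception as exc:
                raise PorefluxError(
                    f"stage analyze-traces fit failed ({cond}): {exc}"
                ) from exc
            entry = {
                "condition": cond,
                "temperature_K": trace.temperature,
                "k_per_s": fres.k,
                "k_se": fres.k_se,
            }
            if cond == "osmotic":
                rec = kinetics.osmotic_Pf(fres.k, cell, k_se=fres.k_se)
                entry["Pf_cm_s"] = rec.value
            elif cond == "D2O-exchange":
                rec = kinetics.diffusional_Pd(fres.k, cell, k_se=fres.k_se)
                entry["Pd_cm_s"] = rec.value
            elif cond in ("NH3", "H+"):
                rec = kinetics.solute_permeability(
                    fres.k, cell, "NH3" if cond == "NH3" else "H"
                )
                entry["P_cm_s"] = rec.value
            fits.append(entry)
        report["traces"] = fits
        temps = sorted({(f["temperature_K"], f["k_per_s"]) for f in fits})
        if len({t for t, _ in temps}) >= 2:
            Ea, A, se = kinetics.arrhenius_Ea(temps)
            report["arrhenius"] = {"Ea_kcal_mol": Ea, "prefactor": A, "Ea_se": se}

    _stage("report")
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "summary.txt", "w") as fh:
        fh.write(render_summary(report))
    return report


def render_summary(report: dict) -> str:
    """Human-readable summary juxtaposing the computed transport numbers."""
    lines = [
        "poreflux run summary",
        "=" * 58,
        f"mode: {report['mode']}   seed: {report['seed']}",
    ]
    tr = report.get("trajectory")
    if tr:
        lines += [
            "",
            "single-channel transport (per monomer)",
            "-" * 58,
            f"  complete events     {tr['n_events']}",
            f"  turnover            {tr['turnover_per_monomer_ns']:.3g} /monomer/ns",
            f"                      {tr['turnover_per_channel_s']:.3g} /channel/s",
            f"  p_f                 {tr['pf_cm3_s']:.4g} cm^3/s",
            f"  p_d                 {tr['pd_cm3_s']:.4g} cm^3/s",
            f"  p_f/p_d - 1         {tr['pf_over_pd_minus_1']:.3g}",
            f"  occupancy           {tr['occupancy']:.3g}",
            f"  crossing time       {tr['crossing_time_ns']:.3g} ns",
        ]
    for entry in report.get("traces", []):
        lines += [
            "",
            f"stopped-flow ({entry['condition']}, {entry['temperature_K']:.2f} K)",
            "-" * 58,
            f"  k                   {entry['k_per_s']:.4g} 1/s",
        ]
        for key in ("Pf_cm_s", "Pd_cm_s", "P_cm_s"):
            if key in entry:
                lines.append(f"  {key.split('_')[0]}                  {entry[key]:.4g} cm/s")
    arr = report.get("arrhenius")
    if arr:
        lines += [
            "",
            f"Arrhenius Ea          {arr['Ea_kcal_mol']:.3g} kcal/mol",
        ]
    return "\n".join(lines) + "\n"
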