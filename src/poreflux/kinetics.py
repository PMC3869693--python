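"""Stopped-flow rate fitting and the permeability calculus.

Rate constants from mono-/bi-exponential fits convert into macroscopic
permeabilities through the cell geometry:

* osmotic:      Pf = k (V/S) / (V_W C_out)        [cm/s]
* diffusional:  Pd = k (V/S)                      [cm/s]
* solute (NH3, H+): P = k (V/S) * correction      [cm/s]

Single-channel (unit) permeabilities follow from a control/null pair:
p_unit = (P_control - P_null) * surface_area / copies, and the single-file
water count is N = p_f / p_d - 1.  Arrhenius activation energies come from
the slope of ln k against 1/T.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats

from .constants import R_KCAL_MOL_K
from .exceptions import FitError, ValidationError
from .types import (
    CellParams,
    FitResult,
    PermeabilityRecord,
    StoppedFlowTrace,
    UnitPermeabilityRecord,
)


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------

def _multi_exp(t, baseline, *params):
    y = np.full_like(t, baseline, dtype=float)
    for i in range(0, len(params), 2):
        y += params[i] * np.exp(-params[i + 1] * t)
    return y


def _initial_guess(t, y, n_exponentials):
    """Initialisation from the log-linearised tail (slow phase first)."""
    tail = max(5, len(y) // 20)
    baseline = float(np.mean(y[-tail:]))
    resid = y - baseline
    sign = 1.0 if np.trapezoid(resid, t) >= 0 else -1.0
    r = sign * resid
    pos = r > max(1e-12, 1e-6 * np.max(np.abs(r)))
    if pos.sum() >= 3:
        slope, intercept, *_ = stats.linregress(t[pos], np.log(r[pos]))
        k_slow = max(-slope, 1e-12)
        A_slow = sign * np.exp(intercept)
    else:
        k_slow = 1.0 / max(t[-1], 1e-12)
        A_slow = y[0] - baseline
    if n_exponentials == 1:
        return [baseline, A_slow, k_slow]
    # peel the slow phase and log-fit the early residual for the fast one
    early = sign * (resid - A_slow * np.exp(-k_slow * t))
    head = early[: max(5, len(y) // 4)]
    th = t[: len(head)]
    posh = head > max(1e-12, 1e-6 * np.max(np.abs(head), initial=1e-12))
    if posh.sum() >= 3:
        slope, intercept, *_ = stats.linregress(th[posh], np.log(head[posh]))
        k_fast = max(-slope, 2 * k_slow)
        A_fast = sign * np.exp(intercept)
    else:
        k_fast = 10.0 * k_slow
        A_fast = 0.5 * A_slow
    return [baseline, A_fast, k_fast, A_slow, k_slow]


def fit_exponential(trace, n_exponentials: int = 1, maxfev: int = 20000) -> FitResult:
    """Nonlinear least-squares fit of baseline + sum_i A_i exp(-k_i t).

    ``trace`` is a :class:`StoppedFlowTrace` or a (times, signal) pair.
    Initialisation comes from a log-linearised tail fit; SEs from the
    covariance of the residuals.  For ``n_exponentials = 2`` the two phases
    are flagged degenerate (warning) when the rate ratio is below 3.
    Non-convergence raises :class:`FitError`.
    """
    if isinstance(trace, StoppedFlowTrace):
        t, y = trace.times, trace.signal
    else:
        t, y = (np.asarray(a, float) for a in trace)
    if n_exponentials not in (1, 2):
        raise ValidationError("n_exponentials must be 1 or 2")
    if len(t) < 5 * n_exponentials + 1:
        raise ValidationError("too few samples for the requested fit")
    if np.ptp(y) <= 1e-12 * max(1.0, np.max(np.abs(y))):
        raise FitError("no decay detected: signal is constant")
    p0 = _initial_guess(t, y, n_exponentials)
    lower = [-np.inf] + [-np.inf, 0.0] * n_exponentials
    upper = [np.inf] + [np.inf, np.inf] * n_exponentials
    try:
        popt, pcov = optimize.curve_fit(
            _multi_exp, t, y, p0=p0, bounds=(lower, upper), maxfev=maxfev
        )
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    amps = popt[1::2]
    rates = popt[2::2]
    amp_se = perr[1::2]
    rate_se = perr[2::2]
    order = np.argsort(rates)[::-1]  # decreasing rates
    resid = y - _multi_exp(t, *popt)
    degenerate = False
    if n_exponentials == 2:
        ratio = rates[order][0] / max(rates[order][1], 1e-300)
        if ratio < 3.0:
            degenerate = True
            warnings.warn(
                "bi-exponential phases are degenerate (rate ratio < 3); "
                "individual rates are unreliable",
                stacklevel=2,
            )
    return FitResult(
        rates=rates[order],
        rate_se=rate_se[order],
        amplitudes=amps[order],
        amplitude_se=amp_se[order],
        baseline=float(popt[0]),
        baseline_se=float(perr[0]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_exponentials=n_exponentials,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# permeability conversions
# ---------------------------------------------------------------------------

def osmotic_Pf(k: float, params: CellParams, k_se: float = float("nan")) -> PermeabilityRecord:
    """Pf = k (V/S) / (V_W C_out), cm/s."""
    if k <= 0:
        raise ValidationError("rate constant must be positive")
    if params.c_out <= 0:
        raise ValidationError("C_out must be positive")
    factor = params.v_over_s / (params.V_W * params.c_out)
    return PermeabilityRecord(
        kind="Pf", value=k * factor, k=k, se=k_se * factor,
        params=params, temperature=params.temperature,
    )


def diffusional_Pd(k: float, params: CellParams, k_se: float = float("nan")) -> PermeabilityRecord:
    """Pd = k (V/S), cm/s, with V/S = r/3 for spherical ghosts."""
    if k <= 0:
        raise ValidationError("rate constant must be positive")
    return PermeabilityRecord(
        kind="Pd", value=k * params.v_over_s, k=k, se=k_se * params.v_over_s,
        params=params, temperature=params.temperature,
    )


def solute_permeability(
    k: float, params: CellParams, species: str, correction: float = 1.0,
    k_se: float = float("nan"),
) -> PermeabilityRecord:
    """P = k (V/S) * correction for NH3 or H+ gradients, cm/s.

    ``correction`` is a multiplicative factor (default 1) exposed for
    buffer-capacity effects in the proton measurement.
    """
    if k <= 0:
        raise ValidationError("rate constant must be positive")
    if species not in ("NH3", "H"):
        raise ValidationError("species must be 'NH3' or 'H'")
    val = k * params.v_over_s * correction
    return PermeabilityRecord(
        kind=f"P_{species}", value=val, k=k, se=k_se * params.v_over_s * correction,
        params=params, temperature=params.temperature,
    )


def unit_permeability(
    P_control: float,
    P_null: float,
    params: CellParams,
    channel: str,
    kind: str = "pf_unit",
) -> UnitPermeabilityRecord:
    """p_unit = (P_control - P_null) * surface_area / copies, cm^3/s.

    ``P_control`` is measured on cells expressing the channel, ``P_null``
    on the channel-deficient variant; their difference times the cell
    surface area, divided by the channel copy number, gives the
    single-channel coefficient.
    """
    if P_control < P_null:
        raise ValidationError(
            "P_control < P_null: control/null measurements are inconsistent"
        )
    if channel not in params.copy_numbers:
        raise ValidationError(f"no copy number configured for channel {channel!r}")
    copies = params.copy_numbers[channel]
    if copies <= 0:
        raise ValidationError("copy number must be positive")
    p_unit = (P_control - P_null) * params.surface_area / copies
    return UnitPermeabilityRecord(
        channel=channel, p_unit=p_unit, kind=kind,
        P_control=P_control, P_null=P_null,
        surface_area=params.surface_area, copies=copies,
    )


def single_file_N(p_f: float, p_d: float) -> float:
    """N = p_f / p_d - 1, the single-file water count (raw value).

    Report alongside ``round(N, 1)`` and ``round(N)`` as needed; both
    rounding conventions appear in practice.
    """
    if p_d <= 0:
        raise ValidationError("p_d must be positive")
    return p_f / p_d - 1.0


# ---------------------------------------------------------------------------
# Arrhenius analysis
# ---------------------------------------------------------------------------

def arrhenius_Ea(series) -> tuple:
    """(Ea kcal/mol, prefactor 1/s, Ea_se) from ln k vs 1/T least squares."""
    arr = np.asarray(list(series), float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError("series must be >= 2 (temperature, rate) pairs")
    T, k = arr[:, 0], arr[:, 1]
    if len(np.unique(T)) < 2:
        raise ValidationError("at least 2 distinct temperatures are required")
    if np.any(k <= 0) or np.any(T <= 0):
        raise ValidationError("temperatures and rates must be positive")
    res = stats.linregress(1.0 / T, np.log(k))
    Ea = -res.slope * R_KCAL_MOL_K
    se = (res.stderr if np.isfinite(res.stderr) else 0.0) * R_KCAL_MOL_K
    return float(Ea), float(np.exp(res.intercept)), float(se)


# ---------------------------------------------------------------------------
# back-solving helpers (formula self-consistency checks)
# ---------------------------------------------------------------------------

def implied_v_over_s_from_Pf(Pf: float, k: float, c_out: float, V_W: float = 18.0) -> float:
    """V/S consistent with a (Pf, k) pair under the osmotic conversion."""
    if k <= 0 or c_out <= 0:
        raise ValidationError("k and c_out must be positive")
    return Pf * V_W * c_out / k


def implied_v_over_s_from_Pd(Pd: float, k: float) -> float:
    """V/S consistent with a (Pd, k) pair under the diffusional conversion."""
    if k <= 0:
        raise ValidationError("k must be positive")
    return Pd / k


def implied_area_from_unit(p_unit: float, P_control: float, P_null: float,
                           copies: float) -> float:
    """Surface area consistent with a unit permeability and its inputs."""
    dP = P_control - P_null
    if dP <= 0 or copies <= 0:
        raise ValidationError("need P_control > P_null and positive copies")
    return p_unit * copies / dP
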