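"""Translocation counting and the two single-channel permeability estimators.

* ``p_d`` (diffusional) comes from counting complete bidirectional
  translocations Phi_c: at equilibrium the unidirectional flux is
  q0 = Phi_c / (2 T) per monomer, and p_d = v_w * q0.
* ``p_f`` (osmotic) comes from the collective-diffusion method: the
  cumulative in-pore water displacement normalised by pore length defines a
  collective coordinate n(t); its diffusion coefficient D_n (from the MSD
  slope) gives p_f = v_w * D_n.

For a single-file pore with mean occupancy N, p_f/p_d - 1 ~= N.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import NS_PER_S, VW_CM3
from .exceptions import ValidationError
from .types import (
    ChannelGeometry,
    CollectiveCoordinate,
    PermeationEventTable,
    SingleChannelPermeability,
    TrajectorySet,
)


# ---------------------------------------------------------------------------
# event counting
# ---------------------------------------------------------------------------

def detect_events(traj: TrajectorySet, geom: ChannelGeometry) -> PermeationEventTable:
    """Count complete translocations with a below/inside/above state machine.

    Per molecule, an event is recorded only for the transition sequence
    below -> inside -> above (direction +1) or above -> inside -> below
    (direction -1); re-exit to the entry side records nothing.  A gap in a
    molecule's presence (missing frames) resets its state, as does a direct
    below <-> above jump with no observed in-lumen frame.

    ``t_enter`` is the first in-lumen observation of the crossing;
    ``t_exit`` the first observation beyond the far plane.
    """
    lo, hi = geom.z_event_bounds
    if not lo < hi:
        raise ValidationError("event bounds inverted")
    rec = traj.sorted_records()
    ids = rec["id"].to_numpy()
    frames = rec["frame"].to_numpy()
    z = rec["z"].to_numpy()
    region = np.zeros(len(rec), dtype=np.int8)
    region[z < lo] = -1
    region[z > hi] = 1
    times = traj.times
    out_id, out_enter, out_exit, out_dir = [], [], [], []
    if len(rec):
        # segment boundaries: new molecule or a frame gap
        new_mol = np.r_[True, ids[1:] != ids[:-1]]
        gap = np.r_[True, frames[1:] != frames[:-1] + 1]
        seg_start = np.flatnonzero(new_mol | gap)
        seg_end = np.r_[seg_start[1:], len(rec)]
        for s, e in zip(seg_start, seg_end):
            rseg = region[s:e]
            # only region-change rows matter within a contiguous segment
            changes = np.flatnonzero(np.r_[True, rseg[1:] != rseg[:-1]])
            side = 0  # -1 below, +1 above, 0 unknown
            t_enter = np.nan
            for j in changes:
                i = s + j
                r = rseg[j]
                if r == 0:
                    if side != 0 and np.isnan(t_enter):
                        t_enter = times[frames[i]]
                else:
                    if side == -r and not np.isnan(t_enter):
                        out_id.append(ids[i])
                        out_enter.append(t_enter)
                        out_exit.append(times[frames[i]])
                        out_dir.append(int(r))
                    side = r
                    t_enter = np.nan
    events = pd.DataFrame(
        {
            "id": np.asarray(out_id, dtype=int),
            "t_enter": np.asarray(out_enter, dtype=float),
            "t_exit": np.asarray(out_exit, dtype=float),
            "direction": np.asarray(out_dir, dtype=int),
        }
    )
    return PermeationEventTable(
        events=events, duration=traj.duration, n_monomers=geom.n_monomers
    )


def turnover_rate(events: PermeationEventTable) -> tuple:
    """(events/monomer/ns, molecules/channel/s) from the event table."""
    if events.duration <= 0:
        raise ValidationError("trajectory duration must be positive")
    per_ns = len(events) / (events.duration * events.n_monomers)
    return per_ns, per_ns * NS_PER_S


def diffusional_permeability(
    events: PermeationEventTable, vw: float = VW_CM3
) -> SingleChannelPermeability:
    """p_d = v_w * q0 with q0 = Phi_c / (2 T) per monomer (cm^3/s).

    The factor 2 converts the bidirectional complete-translocation count to
    the unidirectional equilibrium flux.  The standard error propagates
    Poisson counting statistics (sqrt of the event count).
    """
    if events.duration <= 0:
        raise ValidationError("trajectory duration must be positive")
    n = len(events)
    q0 = n / (2.0 * events.duration * events.n_monomers)  # events/ns
    pd_val = vw * q0 * NS_PER_S
    pd_se = vw * np.sqrt(n) / (2.0 * events.duration * events.n_monomers) * NS_PER_S
    return SingleChannelPermeability(
        pf=float("nan"), pd=pd_val, pd_se=pd_se, q0=q0, vw=vw
    )


# ---------------------------------------------------------------------------
# collective diffusion
# ---------------------------------------------------------------------------

def collective_coordinate(
    traj: TrajectorySet, geom: ChannelGeometry
) -> CollectiveCoordinate:
    """Cumulative in-lumen displacement of all waters, normalised by L.

    Per consecutive-frame step, every molecule inside the lumen at either
    endpoint contributes its displacement clipped to the lumen span (so
    entries/exits contribute only the in-lumen portion); the per-step sum
    divided by the lumen length L accumulates into n(t), with n(0) = 0.
    """
    lo, hi = geom.z_lumen
    L = geom.lumen_length
    rec = traj.sorted_records()
    ids = rec["id"].to_numpy()
    frames = rec["frame"].to_numpy()
    z = rec["z"].to_numpy()
    incr = np.zeros(max(traj.n_frames - 1, 0))
    if len(rec) > 1:
        pair = (ids[1:] == ids[:-1]) & (frames[1:] == frames[:-1] + 1)
        z0 = z[:-1][pair]
        z1 = z[1:][pair]
        f0 = frames[:-1][pair]
        include = ((z0 >= lo) & (z0 <= hi)) | ((z1 >= lo) & (z1 <= hi))
        dz = np.clip(z1[include], lo, hi) - np.clip(z0[include], lo, hi)
        np.add.at(incr, f0[include], dz / L)
    n = np.concatenate([[0.0], np.cumsum(incr)])
    return CollectiveCoordinate(times=traj.times.copy(), n=n, L=L)


def collective_msd(cc: CollectiveCoordinate, lags: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of n(t) at the given integer lags."""
    n = cc.n
    return np.array([np.mean((n[lag:] - n[:-lag]) ** 2) for lag in lags])


def _dn_from_series(n: np.ndarray, dt: float, fit_window: tuple) -> float:
    lo_lag, hi_lag = int(fit_window[0]), int(fit_window[1])
    hi_lag = min(hi_lag, len(n) - 1)
    lags = np.unique(np.round(np.geomspace(lo_lag, hi_lag, 12)).astype(int))
    msd = np.array([np.mean((n[lag:] - n[:-lag]) ** 2) for lag in lags])
    slope, _ = np.polyfit(lags * dt, msd, 1)
    return slope / 2.0


def osmotic_permeability(
    cc: CollectiveCoordinate,
    vw: float = VW_CM3,
    fit_window: tuple = (2, 20),
    n_blocks: int = 5,
) -> SingleChannelPermeability:
    """p_f = v_w * D_n with D_n from the MSD slope of n(t) (cm^3/s).

    The MSD over log-spaced lags inside ``fit_window`` (in sampling
    intervals) is averaged over all time origins and fit linearly;
    D_n = slope / 2.  The standard error comes from block averaging over
    ``n_blocks`` contiguous blocks.
    """
    if fit_window[0] <= 0 or fit_window[1] <= fit_window[0]:
        raise ValidationError("fit window must be positive and ordered")
    if len(cc.n) < 10 * fit_window[1]:
        raise ValidationError(
            "collective coordinate must span at least 10x the fit window"
        )
    dt = float(np.median(np.diff(cc.times)))
    D_n = _dn_from_series(cc.n, dt, fit_window)
    edges = np.linspace(0, len(cc.n), n_blocks + 1).astype(int)
    block_D = []
    for b0, b1 in zip(edges[:-1], edges[1:]):
        seg = cc.n[b0:b1]
        if len(seg) > 2 * fit_window[1]:
            block_D.append(_dn_from_series(seg - seg[0], dt, fit_window))
    if len(block_D) >= 2:
        se = float(np.std(block_D, ddof=1) / np.sqrt(len(block_D)))
    else:
        se = float("nan")
    D_n = max(D_n, 0.0)
    return SingleChannelPermeability(
        pf=vw * D_n * NS_PER_S,
        pd=float("nan"),
        pf_se=vw * se * NS_PER_S,
        D_n=D_n,
        vw=vw,
    )


def permeability_from_trajectory(
    traj: TrajectorySet,
    geom: ChannelGeometry,
    vw: float = VW_CM3,
    fit_window: tuple = (2, 20),
) -> SingleChannelPermeability:
    """Convenience wrapper combining both estimators on one trajectory."""
    ev = detect_events(traj, geom)
    pdp = diffusional_permeability(ev, vw=vw)
    cc = collective_coordinate(traj, geom)
    pfp = osmotic_permeability(cc, vw=vw, fit_window=fit_window)
    return SingleChannelPermeability(
        pf=pfp.pf,
        pd=pdp.pd,
        pf_se=pfp.pf_se,
        pd_se=pdp.pd_se,
        D_n=pfp.D_n,
        q0=pdp.q0,
        vw=vw,
    )
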