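"""Axial profiles along the pore: density, PMF, dipole order parameter,
hydrogen-bond counts, occupancy and crossing-time statistics.

The potential of mean force is obtained by Boltzmann inversion of the
bulk-normalised axial density, W(z) = -kT ln n(z), with
n(z) = rho(z) / rho_bulk and rho(z) = counts / (frames * Lx(z) Ly(z) dz).
Zero-count bins are masked (NaN), never imputed, so downstream barrier
extraction cannot propagate infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import KB_KCAL_MOL_K, TIP3P_BULK_DENSITY_NM3
from .exceptions import ValidationError
from .types import (
    AxialProfile,
    ChannelGeometry,
    HBondCriterion,
    PermeationEventTable,
    TrajectorySet,
)


def _bin_edges(z_range: tuple, bin_width: float) -> np.ndarray:
    lo, hi = z_range
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    return np.linspace(lo, hi, n_bins + 1)


# ---------------------------------------------------------------------------
# density and PMF
# ---------------------------------------------------------------------------

def axial_density(
    traj: TrajectorySet,
    geom: ChannelGeometry,
    bin_width: float = 0.05,
    bulk_density: float = TIP3P_BULK_DENSITY_NM3,
    z_range: tuple | None = None,
) -> AxialProfile:
    """Bulk-normalised axial density n(z).

    rho(z) = counts / (frames * Lx(z) * Ly(z) * bin_width), normalised by
    ``bulk_density`` (the TIP3P bulk value by default, or a value measured
    from a designated bulk slab).  The per-bin sd assumes Poisson counts.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    z_range = z_range or geom.z_lumen
    if z_range[1] <= z_range[0]:
        raise ValidationError("empty z range")
    edges = _bin_edges(z_range, bin_width)
    z = traj.records["z"].to_numpy()
    counts, _ = np.histogram(z, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    area = np.asarray(geom.area(mids), float)
    if np.any(area <= 0):
        raise ValidationError("cross-section area must be positive over the lumen")
    widths = np.diff(edges)
    n_frames = max(traj.n_frames, 1)
    rho = counts / (n_frames * area * widths)
    n_z = rho / bulk_density
    sd = np.where(counts > 0, n_z / np.sqrt(np.maximum(counts, 1)), np.nan)
    return AxialProfile(bin_edges=edges, values=n_z, counts=counts, sd=sd, kind="density")


def pmf_from_density(
    profile: AxialProfile,
    temperature: float = 300.0,
    reference_region: tuple | None = None,
) -> AxialProfile:
    """W(z) = -kT ln n(z) in kcal/mol, shifted so the reference minimum is 0.

    ``reference_region`` is a (z_lo, z_hi) span (e.g. a bulk vestibule)
    whose unmasked minimum defines the zero; by default the global unmasked
    minimum is used.  Zero-count bins stay masked.
    """
    if profile.kind != "density":
        raise ValidationError("pmf_from_density expects a density profile")
    n_z = profile.values
    if np.any(n_z[np.isfinite(n_z)] < 0):
        raise ValidationError("densities must be non-negative")
    kT = KB_KCAL_MOL_K * temperature
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where((n_z > 0) & np.isfinite(n_z), -kT * np.log(n_z), np.nan)
        sd = np.where(np.isfinite(W) & (profile.sd > 0), kT * profile.sd / n_z, np.nan)
    mids = profile.centers
    if reference_region is not None:
        in_ref = (mids >= reference_region[0]) & (mids <= reference_region[1])
        ref_vals = W[in_ref & np.isfinite(W)]
        if ref_vals.size == 0:
            raise ValidationError("reference region holds no unmasked bins")
    else:
        ref_vals = W[np.isfinite(W)]
        if ref_vals.size == 0:
            raise ValidationError("profile is fully masked")
    W = W - ref_vals.min()
    return AxialProfile(
        bin_edges=profile.bin_edges, values=W, counts=profile.counts, sd=sd, kind="pmf"
    )


def barrier_height(
    pmf: AxialProfile, region: tuple, reference_region: tuple | None = None
) -> float:
    """max W over ``region`` minus min W over the reference region (kcal/mol)."""
    if pmf.kind != "pmf":
        raise ValidationError("barrier_height expects a pmf profile")
    mids = pmf.centers
    sel = (mids >= region[0]) & (mids <= region[1]) & np.isfinite(pmf.values)
    if not sel.any():
        raise ValidationError("region is fully masked")
    if reference_region is None:
        ref = np.isfinite(pmf.values)
    else:
        ref = (
            (mids >= reference_region[0])
            & (mids <= reference_region[1])
            & np.isfinite(pmf.values)
        )
        if not ref.any():
            raise ValidationError("reference region is fully masked")
    return float(pmf.values[sel].max() - pmf.values[ref].min())


# ---------------------------------------------------------------------------
# dipole order parameter
# ---------------------------------------------------------------------------

def dipole_order_parameter(
    traj: TrajectorySet,
    geom: ChannelGeometry,
    bin_width: float = 0.05,
    z_range: tuple | None = None,
) -> AxialProfile:
    """Per-bin mean and sd of cos(theta) = u . z-hat over all observations."""
    if not traj.has_dipoles:
        raise ValidationError("trajectory carries no dipole vectors")
    z_range = z_range or geom.z_lumen
    edges = _bin_edges(z_range, bin_width)
    z = traj.records["z"].to_numpy()
    uz = traj.records["uz"].to_numpy()
    idx = np.digitize(z, edges) - 1
    ok = (idx >= 0) & (idx < len(edges) - 1)
    idx, uz_ok = idx[ok], uz[ok]
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=uz_ok, minlength=len(edges) - 1)
    sq = np.bincount(idx, weights=uz_ok**2, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = sq / np.maximum(counts, 1) - mean**2
        sd = np.where(counts > 1, np.sqrt(np.maximum(var, 0.0)), np.nan)
    return AxialProfile(bin_edges=edges, values=mean, counts=counts, sd=sd, kind="order")


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class WaterFrame:
    """One frame of 3-site waters: oxygen and two hydrogen positions (nm)."""

    o: np.ndarray  # (n, 3)
    h1: np.ndarray
    h2: np.ndarray

    def __post_init__(self):
        self.o = np.atleast_2d(np.asarray(self.o, float))
        self.h1 = np.atleast_2d(np.asarray(self.h1, float))
        self.h2 = np.atleast_2d(np.asarray(self.h2, float))
        if not (self.o.shape == self.h1.shape == self.h2.shape):
            raise ValidationError("o, h1, h2 must have matching shapes")


@dataclass
class PartnerSites:
    """Non-water hydrogen-bond partners (e.g. pore-lining residues)."""

    donor_heavy: np.ndarray  # (nd, 3)
    donor_h: np.ndarray  # (nd, 3)
    acceptors: np.ndarray  # (na, 3)

    def __post_init__(self):
        self.donor_heavy = np.asarray(self.donor_heavy, float).reshape(-1, 3)
        self.donor_h = np.asarray(self.donor_h, float).reshape(-1, 3)
        self.acceptors = np.asarray(self.acceptors, float).reshape(-1, 3)
        if self.donor_heavy.shape != self.donor_h.shape:
            raise ValidationError("donor heavy-atom and H arrays must align")


def hbond_pairs(
    donor_heavy: np.ndarray,
    donor_h: np.ndarray,
    acceptors: np.ndarray,
    criterion: HBondCriterion = HBondCriterion(),
) -> np.ndarray:
    """(donor_index, acceptor_index) pairs satisfying the geometric criterion.

    Distance test: |D - A| <= max_DA_distance.  Angle test: the D-H...A
    angle deviates from linearity (180 deg) by at most max_angle.
    Coincident donor/acceptor sites (same position) are skipped.
    """
    donor_heavy = np.asarray(donor_heavy, float).reshape(-1, 3)
    donor_h = np.asarray(donor_h, float).reshape(-1, 3)
    acceptors = np.asarray(acceptors, float).reshape(-1, 3)
    if donor_heavy.size == 0 or acceptors.size == 0:
        return np.empty((0, 2), dtype=int)
    tree = cKDTree(acceptors)
    cand = tree.query_ball_point(donor_heavy, r=criterion.max_DA_distance)
    d_idx = np.array([i for i, lst in enumerate(cand) for _ in lst], dtype=int)
    a_idx = np.array([a for lst in cand for a in lst], dtype=int)
    if d_idx.size == 0:
        return np.empty((0, 2), dtype=int)
    D = donor_heavy[d_idx]
    H = donor_h[d_idx]
    A = acceptors[a_idx]
    same = np.linalg.norm(D - A, axis=1) < 1e-9
    hd = D - H
    ha = A - H
    nd = np.linalg.norm(hd, axis=1)
    na = np.linalg.norm(ha, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", hd, ha) / (nd * na)
    angle_dha = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    dev = 180.0 - angle_dha
    keep = (~same) & (dev <= criterion.max_angle) & (nd > 0) & (na > 0)
    return np.column_stack([d_idx[keep], a_idx[keep]])


def water_hbond_counts(
    waters: WaterFrame,
    partners: PartnerSites | None = None,
    criterion: HBondCriterion = HBondCriterion(),
) -> tuple:
    """Per-water H-bond counts in one frame: (water-water, water-partner).

    Each water donates through its two hydrogens and accepts on its oxygen;
    a water's count includes both donated and accepted bonds, so the
    water-water tally is symmetric by construction.
    """
    n = waters.o.shape[0]
    ww = np.zeros(n)
    wp = np.zeros(n)
    don_heavy = np.vstack([waters.o, waters.o])
    don_h = np.vstack([waters.h1, waters.h2])
    # water -> water
    pairs = hbond_pairs(don_heavy, don_h, waters.o, criterion)
    for d, a in pairs:
        w_donor = d % n
        if w_donor == a:
            continue  # a water cannot bond to itself
        ww[w_donor] += 1
        ww[a] += 1
    if partners is not None:
        # water donates to partner acceptors
        pw = hbond_pairs(don_heavy, don_h, partners.acceptors, criterion)
        for d, _a in pw:
            wp[d % n] += 1
        # partner donates to water oxygens
        pw2 = hbond_pairs(partners.donor_heavy, partners.donor_h, waters.o, criterion)
        for _d, a in pw2:
            wp[a] += 1
    return ww, wp


def hbond_profile(
    water_frames,
    geom: ChannelGeometry,
    partners: PartnerSites | None = None,
    criterion: HBondCriterion = HBondCriterion(),
    bin_width: float = 0.05,
    z_range: tuple | None = None,
) -> tuple:
    """Mean water-water and water-partner H-bond counts binned by water z.

    ``water_frames`` is an iterable of :class:`WaterFrame`.  Returns two
    :class:`AxialProfile` objects (kinds ``hbond_ww`` and ``hbond_wp``).
    """
    z_range = z_range or geom.z_lumen
    edges = _bin_edges(z_range, bin_width)
    nb = len(edges) - 1
    counts = np.zeros(nb)
    sums = {"ww": np.zeros(nb), "wp": np.zeros(nb)}
    sqs = {"ww": np.zeros(nb), "wp": np.zeros(nb)}
    for frame in water_frames:
        ww, wp = water_hbond_counts(frame, partners=partners, criterion=criterion)
        zw = frame.o[:, 2]
        idx = np.digitize(zw, edges) - 1
        ok = (idx >= 0) & (idx < nb)
        counts += np.bincount(idx[ok], minlength=nb)
        sums["ww"] += np.bincount(idx[ok], weights=ww[ok], minlength=nb)
        sums["wp"] += np.bincount(idx[ok], weights=wp[ok], minlength=nb)
        sqs["ww"] += np.bincount(idx[ok], weights=ww[ok] ** 2, minlength=nb)
        sqs["wp"] += np.bincount(idx[ok], weights=wp[ok] ** 2, minlength=nb)
    out = []
    for key in ("ww", "wp"):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, sums[key] / np.maximum(counts, 1), np.nan)
            var = sqs[key] / np.maximum(counts, 1) - mean**2
            sd = np.where(counts > 1, np.sqrt(np.maximum(var, 0.0)), np.nan)
        out.append(
            AxialProfile(
                bin_edges=edges, values=mean, counts=counts.astype(int), sd=sd,
                kind=f"hbond_{key}",
            )
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# occupancy and crossing times
# ---------------------------------------------------------------------------

def occupancy_and_crossing(
    traj: TrajectorySet,
    geom: ChannelGeometry,
    events: PermeationEventTable | None = None,
) -> tuple:
    """(mean lumen occupancy per monomer, mean crossing time in ns).

    Occupancy is the time-averaged count of waters inside ``z_lumen``
    divided by ``n_monomers``; the crossing time averages (t_exit -
    t_enter) over the event table and is NaN when there are no events.
    """
    lo, hi = geom.z_lumen
    z = traj.records["z"].to_numpy()
    inside = (z >= lo) & (z <= hi)
    occ = inside.sum() / max(traj.n_frames, 1) / geom.n_monomers
    if events is not None and len(events):
        crossing = float(
            (events.events["t_exit"] - events.events["t_enter"]).mean()
        )
    else:
        crossing = float("nan")
    return float(occ), crossing


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_profiles(profiles, path, labels=None) -> None:
    """Stack profiles into aligned axial panels and save to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profiles = list(profiles)
    fig, axes = plt.subplots(
        len(profiles), 1, sharex=True, figsize=(6, 2.2 * len(profiles)), squeeze=False
    )
    for ax, prof, label in zip(
        axes[:, 0], profiles, labels or [p.kind for p in profiles]
    ):
        ax.plot(prof.centers, prof.values, "-", lw=1.5)
        finite = np.isfinite(prof.values) & np.isfinite(prof.sd)
        ax.fill_between(
            prof.centers[finite],
            prof.values[finite] - prof.sd[finite],
            prof.values[finite] + prof.sd[finite],
            alpha=0.25,
        )
        ax.set_ylabel(label)
    axes[-1, 0].set_xlabel("z (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
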