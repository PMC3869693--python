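"""Domain containers for trajectories, geometry, profiles and kinetics records.

The coordinate convention is fixed: z is the pore axis, z = 0 at the pore
centre, positive z points towards the extracellular vestibule.  All lengths
are nm, all trajectory times are ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TRACE_TEMPERATURE_K, VW_CM3
from .exceptions import ValidationError

DIPOLE_COLUMNS = ("ux", "uy", "uz")


@dataclass
class TrajectorySet:
    """Time-ordered particle coordinates in a channel-aligned frame.

    Parameters
    ----------
    times : array of float
        Frame times in ns, strictly increasing; one entry per frame even if a
        frame holds no particles (open-boundary simulations may have empty
        frames).
    records : DataFrame
        One row per (frame, molecule) observation with columns
        ``frame, id, x, y, z`` and optionally unit dipole components
        ``ux, uy, uz``.
    box : tuple or None
        Periodic box lengths (Lx, Ly, Lz) in nm, if the coordinates are
        wrapped; ``None`` for non-periodic data.
    """

    times: np.ndarray
    records: pd.DataFrame
    box: tuple | None = None
    axis_convention: str = "z=pore axis, extracellular positive"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("frame times must be strictly increasing")
        req = ["frame", "id", "x", "y", "z"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValidationError(f"records missing columns {missing}")
        if len(self.records):
            fr = self.records["frame"].to_numpy()
            if fr.min() < 0 or fr.max() >= len(self.times):
                raise ValidationError("record frame index outside times range")
            dup = self.records.duplicated(subset=["frame", "id"])
            if dup.any():
                bad = self.records.loc[dup.idxmax()]
                raise ValidationError(
                    f"duplicate molecule id {int(bad['id'])} in frame {int(bad['frame'])}"
                )
        if self.has_dipoles and len(self.records):
            u = self.records[list(DIPOLE_COLUMNS)].to_numpy(float)
            norms = np.linalg.norm(u, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValidationError("dipole vectors must have unit norm (1e-6)")

    @property
    def has_dipoles(self) -> bool:
        return all(c in self.records.columns for c in DIPOLE_COLUMNS)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Trajectory span in ns (0 for a single frame)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def frame(self, i: int) -> pd.DataFrame:
        return self.records[self.records["frame"] == i]

    def sorted_records(self) -> pd.DataFrame:
        """Records sorted by (id, frame); cached for the analysis passes."""
        return self.records.sort_values(["id", "frame"], kind="mergesort")


@dataclass
class ChannelGeometry:
    """Axial pore boundaries and cross-section of one channel monomer.

    ``z_lumen`` is the full lumen span used for occupancy and profiles;
    ``z_event_bounds`` are the entry/exit planes of the translocation
    counter.  By default the event planes sit 0.05 nm beyond the lumen on
    each side, a small hysteresis that suppresses boundary chatter.

    ``cross_section`` is either a constant pair (Lx, Ly) in nm or a table
    of shape (n, 3) with rows (z, Lx, Ly); for cylindrical synthetic pores
    Lx = Ly = 2 r.
    """

    z_lumen: tuple = (-0.7, 0.7)
    z_event_bounds: tuple | None = None
    cross_section: object = (0.4, 0.4)
    n_monomers: int = 1
    #: default region labels following the S_0 / S_m / S_i nomenclature
    regions: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "S_0": (0.4, 0.75),
            "S_m": (-0.4, 0.4),
            "S_i": (-0.75, -0.4),
        }
    )

    def __post_init__(self) -> None:
        lo, hi = self.z_lumen
        if not lo < hi:
            raise ValidationError("z_lumen must be ordered (low, high)")
        if self.z_event_bounds is None:
            self.z_event_bounds = (lo - 0.05, hi + 0.05)
        elo, ehi = self.z_event_bounds
        if not elo < ehi:
            raise ValidationError("z_event_bounds must be ordered (low, high)")
        if self.n_monomers < 1:
            raise ValidationError("n_monomers must be >= 1")
        cs = np.asarray(self.cross_section, dtype=float)
        if cs.ndim == 1 and cs.size == 2:
            if np.any(cs <= 0):
                raise ValidationError("cross-section lengths must be positive")
        elif cs.ndim == 2 and cs.shape[1] == 3:
            if np.any(cs[:, 1:] <= 0):
                raise ValidationError("cross-section lengths must be positive")
        else:
            raise ValidationError("cross_section must be (Lx, Ly) or an (n,3) table")
        self._cs = cs

    @property
    def lumen_length(self) -> float:
        return float(self.z_lumen[1] - self.z_lumen[0])

    def cross_widths(self, z) -> tuple:
        """(Lx(z), Ly(z)) interpolated from the table, or the constants."""
        z = np.asarray(z, dtype=float)
        if self._cs.ndim == 1:
            lx = np.full_like(z, self._cs[0])
            ly = np.full_like(z, self._cs[1])
        else:
            lx = np.interp(z, self._cs[:, 0], self._cs[:, 1])
            ly = np.interp(z, self._cs[:, 0], self._cs[:, 2])
        return lx, ly

    def area(self, z):
        lx, ly = self.cross_widths(z)
        return lx * ly


@dataclass
class StoppedFlowTrace:
    """A stopped-flow relaxation time course.

    times in s, strictly increasing; signal in instrument units.  The
    condition label records what drove the relaxation (osmotic shrinkage,
    D2O exchange, NH3 or H+ gradients).
    """

    times: np.ndarray
    signal: np.ndarray
    temperature: float = DEFAULT_TRACE_TEMPERATURE_K
    condition: str = "osmotic"
    gradient: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValidationError("times and signal must have equal length")
        if self.times.size < 20:
            raise ValidationError("a trace needs at least 20 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("trace time column must be strictly increasing")


@dataclass
class PermeationEventTable:
    """Complete translocations through the pore.

    ``events`` has columns (id, t_enter, t_exit, direction) with direction
    +1 for intracellular -> extracellular crossings and -1 for the reverse.
    """

    events: pd.DataFrame
    duration: float
    n_monomers: int = 1

    def __post_init__(self) -> None:
        req = ["id", "t_enter", "t_exit", "direction"]
        missing = [c for c in req if c not in self.events.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        if len(self.events) and not np.all(
            self.events["t_exit"].to_numpy() > self.events["t_enter"].to_numpy()
        ):
            raise ValidationError("t_exit must exceed t_enter for every event")
        if self.duration < 0:
            raise ValidationError("duration must be non-negative")

    def __len__(self) -> int:
        return len(self.events)

    def to_csv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)


@dataclass
class CollectiveCoordinate:
    """Cumulative collective water displacement n(t), normalised by pore length."""

    times: np.ndarray
    n: np.ndarray
    L: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.times.shape != self.n.shape:
            raise ValidationError("times and n must match in length")
        if self.n.size and abs(self.n[0]) > 1e-12:
            raise ValidationError("collective coordinate must start at 0")
        if self.L <= 0:
            raise ValidationError("pore length must be positive")


@dataclass
class SingleChannelPermeability:
    """Per-monomer permeability coefficients from one equilibrium trajectory."""

    pf: float  # cm^3/s
    pd: float  # cm^3/s
    pf_se: float = float("nan")
    pd_se: float = float("nan")
    D_n: float = float("nan")  # 1/ns
    q0: float = float("nan")  # unidirectional events/ns per monomer
    vw: float = VW_CM3  # cm^3

    @property
    def single_file_N(self) -> float:
        return self.pf / self.pd - 1.0 if self.pd > 0 else float("nan")


@dataclass
class AxialProfile:
    """A per-bin quantity resolved along the pore axis.

    ``values`` holds NaN in masked bins (e.g. zero-count PMF bins); masked
    bins are never imputed.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    sd: np.ndarray
    kind: str = "density"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        self.sd = np.asarray(self.sd, dtype=float)
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValidationError("values must have one entry per bin")
        if len(self.counts) != len(self.values) or len(self.sd) != len(self.values):
            raise ValidationError("counts/sd must align with values")
        if np.any(np.asarray(self.counts) < 0):
            raise ValidationError("bin counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is masked (no data)."""
        return ~np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_mid": self.centers,
                "value": self.values,
                "sd": self.sd,
                "count": self.counts,
            }
        )

    def to_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    A donor D-H and acceptor A are bonded when the heavy-atom distance
    D..A <= max_DA_distance and the D-H...A angle deviates from linearity
    by at most max_angle degrees.  Defaults are the de facto standard
    0.35 nm / 30 degrees.
    """

    max_DA_distance: float = 0.35
    max_angle: float = 30.0

    def __post_init__(self) -> None:
        if self.max_DA_distance <= 0:
            raise ValidationError("max_DA_distance must be positive")
        if not 0 < self.max_angle < 90:
            raise ValidationError("max_angle must be in (0, 90) degrees")


@dataclass
class CellParams:
    """Cell/vesicle parameters entering the permeability conversions.

    v_over_s : cm
        Volume-to-surface ratio of the cell or ghost (r/3 for spheres).
    surface_area : cm^2
        Membrane area of one cell, used for unit permeabilities.
    c_out : mol/cm^3
        Total post-mixing extracellular solute concentration (osmotic runs).
    copy_numbers : mapping channel -> copies per cell.
    """

    v_over_s: float
    surface_area: float
    c_out: float
    copy_numbers: Mapping[str, float] = field(default_factory=dict)
    temperature: float = DEFAULT_TRACE_TEMPERATURE_K
    V_W: float = 18.0

    def __post_init__(self) -> None:
        for name in ("v_over_s", "surface_area", "c_out", "temperature"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.V_W != 18.0:
            raise ValidationError("V_W is the molar volume of water, fixed at 18 cm^3/mol")

    @classmethod
    def rbc_reference(cls) -> "CellParams":
        """Reference red-blood-cell parameters.

        v_over_s and surface_area are reconstructions back-solved from the
        control-cell rate/permeability pairs and the per-channel
        permeability with the measured copy number -- not independently
        measured values; override them when real geometry is known.
        c_out is the isotonic background plus the imposed 400 mosm/kg
        mannitol gradient.
        """
        return cls(
            v_over_s=6.52e-5,
            surface_area=1.0e-6,
            c_out=7.0e-4,
            copy_numbers={"UT-B": 13910.0, "AQP1": 175000.0},
        )


@dataclass
class FitResult:
    """Result of a mono- or bi-exponential relaxation fit."""

    rates: np.ndarray  # 1/s, decreasing for n=2
    rate_se: np.ndarray
    amplitudes: np.ndarray
    amplitude_se: np.ndarray
    baseline: float
    baseline_se: float
    residual_rms: float
    n_exponentials: int
    degenerate: bool = False

    @property
    def k(self) -> float:
        """The (fastest) fitted rate constant, 1/s."""
        return float(self.rates[0])


@dataclass
class PermeabilityRecord:
    """A macroscopic permeability coefficient with its provenance."""

    kind: str  # Pf | Pd | P_NH3 | P_H
    value: float  # cm/s
    k: float  # 1/s
    se: float = float("nan")
    params: CellParams | None = None
    temperature: float = DEFAULT_TRACE_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("permeability must be non-negative")


@dataclass
class UnitPermeabilityRecord:
    """Single-channel permeability derived from a control/null pair."""

    channel: str
    p_unit: float  # cm^3/s
    kind: str = "pf_unit"
    P_control: float = float("nan")
    P_null: float = float("nan")
    surface_area: float = float("nan")
    copies: float = float("nan")
    N_singlefile: float = float("nan")

    def __post_init__(self) -> None:
        if self.p_unit < 0:
            raise ValidationError("unit permeability must be non-negative")
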