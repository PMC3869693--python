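# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `poreflux`, and what the synthetic-data validations do
and do not demonstrate about real channel data.

## Coordinate and unit conventions

All trajectory quantities are internal in nm and ns; permeabilities cross
into cm-based units only at reporting boundaries (cm³/s per channel, cm/s
macroscopic). The pore axis is z, with z = 0 at the pore centre and
positive z pointing to the extracellular vestibule, so the signs of PMF
and order-parameter profiles are directly comparable between datasets.
Default region labels follow the S₀ (0.4…0.75 nm) / S_m (−0.4…0.4) /
S_i (−0.75…−0.4) convention for a 1.4 nm lumen. Constants: k_B = R =
0.0019872 kcal mol⁻¹ K⁻¹, V_W = 18 cm³/mol (fixed), v_w = V_W/N_A,
TIP3P bulk density 33.37 nm⁻³.

## Trajectory estimators

**Event counting (p_d).** A per-molecule three-state machine
(below/inside/above the event planes) records a complete translocation
only for below→inside→above or the reverse; bounces and direct
plane-to-plane jumps with no observed in-lumen frame record nothing, and
gaps in a molecule's presence reset its state. The event planes default
to the lumen extended by 0.05 nm hysteresis per side, which suppresses
boundary chatter in noisy data; for the synthetic fixtures, where
reservoir slabs begin exactly at the pore mouths, the natural choice is
the lumen bounds themselves and the tests pass them explicitly. With Φc
events over time T and m monomers, the unidirectional equilibrium flux is
q0 = Φc/(2Tm) — the factor 2 converts the bidirectional count — and
p_d = v_w·q0. The standard error propagates Poisson counting statistics
(√Φc); on hopping-model replicates its 1.96·SE interval covers the
long-run rate in ≈95% of runs.

**Collective diffusion (p_f).** Per consecutive-frame step, every
molecule inside the lumen at either endpoint contributes its displacement
clipped to the lumen span; the sum over molecules divided by the lumen
length L accumulates into the collective coordinate n(t). D_n is the
half-slope of the time-origin-averaged MSD of n over log-spaced lags in a
window of 2–20 sampling intervals (default), fitted linearly with an
intercept; the short-lag window avoids the long-lag regime where the
finite synthetic reservoirs distort the statistics (below). SEs come
from block averaging over 5 contiguous blocks. Clipping mid-step
entries/exits to the lumen span is a first-order approximation; whether
to clip at all is a convention, and the discretisation error it causes is
bounded by one step per entering/leaving molecule.

**Profiles.** Density: ρ(z) = counts/(frames·Lx(z)·Ly(z)·Δz), normalised
by the bulk density (TIP3P default, or a measured bulk-slab value);
cross-sections are supplied as a constant pair or a (z, Lx, Ly) table
because the estimator is only well-defined given them. PMF:
W(z) = −kT ln n(z), zero-count bins masked (NaN), never imputed, so
barrier extraction cannot propagate infinities; the profile is shifted so
the minimum over a caller-designated reference region (a vestibule or
bulk slab) is zero. Default bin width 0.05 nm resolves ~0.1 nm PMF
features without starving bins at the sampling used here. H-bonds use the
de facto standard geometric criterion — donor–acceptor distance ≤ 0.35 nm
and D–H⋯A deviation from linearity ≤ 30° — with a KD-tree neighbour
search that the tests pin against an exhaustive all-pairs loop. The
order parameter is the per-bin mean of cos θ = u·ẑ over all observations.

## Synthetic single-file pore

Two interchangeable dynamics generate ground-truth-known trajectories of
a ~1.4 nm single-file pore coupled to reservoirs.

**Vacancy-hopping lattice.** n sites (default 7 over 1.4 nm) with
hard-core single occupancy; per time step, Metropolis-accepted hops
between adjacent sites, grand-canonical Metropolis entries/exits at the
end sites against a reservoir of dimensionless activity
a = ρ_res/33.37, and birth/death reservoir slabs whose particle positions
are ideal-gas resampled. The stationary site occupancy is the
grand-canonical product value a·e^(−U_i/kT)/(1+a·e^(−U_i/kT)) up to weak
buffer coupling; the tests nevertheless validate occupancy and crossing
flux against a brute-force pure-python re-implementation of the identical
chain, not against that closed form. Defaults: flat in-pore potential
−0.6 kcal/mol at bulk activity, giving mean occupancy ≈ 5; hop attempt
rate 200 ns⁻¹, giving full-pore crossing times near 1 ns. At this
filling the complete-translocation rate is ~1.5/monomer/ns; rate and
crossing time cannot both be matched to a memoryless chain, and the rate
was left the free quantity.

**Brownian no-passing file.** Independent overdamped walkers in the
tabulated potential (constant potentials are ramped to zero over 0.1 nm
at the pore mouths so the Euler–Maruyama step never crosses a
discontinuity); after every step the z-order of pore-region particles is
restored, which for identical particles is statistically equivalent to
elastic hard-core collisions. Two reservoir design points matter and were
fixed using ideal-gas control runs (comparing D_n against M·D/L²):

1. slab positions are resampled uniformly every step (well-mixed), so
   re-entries from the reservoir are memoryless, as from a 3-D bulk — a
   diffusing 1-D slab is recurrent and drives n(t) subdiffusive;
2. the slab birth/death rate (default 60 ns⁻¹) must well exceed the
   channel conductance D/L, or the reservoir throttles collective current
   fluctuations at long lag.

Even so, the synthetic reservoirs are not infinite baths: D_n develops a
downward drift at lags beyond a few ns, which is why the estimator's
default fit window sits at short lags.

**What the validations show.** On the Brownian file, p_f/p_d − 1 tracks
the mean occupancy within ±16% over occupancies ≈ 3–7 (two seeds per
level), consistent with the single-file relation. On the vacancy lattice
at moderate filling the same ratio undershoots the occupancy by ~40%:
vacancy-mediated tracer motion breaks the concerted-file assumption
behind p_f/p_d = N+1, which that model only approaches in the near-full
limit. Passing these tests therefore demonstrates estimator correctness
and the single-file relation in the continuum no-passing regime; it does
not demonstrate anything about protein flexibility, hydrogen-bond
kinetics, or the absolute permeability scale of a real channel, none of
which the surrogate models contain.

A deterministic benchmark trajectory with exactly 257 complete crossings
over 200 ns and 3 monomers ships with the package
(`poreflux.benchmark_trajectory_path()`); it pins the turnover arithmetic
(0.43 events/monomer/ns ↔ 4.3×10⁸ molecules·channel⁻¹·s⁻¹) as a
regression test. Each constructed crossing spans two frames beyond each
event plane, so the count is invariant under frame subsampling by 2.

## Stopped-flow calculus

Relaxation traces are fit as baseline + Σ A_i·exp(−k_i t) by nonlinear
least squares, initialised from a log-linearised tail (and, for two
phases, peeling the slow phase from the early residual); SEs come from
the parameter covariance. Two-phase fits are flagged degenerate when the
rate ratio is below 3. A constant signal raises an explicit "no decay"
error, and non-convergence raises rather than returning defaults.

The conversion formulas are assembled from the definitions of their
symbols: P_f = k·(V/S)/(V_W·C_out); P_d = k·(V/S) with V/S = r/3 for
spherical ghosts; solute P = k·(V/S) with an exposed multiplicative
correction (default 1) for buffer-capacity effects in the proton
measurement, whose exact treatment is instrument-dependent. They are
cross-validated by back-solving V/S from the published control-cell
rate/permeability pairs: the exchange route gives V/S = 6.52×10⁻⁵ cm, the
proton row 6.1×10⁻⁵ cm, and the osmotic route agrees within 3% once
C_out is taken as the isotonic background plus the full stated 400
mosm/kg gradient (C_out = 7.0×10⁻⁴ mol/cm³, the package default); with a
half-gradient interpretation the two routes differ by ~27%, so the
default is the self-consistent reading. C_out remains an explicit config
input.

Unit permeabilities use p_unit = (P_control − P_null)·area/copies. The
default surface area (1.0×10⁻⁶ cm²) is a reconstruction back-solved from
the published UT-B unit permeability and copy number — not an
independently measured area — and is documented as such on
`CellParams.rbc_reference`; users with real geometry should override it.
The same area does **not** reproduce the published diffusional unit
permeability for UT-B (it yields 2.6 rather than 3.51 ×10⁻¹⁴ cm³/s) or
the AQP1 osmotic value; those derivations are under-determined by the
available description and the package records, rather than forces, the
discrepancy. Single-file counts are reported raw and under both rounding
conventions (one decimal and nearest integer). Arrhenius energies are
−slope·R of the least-squares line through (1/T, ln k).

## Numerical details and edge cases

- Duplicate molecule ids within a frame, non-monotone times, non-unit
  dipoles (tolerance 10⁻⁶) and ragged XYZ frames are validation errors.
- Periodic unwrapping applies per-molecule minimum-image corrections to
  consecutive-frame displacements; a presence gap restarts the molecule's
  segment, and displacements still exceeding half a box length after
  correction raise a warning.
- XYZ carries no molecule ids, so the writer refuses varying-population
  trajectories; the delimited table format (with #key=value metadata:
  dt, t0, n_frames, box) is the general carrier.
- Empty event tables give zero turnover and p_d = 0; crossing time is
  reported as missing (NaN), never zero.
- All stochastic outputs depend only on (spec, seed); identical pipeline
  configs produce byte-identical JSON reports.
- Simulation sizes in the test-suite and acceptance script (hundreds of
  ns of surrogate dynamics, 10⁵–10⁶ Boltzmann samples, 100-seed recovery
  studies) were chosen so each validation's statistical error sits well
  inside the tolerance it asserts.

## Known limitations

- The surrogate dynamics contain no protein degrees of freedom, no
  explicit hydrogens (H-bond inputs are supplied as site tables), and no
  pressure- or concentration-driven nonequilibrium flux — equilibrium
  estimators only.
- The discrete chain's p_f/p_d ratio is occupancy-consistent only near
  full filling (see above); use the Brownian variant for single-file
  ratio studies.
- The effective pore radius and continuum electrostatics of a real
  channel are out of scope; cross-sections are user inputs.
- Binary MD trajectory formats are intentionally not parsed here; convert
  to the plain XYZ/table formats (an adapter must also choose how frames
  are re-centred on a mobile protein, which is a dataset-specific
  decision).
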