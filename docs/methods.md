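# Methods

## Kinetic model of the voltage sensor

The voltage sensor is a continuous-time Markov chain on a linear chain
of N states (default five, labelled A1–A3 for resting/intermediate and
B1–B2 for activated wells). Transition j (state j ↔ j+1) obeys
Eyring-type voltage-dependent rates

    alpha_j(V) = alpha0_j * exp( x_j * zd_j * e0 * V / kT )
    beta_j(V)  = beta0_j  * exp((x_j - 1) * zd_j * e0 * V / kT )

with `alpha0`, `beta0` the rates at 0 mV (1/ms), `zd_j` the gating
charge moved across the transition (e0) and `x_j` ∈ [0, 1] the fraction
moved on the forward branch. The ratio alpha/beta is then the Boltzmann
factor exp(zd·e0·V/kT) regardless of `x`, so equilibria depend only on
the charges while `x` shapes the kinetics. kT/e0 is computed from CODATA
constants (≈25.43 mV at the default 295.15 K, i.e. 22 °C recording
temperature); nothing thermal is hard-coded.

The ensemble obeys the master equation dp/dt = pG (row-vector
convention; G has the forward/backward rates on the first off-diagonals
and zero row sums). It is solved exactly by eigendecomposition of G:
p(t) = p0 · V e^{Λt} V⁻¹. If the eigenvector matrix is numerically
defective (reciprocal condition number < 1e−10) the solver falls back to
a scaling-and-squaring matrix exponential with a warning. Protocols are
piecewise-constant voltages; occupancy is continuous across segment
boundaries and the initial condition is the stationary distribution at
the first (holding) voltage, obtained from the null space of Gᵀ. For a
nearest-neighbour chain this stationary vector equals the running
product of Boltzmann factors (detailed balance), which the tests use as
an independent oracle.

The macroscopic gating current is the rate of change of mean gating
charge,

    I_g(t) = N * e0 * sum_i z_i dp_i/dt ,    z_i = sum_{j<i} zd_j ,

reported in fC/ms with outward (ON) current positive. Inside
`simulate_protocol` the derivative is evaluated exactly as pG, not by
finite differences. Each internal voltage step is recorded on both
sides: the end-of-segment sample is time-stamped 1 ns early so the
sample at the boundary instant carries the new segment's instantaneous
current. This keeps trapezoidal ON/OFF charge integrals conservative to
<0.1% at the default 0.05 ms sampling.

The shipped `example_scheme` is an illustrative parameterization, not a
fitted ground truth: total charge 2 e0 split evenly over four
transitions, x = 0.5 throughout. The trapping variant slows entry into
the activated well (A3→B1 alpha0 = 0.02/ms) and deepens its escape
barrier (beta0 = 0.004/ms, escape time ≈250 ms at 0 mV), so Q_OFF/Q_ON
keeps falling over tens of milliseconds of depolarization and only a
small fraction of charge returns within a 20 ms OFF window — the
experimental trapping signature. The non-trapping variant uses uniform
backward rates (1.2/ms) and conserves charge.

## Sweep analytics

Charges are trapezoidal integrals of baseline-subtracted current,
reported as magnitudes so Q_OFF/Q_ON is directly the recovered-charge
fraction (the signed integral is available where linearity matters).
The OFF baseline is the mean current over the final 10% of the OFF
integration window (default 20 ms after repolarization, configurable).
For the ON baseline two estimators exist:

- `"hold"` (default): mean current over the last 10% of the pre-pulse
  holding segment. This is robust for duration families, where the
  shortest pulses (2 ms) end while the gating transient is still large —
  a within-pulse baseline there would swallow the signal itself.
- `"depol_tail"`: mean over the last 10% of the depolarization. Use
  for recordings carrying a steady residual macroscopic current during
  the pulse; requires the pulse to outlast the gating transient.

The OFF-peak amplitude is the extremum of baseline-subtracted current
within the first 5 ms after repolarization (window not standardized in
the literature; configurable).

Exponential models (`single_decay`, `single_saturating`,
`double_decay`, `double_saturating`, optional offset) are fitted by
Levenberg–Marquardt least squares (lmfit). Time constants are seeded by
a log-linear regression on the residual tail and refined over five
jittered multi-starts; the lowest-RSS converged solution wins, and
non-convergence raises an error carrying the best candidate. Double
fits are canonically reported with tau1 ≤ tau2; amplitude signs are
unconstrained (mixed growth/decay components occur in real trapping
time courses). The double-pulse recovery curve is fitted as
Q_max·(1 − e^(−t/τ)); the saturating form is used deliberately — the
recovered charge grows toward an asymptote with interpulse interval.

## Equilibrium (Boltzmann) analysis

Q(V) curves are fitted with the ascending two-state Boltzmann
Q/Qmax = 1/(1 + exp(−zδF(V−V₀.₅)/RT)). Activation data ascend with
depolarization; the descending orientation (positive exponent) remains
available behind a flag for completeness. Note the scaling consequence:
refitting the same curve shape at doubled temperature doubles the fitted
zδ, since the exponent carries zδ/RT. Replicate patches (one Q(V)
protocol per patch) are pooled as per-voltage mean ± SEM before
fitting.

The activation free energy uses the standard two-state convention
ΔG = zδ·F·V₀.₅ (kcal/mol), the chemical work of moving the sensor from
resting to active at 0 mV; ΔΔG values are differences against a
reference construct. The hydrophobicity regression accepts any
residue → kcal/mol table; Kyte–Doolittle and Wimley–White interface
tables ship as documented options, neither treated as ground truth.

## Trajectory analytics

Charged groups are the side-chain moieties: carboxylate (CG, OD1, OD2)
for aspartate, guanidinium (NE, CZ, NH1, NH2) for arginine, with
unit-mass centers of mass by default. Salt-bridge occupancy is the
fraction of frames with COM distance ≤ 4 Å (the conventional contact
distance). Pair Coulomb energies are screened point-charge estimates
E = ⟨k_C·q_a·q_b/(ε_r·r)⟩ with k_C ≈ 332.06 kcal·Å/(mol·e0²) computed
from CODATA constants. The relative permittivity ε_r is a modelling
choice that changes every energy proportionally; it must be supplied
explicitly and is echoed into all reports — no default is assumed. The
thermodynamic cycle compares the fully-active → intermediate-active
transition between a variant and a reference:
ΔE = E(A_I) − E(A_F) per construct, ΔΔE = ΔE_variant − ΔE_reference.

Superposition is the SVD Kabsch solution with reflection correction;
clustering superposes all frames onto the first frame (Cα atoms when
present), then runs k-means++ on flattened coordinates — equivalent to a
pairwise-RMSD metric up to a constant factor — with a fixed random
seed; each cluster's representative is the frame nearest its mean. An
equilibration burn-in is removed with `discard_initial(fraction)`
(frame-fraction rather than absolute time, since frame intervals vary).

## Synthetic data

Generators emit exactly the dialects the analysis consumes and a
ground-truth sidecar (generator name, parameter map, seed). Noise is
multiplicative Gaussian on Q(V) points (per-patch charge scatter) and
additive Gaussian scaled to the signal peak on currents and time
courses (instrumentation noise after filtering); neither models the
amplifier. All draws derive from one integer seed through numpy
SeedSequence spawning, so datasets are bit-reproducible across
platforms, including written PDB bytes.

The toy trajectory places a mock D160 carboxylate at the origin and
each requested arginine guanidinium on its own fixed axis at a per-frame
distance following the requested process — constant mean with Gaussian
fluctuation, or a two-state (bound/unbound) Markov telegraph with
prescribed stationary bound fraction and mean dwell (default 20
frames). D160–arginine distances therefore follow the specification
exactly; arginine–arginine distances are a geometric consequence. The
rigid group templates are idealized synthetic stand-ins, not force-field
geometries. What these toys do not emulate: solvent, membrane, internal
group flexibility, correlated multi-pair dynamics and periodic-boundary
artifacts — so passing geometry tests validates the estimators, not any
force field.

## Problem sizes, tolerances, edge cases

- Simulated sweeps default to 0.05 ms sampling; conservation tests
  repolarize to the holding potential so the sensor fully relaxes
  (Q_OFF = Q_ON to <1%); the 0 mV tail (proton reversal potential) is
  used for trapping phenomenology, where full charge return is not
  expected within the OFF window.
- Solver cross-checks: spectral vs dense matrix exponential vs RK4
  (dt = 1e−4 ms) agree to <1e−7 on 100 random 5-state schemes.
- Boltzmann and exponential round-trips on noiseless data recover
  parameters to 1e−4–1e−6 relative; under realistic noise the suites
  check median errors and bias rather than single draws.
- A short time-course (11 points, 4 parameters, 1–2% noise) leaves the
  slow time constant with a Cramér–Rao scatter of order tens of percent
  per realization while the estimator remains essentially unbiased; the
  reproduction script therefore reports the median recovered value over
  51 noise realizations for time-constant quantities, and single pooled
  fits (which are precise) for Q(V) quantities.
- Degenerate inputs raise typed errors: reducible schemes, empty
  selections, collinear superposition targets, windows outside a sweep,
  zero Coulomb distances, k exceeding the frame count.

## Known limitations

Linear-chain topologies only (no branched or cyclic schemes), no
stochastic single-channel simulation, no coupling of proton conduction
to gating, no capacitive-transient or leak-subtraction emulation, no
binary trajectory formats (multi-model PDB and per-frame tables only;
an adapter can wrap MDAnalysis/mdtraj readers into `FrameSeries`), and
no periodic-boundary unwrapping (inputs are assumed whole).
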