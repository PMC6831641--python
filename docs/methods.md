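# Methods

## Scope and model

`titrshape` computes and fits 1D NMR lineshapes of a protein resonance
along a ligand titration for three binding schemes:

* **2-state** — P + L ⇌ PL, parameters K_D (µM) and k_off (s⁻¹);
* **3-state** — P + L ⇌ PL ⇌ P′L, adding the isomerization constant
  K_eq = [PL]/[P′L] and reverse rate k_rev; the forward rate is derived,
  k_fwd = k_rev/K_eq, so detailed balance holds by construction;
* **4-state** — a two-site cycle P ⇌ {PL, LP} ⇌ LPL with three
  independent dissociation constants (K_D^A1, K_D^B1, K_D^A2) and four
  off rates; cycle closure fixes K_D^B2 = K_D^B1·K_D^A2/K_D^A1, and every
  on rate is k_on = k_off/K_D (units µM⁻¹s⁻¹).

Assumptions: the system is at chemical equilibrium at every titration
point; only protein species carry observed spin (free ligand is
invisible); exchange is describable by pseudo-first-order rates with the
free-ligand concentration absorbed into k_on·[L]; relaxation is a single
R2 per species (no scalar couplings, no relaxation dispersion, no 2D
lineshapes).

## Equilibrium solvers

Free ligand [L] at a titration point (Ptotal, Ltotal) is the physical
root of the mass-balance polynomial: a quadratic for the 2- and 3-state
schemes (the "+√" branch is the only non-negative root; evaluated in the
cancellation-safe form −2c/(b+√(b²−4c)) when b > 0), and a cubic for the
4-state scheme. The cubic is solved by polynomial root finding with the
unique real root in [0, Ltotal] accepted only if it reproduces the ligand
balance to 1e-8; otherwise the solver falls back to Brent's method on the
ligand mass-balance residual, which is strictly increasing on that
interval. Species concentrations then follow in closed form, and both
mass balances hold to ≲1e-13 relative (verified against an independent
binding-polynomial + bisection oracle over thousands of random parameter
draws).

Degenerate inputs: Ltotal = 0 and/or all rates 0 are legal (static
spectra); Ptotal ≤ 0 is rejected because the protein is the observed
species.

## Lineshape calculation

The spectrum at frequency ω is Σ Re(S) with (M(ω) − K)·S = P, where M is
diagonal with M_ii = R2_i + i(ω − ω0_i), K is the exchange matrix (zero
column sums; stationary on the equilibrium species vector), and P holds
the relative populations normalized to Σp_i = 1 (normalization only
rescales absolute intensity, which the fit's per-resonance scale factor
absorbs anyway). The linear system is solved per grid point (batched LAPACK
solve) rather than via an explicit inverse, which stays stable in the
near-singular slow-exchange limit. For one species this reduces exactly
to the absorption Lorentzian p·R2/(R2² + (ω − ω0)²), whose full width at
half maximum is 2·R2.

**Frequency convention.** All user-facing frequencies, linewidths, and
rates are angular quantities in s⁻¹, with *no* 2π factor in M: this keeps
exchange rates directly comparable to chemical-shift separations Δω in
the same unit, which is how all default parameter sets are expressed.
Data whose axis is in Hz can be handled with `freq_units="hz"`, which
inserts the 2π conversion.

**Default grid.** 1000 evenly spaced points spanning the resonance
positions padded by twice the largest linewidth on each side. A much
wider window (several multiples of the resonance span) was considered and
rejected: with 50 sampled points per line it leaves only ~2 samples per
linewidth on the peaks, destroying the information the fit needs, while
the chosen window matches how such spectra are actually plotted and
recorded. Area-conservation checks use explicit wide grids instead.

## Synthetic data generator

`simulate_titration` + `sample_and_noise` emulate a titration experiment:
spectra at each total-ligand concentration, reduced to n evenly spaced
points per line with additive zero-mean Gaussian noise of
σ = (series-wide maximum intensity)/SNR — one signal-to-noise figure per
dataset, as experimentalists quote it. Defaults (in `fixtures.py`): 300 µM
protein, ligand to 3 equivalents, K_D = 10 µM, 100 s⁻¹ linewidths,
resonances spread over 0–1000 s⁻¹, 50 points per line, SNR 50, rates
spanning 0.01×–100× Δω = 500 s⁻¹. Everything is deterministic under a
fixed seed.

What the generator does **not** emulate: baseline roll and phase errors,
t1-noise/ridges from 2D slices, temperature or concentration errors
between titration points, peak overlap from unrelated resonances, and
non-Gaussian noise. Passing recovery tests on these data therefore
demonstrates correctness of the solver/fitting machinery under the stated
noise model, not robustness to every artifact of real spectra (the a_i,
b_i corrections absorb smooth scale/baseline errors, which covers the
most common of them).

## Fitting pipeline

1. **Normalization** — each resonance's intensities are divided by the
   maximum over that resonance's series (per-series, not per-spectrum, so
   relative intensity changes across the titration are preserved).
2. **Spin pre-fit** — the first titration point must be apo; since it is
   exchange-free its Lorentzian fit pins ω0 and R2 of free P exactly, and
   these stay fixed. Bound-state spin parameters are *searched* during
   fitting, initialized from peaks picked in the last titration point
   (assigned in ascending frequency to the bound species in scheme
   order). Fixing them from the last point instead would bias K_D
   whenever exchange is not slow, because that peak is population-shifted.
   If the pre-fit fails (flat spectra), all spin parameters are left free
   with a warning. Known spin parameters can be supplied and frozen via
   `FitConfig(spins=..., fix_spins=True)`.
3. **Outer search** — bounded least squares (scipy trust-region
   reflective) on the residuals of the target function
   Σ_{i,j,k}([S_pred·a_i + b_i] − S_expt)². Thermodynamic/kinetic
   parameters and R2 values are searched as log10 (they span decades);
   resonance positions linearly within the data window. The a_i, b_i per
   resonance are never outer parameters: they solve 2×2 normal equations
   in closed form at each evaluation, which also makes the objective
   exactly invariant to affine rescaling of the data. Multistart (default
   5 starts, log-uniform over the bounds for the kinetic block) guards
   against local minima; the run is deterministic given the config seed.
   Non-finite model evaluations return penalty residuals.
4. **Global fits** — all resonances/datasets passed together share one
   kinetic/thermodynamic parameter set; each resonance keeps its own spin
   parameters and (a_i, b_i).

**Parameter tying (4-state).** `tie_sites="independent"` shares K_D and
k_off between first and second binding at the same site (two independent
sites); `"independent_equal_kd"` additionally ties the two sites' K_D —
the configuration used in the standard recovery experiments, matching
their single-K_D design. The general 7-parameter cycle is
`tie_sites="none"`.

## Monte Carlo confidence intervals and flags

Each repetition adds fresh Gaussian noise (σ from the configured noise
level or SNR, else a robust MAD estimate from the outer 10% of each
spectrum's points) to the data and refits from the best-fit point
(refitting from scratch is available but ~n_starts× slower and in
practice lands at the same optimum on these problems). The 95% CI is the
2.5th–97.5th percentile band of the resampled estimates. At least 50
repetitions run; the run stops when both endpoints of every parameter
drift by <5% over the most recent third of the run (cap 500). The lag
scales with run length deliberately: a short fixed lag declares
convergence while the tail percentiles are still creeping outward, which
measurably narrows the intervals (CI coverage of the generating value
dropped from ~94% to ~88% in 50-dataset experiments). With σ = 0 the
resampling is degenerate and the interval collapses to the point
estimate. More than 20% failed refits aborts with advice to widen bounds.

**Flags.** A parameter is reported undetermined at a bound (UB/LB) when
(a) its estimate sits within 1% of the log-scale search range of the
bound, (b) more than half the Monte Carlo repetitions pin it there, or
(c) the 95% interval endpoint itself reaches the bound — case (c) matters
above the fast-exchange limit, where the objective is nearly flat in
k_off and the estimate can land anywhere in the insensitive region while
the interval is censored at the upper bound. SV flags a Monte Carlo
coefficient of variation below 1e-3 away from any bound (interval too
narrow to be meaningful). Flagged parameters have their interval
suppressed in reports.

## Numerical choices and degenerate cases

* Quadratic/cubic root selection: physical admissibility (non-negative,
  ≤ Ltotal) decides; the cubic's in-range-real-root rule with bisection
  fallback covers near-degenerate coefficients at extreme K_D ratios.
* Lorentzian pre-fit initial values come from the peak maximum and
  half-height width; flat or near-flat spectra raise a fit failure rather
  than returning nonsense.
* Optimizer tolerances 1e-12 (1e-10 inside Monte Carlo repetitions, with
  a reduced evaluation cap, for speed).
* The MC noise σ for synthetic benchmark fits uses the known generating
  SNR; for real data without a stated noise level the baseline MAD
  estimate is used.

## Problem sizes in the shipped experiments

The recovery experiments in the test suite and `scripts/acceptance.py`
use the generator defaults above (6–10 titration points × 50 points per
line, one resonance). The Monte Carlo coverage experiment uses 50
independent datasets with known spin parameters (so the coverage
statement isolates the kinetic-parameter intervals), and the multi-state
replication fits the slow/slow condition of each scheme — the hardest
case for K_D bias — with its matched and its deliberately wrong 2-state
model; the 2-state fit of slow 3-state data restricts the window to the
P/PL region, the standard procedure when a resonance of the fuller scheme
is ignored. Property suites draw 500–1000 random parameter sets per
scheme. These sizes are the package's benchmark definition and complete
in about a minute each on a single CPU.

## Known limitations

* No gradient-exact derivatives of the Bloch–McConnell solve; the outer
  search uses finite differences.
* No Bayesian posterior or model-selection statistics (AIC/BIC): models
  are compared by refitting, as in standard lineshape practice.
* Peak-pick initialization assumes bound-species resonance positions
  increase in scheme order when several bound peaks are present; supply
  explicit spin parameters when this does not hold.
* Competitive multi-ligand schemes, cooperativity beyond the 4-state
  cycle, and temperature dependence are out of scope.
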