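# Methods

## The kinetic model

Pnao's catalytic cycle is represented as a network of irreversible
mass-action steps over enzyme flavin states. Four experiment schemes are
built from one parameter set:

* **reductive**: `E_ox → E_red·P → E_red + P`. Substrate binding is lumped
  by rapid equilibrium — the first step carries the effective first-order
  rate k_red·[S]/(K_d+[S]), because the experiments determine only an
  apparent K_d and a hyperbolic k_obs, not k_on/k_off. An optional
  explicit-binding mode (k_on = 10⁷ M⁻¹s⁻¹, k_off = k_on·K_d) exists for
  sensitivity checks; its slow eigenvalues agree with the lumped scheme to
  a few percent at the default concentrations.
* **oxidation_o2**: `E_red + O₂ → E_ox`, a single bimolecular step. The
  semiquinone is treated as unreactive toward O₂, consistent with the
  air-stability of the one-electron-reduced enzyme.
* **oxidation_cycn**: two sequential one-electron transfers
  `E_red → E_sq → E_ox`, each rate-limited by bimolecular encounter with
  oxidized CycN (the cytochrome is an obligate one-electron acceptor).
* **full_cycle**: reductive plus CycN oxidation, closing the cycle. The
  topology places product release *before* CycN oxidation (the free reduced
  enzyme reacts with CycN); whether the product-bound reduced enzyme can
  also be oxidized is experimentally open, and the alternative is not
  modeled. Reverse reactions are omitted throughout: within the observed
  windows every step is far from equilibrium.

Species held in large excess (substrate, O₂, CycN in pseudo-first-order
experiments) are clamped at their initial concentration. A clamped network
is linear in the enzyme states, so any noiseless projected trace is exactly
a sum of exponentials whose rates are the nonzero eigenvalues of the rate
matrix. `scheme.eigenrates` exposes this as the analytic oracle; the test
suite requires fitted k_obs of noiseless traces to match it to 10⁻⁴
relative.

Integration uses `scipy.integrate.solve_ivp` (LSODA, stiff-capable) with
rtol 10⁻⁸ and atol 10⁻¹² mol/L; enzyme-state and cytochrome mass
conservation hold to 10⁻⁶ relative on every trajectory, and the integrator
is cross-checked against the matrix-exponential solution of linear schemes
to 10⁻⁶. Internal units are SI (mol/L, s, K; potentials in mV). Interfaces
label all concentrations *after* 1:1 stopped-flow mixing.

## Observables

Absorbance is the Beer–Lambert projection A(t) = L·Σ εᵢcᵢ(t). Published
coefficients: Δε₅₅₀(CycN_red−CycN_ox) = 21,000 M⁻¹cm⁻¹ and
ε₄₁₀(CycN_ox) = 101,600 M⁻¹cm⁻¹. The remaining entries are package
conventions, config-overridable:

* Flavin band, 450 nm: E_ox 11,300; E_red·P 4,605; E_red (free) 1,000;
  E_sq 4,000 M⁻¹cm⁻¹. The complex value sets the relative amplitudes of the
  two reductive phases (~61% in the first phase at 500 µM substrate,
  matching the observed "roughly two-thirds" partitioning).
* The 550 nm channel is treated as a **baseline-referenced difference
  band**: CycN_ox carries 0 and CycN_red the full 21,000. This reflects how
  such traces are actually read (zeroed on the pre-mix baseline; published
  trace overlays are explicitly baseline-adjusted) and keeps the constant
  cytochrome background from saturating the simulated detector at high
  [CycN]; only the difference coefficient enters any analysis.
* Indicator dye, 600 nm: Dye_ox 20,600; Dye_red 600 M⁻¹cm⁻¹ (the leuco
  form is nearly colorless). Bands are treated as non-overlapping.

Points whose *noiseless* absorbance exceeds 1.5 AU are flagged as
CCD-saturated; flags survive noise addition and file round-trips, and all
fits exclude flagged points by default.

## Synthetic data

The generators define the simulated study conditions:

* Concentration panels (after mixing): Pon {25, 50, 100, 150, 250, 375,
  500} µM; O₂ {75, 150, 300, 600, 1200} µM; CycN {10, 20, 40, 80, 160,
  320} µM for transients and 8 log-spaced points over 2.5–80 µM for steady
  state. Enzyme: 17.5 µM for 450 nm transients; 5 µM for the CycN
  experiment, so the whole panel satisfies the ≥2·[E] excess-oxidant
  precondition; 100 nM with 1 mM Pon for steady state.
* Instrument: 1.5 ms dead time (truncating, not shifting, the log-spaced
  grid — t = 0 is flow stop), 300 points per trace spanning to 7 times the
  slowest relaxation, Gaussian noise of 0.002 AU.
* The minor third 550 nm phase (rate 0.5 s⁻¹, 5% of the main amplitude) is
  added as an *empirical* exponential, not a mechanistic species, since its
  physical origin is unresolved (possibly damaged enzyme or an instrument
  artifact).
* The titration abstracts the xanthine-oxidase/mediator chemistry as a
  monotone electron-delivery schedule spanning 1–99% of the two couples'
  capacity over 40 steps; at each step both couples are equilibrated at a
  common solution potential (bracketed root search, 10⁻⁴ mV tolerance, so
  electron balance holds to ~10⁻¹⁰ mol/L). With noise, absorbances are
  perturbed and fractions recomputed from the noisy absorbances, as in a
  real experiment.

All randomness derives from one root seed through named integer substreams;
identical seeds give bit-identical datasets.

What the generators do **not** emulate: mixing artifacts, photobleaching,
baseline drift, spectral overlap between bands, product inhibition, and the
semiquinone formed during aerobic purification. Passing recovery tests
therefore demonstrate the self-consistency of the analysis chain under the
assumed noise model, not robustness to every pathology of real stopped-flow
archives.

## Fitting

Trace models are sums of 1–3 exponentials plus an offset. Rates are fit in
log space (positive by construction) with lmfit/Levenberg–Marquardt.
Initial guesses are self-generated: candidate rate combinations from a
12-point log grid over [0.1/t_end, 10/t_first] are ranked by the residual
of a linear amplitude projection, and up to 8 starts are polished. The
convergence flag is honest — non-convergence is reported, never silently
papered over. Phase-count selection minimizes BIC (ties toward fewer
phases); an F-test could be substituted but BIC needs no significance
threshold.

Phase→constant assignment in secondary analysis is by rank (fastest phase →
first electron transfer), restricted to *statistically significant* phases:
a phase is kept when its rate standard error is below half the rate and its
amplitude exceeds 2σ. This guards the rank assignment against two known
failure modes of multi-exponential fitting — a noise spike absorbed as a
spurious very fast phase, and a near-zero-rate baseline term. The
thresholds were chosen from fit diagnostics (genuine phases show relative
rate SE ≲ 0.2, spurious ones ≳ 1). At low [CycN] the minor phase
(0.5 s⁻¹) is genuinely degenerate with the second electron transfer
(k_cyc2·[C] < 0.5 s⁻¹ below ~16 µM), so the minor-phase constant estimate
pools only significant third phases — in practice the ≥80 µM traces — and
the per-run report falls back to an inverse-variance-weighted mean over all
slowest phases when fewer than three are resolved.

Secondary fits are unweighted least squares for the linear and hyperbolic
models (weighted variants available) and inverse-variance-weighted means
for the constant model. A hyperbolic fit whose K_d exceeds 10× the largest
concentration is flagged unidentifiable; the estimated k_red/K_d ratio
still matches the initial slope.

A known feature of the two-step CycN scheme: with rate constants differing
4.4-fold the exponential amplitude decomposition is ~35%/65%, whereas the
published description calls the two phases "similar" in amplitude. The
generator follows the mechanistic scheme; reports surface the amplitudes
rather than reconciling them.

## Potentiometry

The linearized Nernst analysis regresses ln(red/ox)_enzyme on
ln(red/ox)_dye using steps where both fractions lie in [0.1, 0.9]. Deriving
both couples' Nernst relations gives slope n_enz/n_dye and intercept
(n_enz·F/RT)(E_m,enz − E_m,dye); with the two-electron indigo disulfonate
dye at −139 mV this recovers the −111 mV enzyme midpoint exactly on
noiseless data and within 3 mV at 0.005 AU absorbance noise. (A slope-1
convention with the same intercept magnitude is sometimes printed for this
analysis; the two-couple derivation is the thermodynamically consistent
form and is what the package implements.) The dye electron count n = 2 is a
package default — indigo disulfonate is a two-electron dye. Constants:
F = 96,485 C·mol⁻¹, R = 8.314 J·mol⁻¹K⁻¹, T = 298.15 K, so RT/F = 25.69 mV.

Validity limit: an indicator dye only reports midpoints near its own. With
the [0.1, 0.9] window the joint Nernst window vanishes beyond ~±85 mV
(n = 1) or ~±56 mV (n = 2) from the dye midpoint; the round-trip property
is therefore tested over enzyme midpoints in [−165, −115] mV. The
semiquinone/hydroquinone couple is out of scope (it could not be titrated
with non-physiological reductants).

## Steady state

Initial velocities are extracted from 550 nm progress traces by a linear
fit over the window spanning the first 10% of the total amplitude
(amplitude-based, hence invariant to concentration-dependent time scales),
converted by v = (dA/dt)/(Δε₅₅₀·L·[E])/2 — two cytochromes per turnover.
The *mechanistic* dataset mode integrates the full cycle with the oxidant
clamped at its initial concentration (the standard initial-velocity
idealization) and takes the slope of the late linear region; these
velocities match the reciprocal-wait closed form
1/v = 1/k_red,eff + 1/k_rel + 1/(k_cyc1[C]) + 1/(k_cyc2[C]) to better than
2% at every panel concentration (2.43 s⁻¹ at 160 µM CycN). A depleting
substrate window at the lowest concentrations would confound the first-cycle
transient with the steady flux, which is why the clamped idealization is
used for that mode. The *empirical* mode draws from the Michaelis–Menten
law at (k_cat = 4.4 s⁻¹, K_M = 34 µM) with 5% CV multiplicative noise.

The consistency analysis computes the predicted cycle
k_cat = (1/k_red + 1/k_rel)⁻¹ = 5.806 s⁻¹ and the predicted
K_M = k_cat,pred·(1/k_cyc1 + 1/k_cyc2) ≈ 223 µM. The verdict rule
quantifies "slightly lower than, but comparable to": product-release-limited
when k_rel < 0.5·k_red and fitted k_cat ≤ 1.2·k_rel; reduction-limited in
the mirrored case; mixed otherwise; inconsistent when fitted k_cat exceeds
1.2× the predicted ceiling. The mechanistic K_M prediction (~223 µM)
disagrees with the measured 34 µM; the package reports both and never
averages them — the discrepancy is an open mechanistic question (the
measured K_M may reflect weak CycN–Pnao association not visible in the
transient experiments), and the empirical generator mode is therefore the
reference for steady-state parameter recovery.

## Problem sizes

Recovery studies use 20 instrument seeds for transients (7+5+6 traces per
seed, 300 points each) and 50 seeds for steady state; the full acceptance
computation completes in well under a minute on one CPU. These sizes put
Monte-Carlo error comfortably below the experimental standard errors being
matched (±3 s⁻¹ on k_red, ±8 µM on K_d, ±0.2 s⁻¹ on k_rel,
±40 M⁻¹s⁻¹ on k_ox^O2, ±0.2×10⁵/±0.9×10⁴ M⁻¹s⁻¹ on the CycN slopes).

## Known limitations

* No pH or temperature dependence: rate constants are tied to the 4 °C
  stopped-flow buffer, the midpoint to 25 °C; no extrapolation between the
  two is attempted.
* No global multi-trace fitting of the mechanism; each trace is fit
  independently, as in the original analysis.
* Flavin extinction coefficients and the dye band are conventions, so
  absolute 450/600 nm amplitudes are illustrative; all recovered rate
  constants are amplitude-scale-invariant.
* The CLI is a thin layer over the library; anything it does is available
  programmatically.
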