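# pnaokin

Kinetic simulation and analysis of **Pnao** (pseudooxynicotine amine
oxidase), the flavoenzyme of the *Pseudomonas putida* S16 nicotine
degradation pathway that — despite its name — behaves as a **dehydrogenase**:
it oxidizes pseudooxynicotine (Pon) by hydride transfer to FAD and passes the
two electrons, one at a time, to the cytochrome *c* protein CycN rather than
to O₂.

The package is aimed at enzyme kineticists who want to simulate, regenerate
or re-analyze the three experiment classes that establish this assignment:

1. **Stopped-flow transients** — 450 nm flavin traces for the reductive
   half-reaction and O₂ reoxidation, 550 nm cytochrome traces for oxidation
   by CycN, with log-spaced sampling, instrument dead time, Gaussian noise
   and CCD saturation above 1.5 AU.
2. **Steady-state turnover** — initial velocities of CycN reduction versus
   [CycN] at saturating Pon, with the two-cytochromes-per-turnover
   stoichiometric correction.
3. **Redox potentiometry** — a slow xanthine/xanthine-oxidase (Massey)
   titration of the enzyme couple against indigo disulfonate, analyzed by
   the linearized Nernst plot.

## The model

The catalytic cycle is modeled as irreversible mass-action steps over flavin
states:

```
E_ox  --[ k_red·S/(K_d+S) ]-->  E_red·P  --[ k_rel ]-->  E_red + P
E_red + CycN_ox  --[ k_cyc1 ]-->  E_sq  + CycN_red
E_sq  + CycN_ox  --[ k_cyc2 ]-->  E_ox  + CycN_red
E_red + O2       --[ k_ox_O2 ]->  E_ox            (slow side reaction)
```

Traces are Beer–Lambert projections of the integrated trajectories. For
pseudo-first-order conditions the network is linear and the observed rates
of any noiseless trace equal the nonzero eigenvalues of the rate matrix —
this analytic oracle underpins the test suite. The fitting chain mirrors
standard transient-kinetics practice: traces are fit to sums of 1–3
exponentials, Y(t) = Σ ΔAᵢ·exp(−k_obs,ᵢ t) + A∞, phase counts chosen by BIC;
k_obs is then regressed on concentration (linear, hyperbolic
k_obs = k_red[S]/(K_d+[S]), or constant). Steady-state data are fit to
v = k_cat[C]/(K_M+[C]); the titration is analyzed by regressing
ln(red/ox)_enzyme on ln(red/ox)_dye, with slope n_enz/n_dye and intercept
(n_enz F/RT)(E_m,enz − E_m,dye).

Shipped default parameters: k_red = 74 s⁻¹, K_d = 64 µM, k_rel = 6.3 s⁻¹,
k_ox^O2 = 600 M⁻¹s⁻¹, k_cyc1 = 1.4×10⁵ M⁻¹s⁻¹, k_cyc2 = 3.2×10⁴ M⁻¹s⁻¹,
k_cat = 4.4 s⁻¹, K_M = 34 µM, E_m(ox/sq) = −111 mV.

## Worked example

```sh
pnaokin recover --seed 1
```

simulates all four experiment classes at the default parameters and noise
(0.002 AU), runs the full fitting chain, and prints:

```
parameter recovery (seed 1)
parameter           true     recovered   rel.err
k_red                 74       74.5047     0.68%
K_d              6.4e-05   6.30753e-05     1.44%
k_rel                6.3       6.38326     1.32%
k_ox_o2              600       597.303     0.45%
k_cyc1            140000        152669     9.05%
k_cyc2             32000       32319.4     1.00%
k_art                0.5      0.523221     4.64%
k_cat                4.4       4.32753     1.65%
K_M              3.4e-05   3.15043e-05     7.34%
E_m                 -111          -111     0.00%

predicted cycle k_cat = 5.88 s^-1, predicted K_M = 220 uM
oxidant preference: k_cyc1/k_ox_o2 = 260, k_cyc2/k_ox_o2 = 54
verdict: product-release-limited
failed trace fits: 0/18
```

Every recovered value is re-estimated from freshly simulated noisy traces
(concentrations in mol/L, rates in s⁻¹ or M⁻¹s⁻¹, potentials in mV). The
single-seed CycN slopes scatter by ~10%; averaging over seeds (see below)
centers them on the generating values. The consistency block restates the
two central mechanistic conclusions: turnover is limited by release of the
imine product (k_cat ≲ k_rel ≪ k_red), and CycN out-competes O₂ as oxidant
by more than two orders of magnitude.

Other subcommands: `simulate`, `fit`, `titrate`, `nernst`, `steady-state`
(`pnaokin COMMAND --help`). All of them read/write plain CSV with JSON
sidecars, and every stochastic step is controlled by an explicit seed.

## Layout

| module | contents |
|---|---|
| `pnaokin.params` | `RateParameterSet` with the fitted constants as defaults |
| `pnaokin.scheme` | reaction schemes, ODE integration, eigenrate oracle |
| `pnaokin.observables` | extinction tables, Beer–Lambert projection, `Trace` I/O |
| `pnaokin.synthetic` | seeded generators for all experiment classes |
| `pnaokin.fitting` | multi-exponential fits, BIC phase selection, secondary fits |
| `pnaokin.potentiometry` | equilibrium electron partitioning, Nernst-plot fit |
| `pnaokin.steady_state` | velocity extraction, Michaelis–Menten fit, consistency verdict |
| `pnaokin.pipeline` / `pnaokin.cli` | orchestration and the `pnaokin` command |

See `docs/methods.md` for the modeling assumptions, numerical choices and
known limitations.
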