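# Methods

## The kinetic model

`aggkit` describes unseeded amyloid fibril formation with the standard
moment (master-equation) description of nucleated polymerisation.  Writing
`m(t)` for the free monomer concentration, `P(t)` for the fibril number
concentration and `M(t)` for the fibril mass concentration, three
microscopic processes are modelled:

    dP/dt = k_n m^{n_c}  +  k_2 m^{n_2} M / (1 + m^{n_2}/K_M)
    dM/dt = 2 k_plus m P ,      m = m0 - M ,      P(0) = M(0) = 0

* `k_n` (primary nucleation, order `n_c`): spontaneous formation of new
  aggregates from monomers.
* `k_plus` (elongation): monomer addition at both fibril ends.
* `k_2` (secondary nucleation, order `n_2`): nucleation catalysed by
  existing fibril surface.  The Michaelis-type factor `1/(1 + m^{n_2}/K_M)`
  captures saturation of the fibril surface at high monomer: for
  `K_M -> inf` (the *single-step* model) the rate is simply
  `k_2 m^{n_2} M`; for finite `K_M` (*multi-step*) it approaches the
  surface-limited rate `k_2 K_M M`.

Normalized unseeded traces constrain only the products `k_plus*k_n` and
`k_plus*k_2` (plus `K_M`); the fitting layer therefore works in those
products, and `KineticParameters` exposes the aliasing explicitly.
Reaction orders default to `n_c = n_2 = 2`, the conventional values for
amyloid-β; both are configurable but are held fixed during fitting.
Concentrations are μM throughout (`K_M` in μM^n_2); time units are
whatever the trace uses (hours for the plate generator, minutes for the
NMR-decay generator).

Two effective rates summarise a parameter set at a given `m0`:

    lambda = sqrt(2 k_plus k_n m0^{n_c})          (primary pathway)
    kappa  = sqrt(2 k_plus k_2 m0^{n_2+1} / (1 + m0^{n_2}/K_M))

## Closed-form solution and its accuracy

`mass_fraction_ode` integrates the moment equations with LSODA at
rtol = 1e-9 and is the package's numerical authority.
`mass_fraction_closed` evaluates the first-order self-consistent analytic
solution

    M(t)/m0 = 1 - [ (B+ + C+)(B- + C+ e^{kt}) /
                    ((B- + C+)(B+ + C+ e^{kt})) ]^{k_inf^2/(k k~)} e^{-k_inf t}

with `C± = ±lambda^2/(2 kappa^2)`, `k~ = sqrt(k_inf^2 + lambda^4/kappa^2)`
and `B± = (k_inf ± k~)/(2 kappa)`.  The completion rate `k_inf = 2 k_plus
P(inf)` is evaluated from the exact conversion integral

    k_inf^2 = 4 k_plus k_2 ∫_0^{m0} (m0-M)^{n_2-1} M / (1 + (m0-M)^{n_2}/K_M) dM
              + 2 lambda^2 / n_c

(analytic for `n_2 = 2`, quadrature otherwise), which reduces to the
familiar `2 kappa^2/(n_2(n_2+1)) + 2 lambda^2/n_c` without saturation and
keeps the solution anchored to the ODE when `K_M` is small.

Numerically the bracket is evaluated with `u = e^{-kappa t}` and the power
in log space, so the expression neither overflows nor loses the late-time
limit `M -> m0`.

Measured accuracy against the ODE (absolute, on `M/m0`):

| regime                                   | max deviation |
|------------------------------------------|---------------|
| `kappa/lambda ~ 1e3`, single-step        | ~0.005        |
| `kappa/lambda >= 30`, single-step        | < 0.01        |
| `kappa/lambda = 10`                      | ~0.017        |
| `kappa/lambda = 1`                       | ~0.12         |
| strong saturation (`m0^{n_2}/K_M ~ 20`)  | ~0.05         |

The analytic solution is a perturbation expansion around
secondary-dominated growth; its error grows as primary nucleation becomes
comparable (`kappa -> lambda`).  All fitting in this package operates in
the secondary-dominated regime (the synthetic designs sit at
`kappa/lambda > 100`), and `global_fit` flags any fit whose optimum lands
at `kappa < lambda` as degenerate.  The property tests assert the measured
bands above; they do not claim accuracy the formula does not have.

## Trace analysis

Half times come from a four-parameter logistic
`F(t) = base + (plateau - base)/(1 + exp(-(t - t_mid)/w))` fitted by least
squares; `tau_1/2 = t_mid` is read off the fitted curve (robust to noise),
with its standard error from the fit covariance.  Declining traces (NMR
signal decay, CD extremes) are handled by the sign of `plateau - base`; a
fitted negative width is folded into a base/plateau swap.  Multi-start
initialisation seeds `t_mid` at the raw midpoint crossing and `w` at 5%
(then 2%, 10%, 25%) of the time span.  The logistic is an *approximation*
to the true rate-law shape: on noiseless model traces the extracted half
time agrees with the exact `model_halftime` to better than 2%.

Normalization maps the fitted baseline to 0 and plateau to 1 and flips
declining traces so the signal is aggregation extent; replicate averaging
(after normalization, in that order) interpolates linearly onto the first
trace's time points restricted to the intersection of all time ranges — no
extrapolation.  The scaling exponent `gamma` is the OLS slope of
`log tau_1/2` against `log m0` (at least three distinct concentrations).

## Global fitting and model comparison

`global_fit` minimises the unweighted chi-square
`sum_traces sum_t (data - M(t)/m0)^2` on normalized traces with shared
parameters, in log10 space within bounds `kp*kn in [1e-10, 1e2]`,
`kp*k2 in [1e-4, 1e8]`, `K_M in [1e-4, 1e8]` (μM units).  A deterministic
7x7(x5) coarse grid scan ranks starting points; the best few plus
seed-jittered copies (20 starts by default) are refined with bounded
trust-region least squares, and the lowest chi-square wins.  Results are
bitwise reproducible for a given seed.  Fits touching the box bounds, or
landing outside the secondary-dominated regime, carry an `at_boundary`
flag rather than failing silently.

`compare_models` exploits the nesting (single-step = multi-step at
`K_M = inf`): the multi-step fit is additionally seeded from the
single-step optimum with `K_M` at its upper bound, so
`chi2_multi <= chi2_single` holds by construction.  The multi-step model
is preferred only when it improves chi-square by more than 5% (relative,
configurable); otherwise parsimony returns the single-step verdict.  No
information criteria are used — the comparison is deliberately plain
chi-square with a parsimony guard.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, with ground
truth written alongside, and draw all randomness from one seed.

* **ThT plate** (`generate_tht_dataset`): nine concentrations 1–9 μM, six
  replicates, 0–24 h at a 1.2-min cycle; raw signal
  `baseline + gain*m0*(M/m0) + noise` with gain 500 a.u./μM, baseline
  50 a.u. and i.i.d. Gaussian noise at 2% of each trace's amplitude.  The
  default kinetic parameters (`kp*kn = 5e-5 μM⁻²h⁻²`, `kp*k2 =
  1.5 μM⁻³h⁻²`, `K_M = 9 μM²`) sit in the partially saturated regime
  (`m0²/K_M` from 0.1 to 9 across the series), chosen by a one-time design
  scan so the half-time scaling exponent is close to −1 — the regime the
  analysis is built to diagnose.  Final intensity is linear in `m0` by
  construction (gain × converted monomer).
* **¹⁹F decay** (`generate_f19_trace`): one declining 50 μM trace, 0–600
  min in 5-min steps, 3% noise; the rate products are rescaled
  analytically (time-rescaling symmetry: all rate constants × a contracts
  time by a) so the model half time lands exactly on the 258-min design
  value.
* **CD series** (`generate_cd_series`): two-state mixtures
  `alpha(t)*coil + (1-alpha(t))*beta` with `alpha = 1 - M/m0` at 10 μM,
  121 spectra over three half times.  The basis spectra are synthetic
  Gaussian-band shapes (deep coil minimum near 197 nm, β bands near
  196/218 nm), with the β spectrum rescaled so the crossing sits exactly
  at the requested isodichroic wavelength (208 nm default).  They are
  design shapes, not digitised experimental spectra.

Not emulated: plate edge and evaporation effects, ThT photobleaching and
binding photophysics, heteroscedastic or correlated noise, NMR baseline
roll, instrument drift.  Passing the end-to-end tests therefore shows the
*analysis machinery* is correct and self-consistent under the stated noise
model; it does not certify robustness to instrument artifacts real plates
exhibit.

## Sequence module

Charge profiles count D/E/K/R and score net charge as #{K,R} − #{D,E};
histidine is neutral (appropriate near pH 7) and termini are ignored; the
residue sets are arguments for other conventions.  Percent identity uses a
global BLOSUM62 alignment with affine gaps (open 10, extend 0.5) —
identity claims are method-sensitive, so these settings are fixed and
reported.  Evolutionary distances use the Poisson correction
`d = -ln(1 - p)` on the proportion `p` of differing aligned sites
(pairwise deletion of gapped columns).  Neighbor-Joining is the classical
Saitou–Nei algorithm with the Q-criterion, deterministic lowest-index
tie-breaking and branch lengths clamped at zero; it reconstructs additive
(tree-metric) inputs exactly.  No natural spidroin NT sequences ship with
the package; tests use constructed stand-ins labelled synthetic.

## Numerical choices and degenerate inputs

* ODE integration failures raise with diagnostics, never return NaN.
* `model_halftime` brackets by horizon doubling from `1/kappa`, then uses
  Brent's method at relative tolerance 1e-6; a curve that never reaches
  one half raises.
* Logistic fits refuse traces that never cross their own midpoint, and
  refuse a fitted `t_mid` outside the observed range.
* `scaling_exponent` with exactly collinear input reports a zero standard
  error; constant half times give slope 0.
* Distance matrices are validated (symmetry, zero diagonal, finiteness)
  before NJ; saturated p-distances (`p >= 1`) raise rather than return
  infinity.

## Problem sizes

Default analyses run on 54 traces × 1201 points (plate), 121-point decay
and CD series, 20 synthetic plates for recovery statistics and 200 random
draws for the closed-form/ODE comparison; the full test suite and the
reproduction script each complete in about a minute on one core.

## Known limitations

* The closed form should not be trusted outside the secondary-dominated
  regime (see the accuracy table); fits there are flagged, not refined.
* `gamma` is monotone in `K_M` only while secondary nucleation dominates;
  at extreme saturation the primary pathway takes over and the trend
  reverses (tested over `K_M` = 0.2–1e4 μM²).
* Seeded kinetics, fragmentation, spatial effects and length-resolved
  distributions are out of scope; the moment description assumes
  well-mixed, unseeded reactions.
* Chi-square is unweighted; per-point noise weighting exists as a config
  option but no error model is estimated from data.
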