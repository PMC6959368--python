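# aggkit

Analysis toolkit for amyloid aggregation kinetics, built around the
nucleated-polymerisation rate laws used to characterise amyloid-β (Aβ40,
Aβ42) self-assembly, with a small sequence module for spidroin
N-terminal-domain (solubility-tag) comparisons.

It is written for people who run thioflavin-T (ThT) plate-reader assays,
real-time ¹⁹F-NMR decay experiments or CD aggregation series and want to go
from raw traces to mechanistic parameters: half times, the concentration
scaling exponent, and globally fitted nucleation rate constants with a
single-step vs. saturating (multi-step) secondary-nucleation verdict.

## The model

Unseeded fibril formation is described by moment equations for the fibril
number `P` and mass `M` (free monomer `m = m0 − M`):

    dP/dt = k_n m^{n_c} + k_2 m^{n_2} M / (1 + m^{n_2}/K_M)
    dM/dt = 2 k_+ m P

with primary nucleation (`k_n`, order `n_c`), elongation (`k_+`) and
secondary nucleation on the fibril surface (`k_2`, order `n_2`) that
saturates at high monomer through the Michaelis-type constant `K_M`
(`K_M → ∞` gives the single-step model).  The package provides both a
stiff-safe ODE integrator and the standard closed-form solution for
`M(t)/m0`, parameterised by the effective rates
`λ = sqrt(2 k_+ k_n m0^{n_c})` and
`κ = sqrt(2 k_+ k_2 m0^{n_2+1}/(1 + m0^{n_2}/K_M))`.

Trace analysis fits a four-parameter logistic to extract the aggregation
half time `τ½`; across a dilution series the half times follow
`τ½ ∝ [monomer]^γ`, and `γ` (the slope in a double-log plot) diagnoses the
dominant mechanism: ≈ −(n₂+1)/2 for unsaturated secondary nucleation,
≈ −1/2 when saturated, in between when partially saturated.  Global
fitting shares the rate products `k_+k_n`, `k_+k_2` (and `K_M`) across all
concentrations and compares the two models by χ².

Everything is testable end to end without instrument data: the
`synth` module generates ThT plates, ¹⁹F decays and two-state CD spectral
series (with an isodichroic point) from known ground truth.

See `docs/methods.md` for assumptions, accuracy and design choices.

## Worked example

```
$ aggkit simulate tht --seed 5 --out plate/
ThT plate written to plate (designed gamma = -0.997)

$ aggkit halftimes plate/traces.csv plate/meta.json --out halftimes.json
{
  "1.0": {"m0_uM": 1.0, "tau_half": 6.828, "tau_half_se": 0.0036, ...},
  ...
  "9.0": {"m0_uM": 9.0, "tau_half": 0.733, "tau_half_se": 0.0008, ...}
}

$ aggkit scaling halftimes.json
{
  "gamma": -1.00018,
  "gamma_se": 0.04212,
  "r_squared": 0.98774,
  "plateau_slope": 499.70,
  "plateau_intercept": 51.10,
  "plateau_r_squared": 0.9999955
}

$ aggkit fit plate/traces.csv plate/meta.json --model compare --seed 1 --out report.json
{
  "single_step": {"params": {...}, "chi2": 54.071, ...},
  "multi_step":  {"params": {"kp_kn": 5.3e-05, "kp_k2": 1.493,
                             "KM": 8.92, ...}, "chi2": 0.726, ...},
  "preferred": "multi_step"
}
```

Reading the output: the six-replicate plate at 1–9 μM yields half times
from ~6.8 h down to ~0.7 h whose double-log slope `gamma ≈ −1.0` falls
between the unsaturated (−1.5) and saturated (−0.5) limits, so secondary
nucleation is partially saturated; consistently, the global fit recovers
the generator's rate products and `K_M ≈ 9 μM²` and prefers the
multi-step model by a ~70-fold lower χ², while the final-intensity fit
returns the 500 a.u./μM fluorescence gain with an intercept at the
50 a.u. baseline.

The same machinery handles declining signals — `aggkit simulate f19`
produces a 50 μM ¹⁹F decay whose sigmoid refit returns a half time of
~258 min — and `aggkit simulate cd` writes a CD series whose spectra all
cross at the 208 nm isodichroic point.  For sequences,
`aggkit seqprops <fasta>` reports charged-residue counts and net charge,
and `aggkit njtree <aligned fasta>` builds a Neighbor-Joining tree from
Poisson-corrected distances.

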