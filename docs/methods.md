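# Methods

## Scope and data model

`lactoferm` analyses batch electrofermentation experiments run in
two-chamber cells: a cathodic working chamber holding the culture and a
proton-exchange-membrane-separated anodic chamber. One experiment
(`CellExperiment`) consists of

- concentration time series per chamber and compound (mM vs h),
- a chronoamperometric current trace with its applied-potential
  schedule (mA, V vs Ag/AgCl) — absent for non-electrochemical controls,
- end-of-cycle headspace gas readings (mmol directly, or bag fraction
  converted through the ideal-gas law),
- a cycle manifest: working volume, cycle boundaries, substrate
  additions, and sample withdrawals (time, volume, chamber),
- anolyte carboxylate concentrations at cycle ends.

Units are normalised at load time (hours, mM, mA, L; 1 d = 24 h).
Between samples, concentrations are interpolated **linearly** — no
kinetic model is imposed on unobserved times — and extrapolation beyond
the sampled span is refused. Withdrawn-sample corrections use the
concentration interpolated at the withdrawal instant by default; a
cycle-average convention is selectable (`withdrawn_moles(...,
convention="cycle_average")`) since protocols differ. A total withdrawn
volume above 5 % of the working volume triggers a warning, as
concentration series then noticeably understate cumulative production.

Concentrations below the assay's quantification limit are entered as 0;
missing gas readings are treated as zero outlet (annotated "n.d." in
reports).

## Compound registry and electron accounting

Electron equivalents use the degree-of-reduction rule γ = 4C + H − 2O on
the **neutral acid form** (C₃H₆O₃ for lactate, etc.). This reproduces
the standard per-carbon electron densities (lactate 4, acetate 4,
propionate 14/3, butyrate 5 e⁻/C) without tracking dissociation state,
which is irrelevant to redox bookkeeping. CO₂ is the zero reference; O₂
(γ = −4) is deliberately unregistered — oxygen intrusion is a loss term,
not a ledger species — and O₂ gas readings are skipped with a flag.
Molar masses are fixed at standard values (lactic 90.08, acetic 60.05,
propionic 74.08, butyric 88.11, caproic 116.16, H₂ 2.016, CO₂ 44.01
g/mol). The registry ships as a CSV and is user-extensible because
routine HPLC methods monitor C2–C6 acids and alcohols even when only a
few appear above detection.

## Balances and performance coefficients

Delivered charge is the trapezoidal integral of |current| over the
window, divided by the Faraday constant (96 485 C/mol); current
magnitude is used because cathodic current is conventionally negative.
The carbon balance is outlet C (residual substrates + products in both
chambers + withdrawn samples + CO₂) over inlet C (substrates fed,
initial plus re-additions). The electron balance adds delivered charge
to the inlet and headspace H₂ to the outlet. Balances above 100 % are
flagged rather than clipped — they indicate inconsistent inputs.

The electrofermentation coefficient η_EF divides delivered charge by the
electron content of **soluble products formed**: gases are excluded, and
so is any compound fed as substrate in that cell (a fed compound's
residual is not a fermentation product). This exclusion rule is the only
convention that reproduces all five published coefficients across cells
fed lactate+butyrate (butyrate excluded) and lactate only (butyrate
counted). Controls with zero delivered charge report η_EF = 0.

Specific energy consumption is E_C = I_avg · V_cell · t / Σ mᵢ (kWh per
kg of product acid). The average current excludes spans run at the
−1.2 V start-up potential, while the charge integral for the electron
balance includes them — the start-up electrons are real inputs even if
unrepresentative of steady operation. Note that with the published
high-substrate-cell inputs (2.18 mA, 3 V, 381.6 h, ≈1.25 g product) the
formula evaluates to ≈2.0 kWh/kg; the test suite pins the formula's
arithmetic (unit identity, homogeneity in mass), not any headline bound,
because the mass basis used for reported sub-1 figures elsewhere is not
always stated.

Report rounding: balances 1 d.p., η_EF 2 d.p., rates 2 d.p.

## Pathway decomposition

The built-in network is

| reaction | stoichiometry | e⁻ from cathode |
|---|---|---|
| fermentation | 3 lactate → 2 propionate + acetate + CO₂ | 0 |
| homoacetogenesis | 4 H₂ + 2 CO₂ → acetate | 0 |
| chain elongation | lactate + acetate → butyrate + CO₂ | 0 |
| H₂ evolution | 2 e⁻ → H₂ | 2 |

Every reaction is verified carbon-balanced and electron-balanced at
construction. Chain elongation is fixed at 1:1:1 lactate:acetate →
butyrate + CO₂: with lactate named as the electron donor and acetate as
the acceptor, this is the unique coefficient set that balances both
carbon (3+2 → 4+1) and electrons (12+8 → 20+0). HCO₃⁻ is accounted as
CO₂ throughout, since carbon ledgers do not resolve speciation.

Decomposition of measured net changes into extents is **algebraic, not a
least-squares fit**: propionate identifies fermentation, butyrate
identifies elongation, and the unexplained acetate identifies
acetogenesis. This mirrors how the attribution is actually reasoned
about at the bench, and it leaves honest residuals: a lactate deficit
beyond network demand (growth, aerobic consumption, storage polymers) is
reported as a residual without biological attribution, and an acetate
*deficit* relative to fermentation stoichiometry floors the acetogenesis
extent at zero with the shortfall flagged. Windows should cover a
production phase (non-negative product deltas); analyses that need to
exclude the chain-elongation phase can simply select an earlier window.
CO₂ recycled is 2·ξ_acet, capped at the CO₂ produced by fermentation and
elongation; any excess is reported as externally sourced and flagged.

## Rates and yields

Interval rates are literal consecutive-sample slopes (mM/d, negative
allowed); they telescope exactly to the net concentration change. The
"highest production rate" is the maximum positive interval rate within a
cycle, 0 if nothing was produced. Molar yields are whole-cycle ratios:
product formed (including product withdrawn with samples and product
found in the anolyte at cycle end, minus any amount of that compound fed
during the cycle) over lactate consumed (initial + additions − residual
− withdrawn unconsumed). On noise-free simulated data with a single
active reaction the yield equals that reaction's coefficient ratio
exactly, which the suite asserts.

## Voltammetry

Cyclic voltammograms (−1.2 to 0 V vs Ag/AgCl, 1 mV/s, four cycles) are
processed per branch (cathodic and anodic sweeps separately) on a
uniform 1 mV potential grid. Analysis defaults to the **third replicate
cycle**, by which the trace has typically stabilised. Smoothing is a
centred Savitzky–Golay fit, 25 mV window, polynomial order 2 — wide
enough to suppress instrument noise, narrow enough to resolve redox
couples separated by ~50 mV; the first derivative is central-difference
(one-sided at endpoints) and is invariant to constant current offsets.

Peak detection subtracts a per-branch linear baseline (the chord between
branch endpoints, standing in for capacitive current) and keeps local
extrema in the branch's direction with prominence ≥ threshold (default
0.01 mA). Reduction peaks come from the cathodic branch, oxidation from
the anodic. Opposite-direction peaks are paired greedily by nearest
potential within 0.10 V (default; accommodates a 50 mV couple with
margin), reporting midpoint and separation. Onset-potential shifts
compare the most positive potential at which |cathodic current| first
exceeds a threshold between begin and end scans; a positive shift means
reduced overpotential, the signature of an electroactive biofilm.

Known artefact: the linear chord is a poor baseline inside the
exponential hydrogen-evolution tail, so spurious "peaks" can appear near
the negative window edge; peaks in the HER region should be disregarded
or the baseline set to `"none"` with a custom window.

## Synthetic data generator

The simulator emulates the study conditions: 150 mL working volume,
batch cycles of 5–7 days (158.4 h default) with lactate restored to
20 mM at each cycle start, butyrate optionally fed on the first cycle,
daily 1 mL sampling (samples drawn before feeding), zero-order butyrate
migration to the anolyte at 0.35 mM/d (the abiotic-membrane rate), and
an applied-potential schedule of −1.2 V for the first 24 h then −1.0 V.

Cumulative reaction extents follow **logistic curves** (total mmol,
midpoint, steepness), pinned to 0 at cycle start and the total at cycle
end. This is a shape choice, not a rate law: three parameters per
reaction reproduce the sigmoidal product profiles of real batches
without asserting kinetics. Default totals (0.8 mmol fermentation,
0.3 mmol acetogenesis per cycle) convert 80 % of a 20 mM lactate feed
and give ~10.7 mM propionate and ~7.3 mM acetate — the concentration
scale observed in such cells. A schedule that would drive lactate
negative raises an error naming the time of infeasibility.

The current trace is built from the acetogenic electron demand
(8 mmol e⁻ per mmol of acetogenesis extent via cathodic H₂) rescaled so
that its *trapezoidal* integral — the same quadrature the balance engine
applies — equals the demand exactly, plus an optional abiotic baseline
whose charge surfaces as headspace H₂. Headspace CO₂ is the net pathway
CO₂ times the gas-capture fraction. Consequently, on noise-free runs
with full gas capture, carbon and electron balances close at 100 % to
floating tolerance, and this is asserted, not assumed.

Measurement noise is additive Gaussian on recorded concentrations
(default sd 0.5 mM), with readings below a 1.0 mM quantification floor
recorded as zero — the standard below-detection-limit convention of
HPLC-RID carboxylate assays. The floor matters statistically: naively
rectifying noise at zero would inflate true-zero product baselines by
E[max(N(0,σ),0)] ≈ 0.2 mM and bias recovered extents; zeroing
sub-detection readings keeps extent recovery unbiased, which the suite
checks over 50 seeds.

What the generator does **not** emulate: pH dynamics and their feedback
on rates (pH can be attached as annotation only), microbial community
composition, biofilm growth, oxygen intrusion chemistry, anolyte
sampling, or electrode-potential fluctuations. Passing tests on
synthetic data therefore demonstrate the *accounting* is correct under
conservation and known stoichiometry — not that real communities follow
logistic extent curves.

The CV generator writes four-cycle voltammograms on the 1 mV grid:
± capacitive offset per branch, Gaussian faradaic peaks (centre, height,
sigma, direction), an exponential HER tail below a configurable onset,
and seeded Gaussian noise.

## Numerical choices and degenerate inputs

- Charge integration: trapezoidal on the recorded grid, with window
  endpoints interpolated; empty windows are errors.
- Day = exactly 24 h; Faraday constant and R from scipy.constants.
- Simulator state stepping: 0.05 h forward grid (events — sampling,
  feeding, migration clipping at zero — resolved in order: record,
  withdraw, feed); current trace emitted at 0.1 h resolution.
- Equal cathode/anode working volumes are assumed when converting
  anolyte concentrations to moles (symmetric H-cell).
- All-negative rate series → maximum production rate 0 (not an error);
  zero lactate consumption → yield undefined (error).
- Duplicate potentials in a CV branch are averaged before resampling.
- Ties in couple pairing resolve by enumeration order after sorting by
  potential distance (stable, deterministic).
- Zero delivered charge → η_EF 0 by convention (controls); zero product
  electrons with nonzero charge → error.

## Known limitations

- The decomposition assumes propionate and butyrate each have a unique
  source reaction; communities running the acrylate and dicarboxylate
  routes simultaneously are indistinguishable here (both map to the same
  net fermentation stoichiometry), but e.g. butyrate from H₂/CO₂ would
  be mis-attributed to chain elongation.
- Balance ledgers aggregate a whole run by default; per-cycle ledgers
  are available but anolyte readings are only taken at cycle ends, so
  intra-cycle anolyte dynamics are invisible.
- The linear CV baseline is a deliberate simplification; no capacitance
  or equivalent-circuit model is fitted.
- Published-table reproduction is limited by the 0.1 mmol printing
  precision of ledger entries: re-derived percentages can differ from
  printed ones by several tenths of a point, and the golden-row tests
  propagate that input-rounding interval instead of assuming a fixed
  tolerance.
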