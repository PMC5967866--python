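# Methods

## Vesicle geometry model

The internal-volume chain assumes unilamellar, monodisperse spherical
vesicles of outer radius `r_outer` with a bilayer of thickness
`m_membrane`. Both leaflets are converted to lipid counts through a single
headgroup area `a_headgroup`: the outer leaflet at radius `r` and the
inner at `r − m` (a midplane-based alternative would shift both radii by
half the bilayer; the `r`/`r − m` convention is kept because it is the one
used in the standard worked calculation for this assay format and the
difference is below the uncertainty of the headgroup area). The aqueous
compartment has radius `r − m`.

Defaults used throughout the tests and examples describe a 100-nm
extruded vesicle preparation: `r_outer = 50 nm`, `m_membrane = 4 nm`,
`a_headgroup = 0.7 nm²`, average lipid MW `790.85 g/mol`, and a 100-µL
assay containing 0.02 mg lipid (4 µL of 5 mg/mL vesicles) with 0.5 mM
external substrate. Constants are full-precision CODATA values
(`N_A = 6.02214076 × 10²³ mol⁻¹`); the benchmark lipid count 82,866.24 is
reproduced to 0.1%, the residual being rounding of π in the hand
calculation. No size-distribution, multilamellarity or lipid-mixture
corrections are attempted; lipid mass is assumed fully incorporated into
vesicles.

## Accumulation statistic and phenotype call

Counts are converted as cpm → dpm (counting efficiency) → mCi
(2.22 × 10⁹ dpm/mCi) → mmol (specific activity). Replicates are averaged
per time point before feature extraction; the peak is the maximum averaged
amount and the plateau the mean of the trailing `plateau_n` points
(default 2 — more robust than a single end point; set 1 to use only the
final time point). SEMs are propagated into the report. The post-peak
decline seen in many uptake curves is summarized, not modelled: its
mechanism (efflux vs vesicle-integrity loss on the filter) is not
identified by this kind of experiment.

The call uses the plateau fold: `channel-like` at or below 10,
`concentrative` at or above 50, `indeterminate` between. The thresholds
separate the two regimes actually observed in such assays (~3–5-fold
equilibrative vs ~150-fold coupled) by an order of magnitude on either
side; both are configurable and always echoed in the report, and the
passive equilibrium baseline (fold = 1 for an uncharged solute with no
potential) is carried alongside. Display strings round folds to the
nearest integer below 10 and nearest ten above; all arithmetic uses full
precision.

## Kinetics and binding fits

Initial rates are least-squares slopes of amount vs time over a 5-s
default window, forced through a measured t = 0 point when present, and
normalised per mg protein per minute. The Michaelis–Menten and
log-logistic models are fitted by unweighted nonlinear least squares
(scipy `curve_fit`) in log-parameter space (log Km, log Vmax, log X50,
log hill) so positivity is structural rather than clipped.
Initialisation: Km₀ = median concentration, Vmax₀ = 1.2 × max rate,
X50₀ = geometric mean of the dose grid, hill₀ = 1. Standard errors are
asymptotic, mapped back from log space by the delta method
(SE(x) = x·SE(log x)); the error convention of published "±" values is
rarely stated, so these are labelled as asymptotic SEs and nothing more.
Non-convergence raises, never passes silently. The Hill slope can be
pinned (`fix_hill=1`) for single-site models. `kcat = Vmax · M / 60000`
is pure dimensional reduction of µmol·mg⁻¹·min⁻¹ to s⁻¹. Protein masses
come from `mw_from_sequence` (average isotopic residue masses plus one
water) or are supplied directly.

## Electrochemistry

Nernst potentials are computed on concentrations (activity coefficients
ignored, as is standard for these assay buffers) at a default 298.15 K.
Conductance is the OLS slope of the unitary I–V relation (pA/mV → pS);
the reversal potential −intercept/slope is reported even when it falls
outside the measured voltage range, with an `extrapolated_reversal` flag.

## Synthetic data

Generators emulate the statistical shape of the real assays, not their
mechanism:

* **Passive uptake** — linear ODE `dC/dt = k_eq(c_out − C) − leak·C`,
  implemented by its closed form (tests cross-check against independent
  numerical integration to 1e-8). Without coupling the mean fold can never
  exceed 1; the peak-then-decline curve shape is available only through an
  explicitly phenomenological exponentially decaying vesicle-integrity
  factor, which scales the measured amount and therefore still cannot
  produce apparent concentration above equilibrium.
* **Coupled uptake** — `C(t) = fold_limit·c_out·(1 − e^{−kt})`, the
  simplest relaxation to a thermodynamically limited steady state
  (default study condition `fold_limit = 150`).
* **Rates / isotherms** — model mean plus multiplicative Gaussian noise
  with fixed CV, truncated at zero (radiometric data show roughly constant
  relative error). Defaults: 5% CV, triplicate, 8 log-spaced
  concentrations over 0.5–50 mM for kinetics; 3% CV, 10 log-spaced doses,
  constant non-proximity background for binding.
* **Single-channel records** — two-state Markov gating per channel
  (stationary open probability, total switching rate 100 s⁻¹, 0.1-ms
  samples) with Gaussian baseline noise; the I–V stage estimates the
  unitary amplitude as mean(one-open) − mean(closed), so conductance
  recovery is independent of open probability.

Every generator takes an explicit seed through `SimConfig`; there is no
global RNG, and repeated calls are bit-reproducible. What passing tests
show: the estimators recover the generating parameters under these noise
models and the classifier separates the two regimes. What they do not
show: robustness to real-data pathologies the generators omit — vesicle
size heterogeneity, filter-binding artefacts, non-stationary baselines,
correlated replicate error.

## Problem sizes and numerical choices

Recovery studies use 100 simulated datasets per estimator and the
classification study 50 seeds per regime — enough for stable medians and
proportions while keeping the full suite and the acceptance script each
under half a minute on one core. Degenerate inputs (zero volume, inverted
thresholds, flat isotherms, singular I–V designs, non-increasing time
grids) raise typed errors rather than producing numbers. Unit conversions
are centralised in `vesiflux.units`.

## Known limitations

The geometry model is deliberately idealised (monodisperse, unilamellar,
100% lipid incorporation); fold-accumulation values inherit any bias in
V_PL linearly. kcat uses total reconstituted protein, so it is a lower
bound whenever part of the protein is inactive or inside-out. Mechanistic
inhibition modelling (competitive vs non-competitive), multi-ion GHK
permeability, and gating kinetics (dwell-time analysis) are out of scope.
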