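# Methods

This note records the models, the numerical choices and the limits of what
the synthetic-data tests demonstrate.

## Labeling kinetics

The covalent reaction between the chloroalkane-dye substrate (A) and the
reconstituted tag (B) is treated as a single irreversible bimolecular step.
For [A]₀ ≠ [B]₀ the free-substrate fraction is

[A](t)/[A]₀ = ([A]₀−[B]₀) / ([A]₀ − [B]₀ e^{−([A]₀−[B]₀) k_app t}),

and FP interpolates linearly between FP_free and FP_bound with the labeled
fraction. The expression is evaluated with the decaying-exponential form on
either side of [A]₀ = [B]₀ so it never overflows, and switches to the
analytic limit FP_bound + (FP_free−FP_bound)/(1 + [A]₀ k_app t) when
|[A]₀−[B]₀|/[A]₀ < 1e-6 (the two agree to 1e-6 relative at that boundary,
which the tests check numerically).

Fitting choices:

* Parameters (log₁₀ k_app, FP_free, FP_bound), nonlinear least squares
  (scipy `least_squares`, tolerances 1e-14). The log parameterization keeps
  the rate positive and evens out its scale; the start value comes from a
  coarse log-grid scan over 1e2–1e7 M⁻¹s⁻¹, and FP_free/FP_bound start at
  the first/last observations.
* **Dead time.** Instruments record the first point some delay after
  mixing. The delay enters as a fixed, configurable offset added to all
  times (default 30 s). It is deliberately *not* a free parameter: a free
  offset trades off against k_app on partially observed curves and is
  weakly identified.
* **Linear fallback.** When the fitted curve predicts less than 20%
  reaction completion at the last time point (or the optimizer fails), the
  trace is refit with a straight line and only the initial slope is
  reported. The threshold is inclusive (completion exactly at 20% keeps the
  second-order model). 20% keeps the fallback inside the near-linear
  regime; no published value exists for this cutoff.
* Replicates are averaged before fitting; the initial slope of a
  second-order fit is the analytic derivative k_app·[B]₀·(FP_bound −
  FP_free).

Background (peptide-free) labeling uses one-phase association
y₀ + (plateau−y₀)(1−e^{−k_obs t}); t½ = ln2/k_obs holds to 1e-12 by
construction, and traces with no measurable amplitude or k_obs at the
numerical floor are flagged rather than reported.

## EC50 dose-response

Rates versus peptide concentration follow the Hill-slope-1 binding curve.
Both published parameterizations (log-sigmoid with zero bottom, hyperbolic
with free bottom) are available and are algebraically identical when
Bottom = 0 (property-tested to 1e-12). With the Hill slope fixed, the
model is linear in (Top, Bottom) given EC50, so the fit profiles those out
analytically and minimizes a one-dimensional function of log₁₀ EC50
(bounded Brent, xatol 1e-12, bounds three decades beyond the tested
concentration range). This makes each fit fast enough that the Monte Carlo
interval (1000 refits) costs well under a second, and leaves no
multi-start failure modes. An EC50 more than tenfold outside the tested
range sets an `extrapolated` flag.

**Monte Carlo interval.** Parametric: Gaussian noise with scale equal to
the fit's residual standard deviation (or the per-point rate SD when every
point provides one) is added to the fitted curve, each synthetic dataset is
refit, the worst 5% of refits by SSE are discarded, and the 2.5th/97.5th
percentiles of the surviving EC50 estimates form the 95% interval. "Worst
fits" is interpreted as highest refit SSE — the natural fit-quality metric
— rather than most extreme EC50. The interval is a percentile interval;
simulation places its coverage at ~90–95% for the 11-point twofold design
at 2% noise, which the acceptance suite checks against a 90–99% band.

## Binding

Saturation K_d fits FP(c) = bottom + (top−bottom)·c/(K_d + c) with K_d on
the log scale, assuming tracer ≪ titrated protein so free ≈ total
concentration. Inverted isotherms (bottom ≥ top) and K_d beyond tenfold of
the titrated range are flagged.

BLI preprocessing subtracts the baseline-phase mean (idempotent) and
applies a Savitzky–Golay filter, default window 11 points / order 2 —
artifact defaults chosen to preserve the sensorgram curvature (the filter
passes polynomials up to its order unchanged) while roughly halving white
noise. The global 1:1 fit shares (log₁₀ k_on, log₁₀ k_off, R_max) across
traces with one additive offset per trace as an immobilization nuisance,
runs a small 3×3 multi-start grid over the rates, and reports
K_d = k_off/k_on. Mass transport, ligand depletion and drift are not
modeled (a linear drift term exists in the generator for robustness
checks); k_off estimates at the 1e-7 s⁻¹ lower bound are flagged as the
slow-dissociator regime, where a 300 s dissociation window carries almost
no decay information.

## Scalar assays

* Dye-corrected concentration: (A₂₈₀ − A_max·CF)/ε_protein × dilution,
  with built-in correction factors CF = 0.34 (TMR) and 0.147 (SiR);
  extinction coefficients are user-supplied. A negative corrected
  absorbance raises an error naming the inputs.
* Melting temperature: Savitzky–Golay first derivative (window 9, order 3
  — no standard method is published for this derivative, these defaults
  suppress 1%-level noise on a 76-point 1 °C grid) of the 350/330 ratio
  curve; the grid argmax is refined by a quadratic through three points.
  The estimate is invariant under affine rescaling of the ratio axis; a
  derivative maximum on the grid boundary is reported as no-transition.
* Gaussian line profiles use the area parameterization
  y = y₀ + A/(ω√(π/2)) e^{−2(x−x_c)²/ω²} with ω fitted on the log scale;
  FWHM = ω√(2 ln 2). Start values come from the observed peak and
  half-maximum crossings.
* Turn-on fold change defaults to the peak-intensity ratio (replicates
  averaged per wavelength first); an integral mode exists and agrees with
  peak mode for shape-preserving scaling.

## Enrichment counting

Amplicon reads are fixed-length windows around the randomized stretch, so
short-read alignment reduces to positional matching: a read counts when
its length equals the template's and ≥90% of non-randomized bases match;
reads failing the gate, or with an N inside a randomized codon, are
discarded with a recorded reason. Frequencies divide by *usable* reads
(both usable and total counts are reported, since "total reads" is
ambiguous as a denominator). The amber stop is kept as a 21st symbol —
NNK permits TAG — so per-position frequencies sum to 1 over 21 symbols.
Enrichment ratios use a 1e-4 pseudo-count and, being frequency ratios, are
depth-invariant.

## Synthetic data

Generators emit exactly the model curves above plus additive i.i.d.
Gaussian noise on the observable, averaged over the declared replicate
count; a single root seed fans out to per-series seeds via numpy
`SeedSequence.spawn`, making every dataset a pure function of (parameters,
seed). Default designs mirror the characterization study: 0.5 nM substrate
with 2.5 nM protein read for 10 h (5 min cadence, 30 s dead time, two
replicates), twofold peptide dilutions 1000→0.98 nM (11 points), fivefold
saturation dilutions from 10 µM, a twofold 300→2.34 nM sensorgram series
(60 s baseline, 300 s association and dissociation, 1 Hz), 20–95 °C melt
ramps at 1 °C, and 20 nm-pixel line profiles over a 600 nm window. Noise
defaults to 2% of the observable's dynamic range (5% for line profiles,
1% of amplitude for melt curves) — magnitudes chosen once as typical
plate-reader/instrument noise, since no noise model is published. FP
plateau values (50→350 mP) and melt-ratio baselines (0.85→0.95) are
likewise unpublished and set to values typical for these instruments.

What passing recovery tests shows — and does not. The generators share
their forward models with the fitters, so recovery tests demonstrate
estimator correctness, identifiability under the stated designs and noise
robustness; they cannot detect model misspecification in real data
(evaporation drifts, photobleaching, mass-transport limitation, non-Gaussian
outliers, PCR bias in sequencing). The ODE, quadrature, closed-form and
hand-count oracles in the test suite verify the forward models themselves
against independent computations.

## Problem sizes

Acceptance-style recovery runs use 100 seeded repetitions for the EC50
pipeline (11 concentrations × 121 time points each, 1000 Monte Carlo
refits per repetition) and 50 repetitions for saturation, BLI, and profile
recovery, 25 for melt curves — enough that medians are stable to well
inside the tolerances being checked.
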