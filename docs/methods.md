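# Methods

## The model

The package audits a single resource balance: can a cell's ribosome
pool resynthesize its proteome within one division time? The minimal
(loss-free) proteome duplication time is

    T0 = (P/R) · L / k

with `P` proteins per cell, `R` functional ribosomes per cell, `L` the
average protein length (472 aa) and `k` the elongation rate (residues
per second). All three factors are measured by separate assays, each of
which this package implements as an estimator together with a synthetic
generator that emulates the assay's structure.

Losses enter through a first-order balance. With productive synthesis
rate `s = (R·k/L)·f_active·(1 − f_drip)` proteins/s — `f_drip` the
fraction of nascent chains degraded shortly after synthesis (defective
ribosomal products, default 0.30), `f_active` the fraction of ribosomes
actually elongating (default 1) — and proteome turnover
`λ = ln2 / t½,proteome` (default half-life 32 h), the proteome obeys
`dP/dt = s − λP`. The corrected duplication time is the time to reach
`2·P0` from `P0`:

    Tc = (1/λ) · ln[(s/λ − P0) / (s/λ − 2·P0)]

defined only when the steady state `s/λ` exceeds `2·P0`; otherwise the
doubling is infeasible, which is reported as a state rather than raised
as an error, because infeasibility is the scientifically meaningful
outcome. As `λ → 0` the expression reduces to `P0/s`. Secretion loss is
not separately parameterized (no reliable number is available); users
can fold it into `f_drip`. Degradation uses a single proteome-wide
half-life; no fast/slow two-compartment kinetics beyond the
instantaneous `f_drip` term.

## Run-off kinetics

The RPM signal after initiation blockade is fit as a one-phase
exponential decay, `S(t) = span·e^(−λt) + plateau`, treated as
empirical (no mechanistic positional run-off model): whether the
exponential form reflects an mRNA-length mixture is left open. The
stalled-ribosome fraction is `plateau/(span + plateau)`; a companion
model-free estimator uses the ratio of late (≈15 min) to initial
signal, and is the fallback when the signal is flat (a fully stalled
population makes λ unidentifiable, so the fit refuses rather than
returning an arbitrary rate).

Numerical choices: summaries default to the median (robust under
lognormal dispersion; geometric mean by flag — the summary statistic
behind reported "MFI" values is generally not specified by
instruments' software, so both are offered). Initialization takes
`plateau0 = min(y)`, `span0 = max − min`, and `λ0` from a log-linear
regression of the plateau-subtracted signal; parameters are bounded
(`λ > 0`, `plateau ≥ 0`) and up to 5 lognormally jittered restarts run
before failure is declared. Negative background-subtracted summaries
are floored at zero by default (flag to disable). Bootstrap CIs
resample cells within each timepoint (sample and background
independently) and refit; the percentile interval is reported. Time is
seconds everywhere internally; hours appear only at report boundaries
(1 hr = 3600 s exactly).

Elongation rates are anchored by inverse proportionality to the
70 s ↔ 6 aa/s reference: `rate = 6 · 70 / t½`, so `rate · t½ = 420 aa`
is invariant. The package computes exact percentages from half-lives
and does not round to a preferred headline.

## Censuses

Protein: tryptophan fluorescence is calibrated by ordinary least
squares with a free intercept (a through-origin flag exists for
blank-subtracted workflows); lysate Trp divided by the 0.69% proteome
Trp mass fraction gives protein mass, and 472 aa × 110 Da × 1 Da
(1.66054e−24 g) converts mass to molecules. Ribosomes: electropherogram
peaks are integrated trapezoidally above a straight baseline drawn
between the window-edge minima (instrument smoothing is not modeled);
the spike-in recovery ratio measures purification yield, clipped to 1
with a warning when noise pushes it above (yield is physically
bounded); copies per cell are
`(conc·vol·fraction/molar mass)·N_A/(yield·n_cells)` with molar masses
mouse 18S 6.40e5, mouse 28S 1.60e6, human 18S 6.40e5, human 28S
1.70e6 g/mol. Functional ribosomes are the raw minimum of the 18S- and
28S-derived counts, with no correction for unassembled subunits
(cytoplasmic localization of nearly all subunits justifies the raw
minimum). All censuses are homogeneous of degree −1 in cell number and
+1 in signal.

## Partition

A254 absorbance is rRNA-dominated, hence proportional to ribosome mass,
so gradient region areas need no per-peak ribosome multiplier. Free
40S/60S subunits carry no nascent chains and are excluded from both
numerator and denominator of the monosome fraction
`m = AUC(80S)/(AUC(80S) + AUC(polysomes))`. The dot-blot estimator
subtracts a single anti-puromycin background from both monosome and
polysome dots, then takes the monosome PMY/RPL7 ratio relative to the
polysome ratio (defined as 100% translating). The translation share is
`f·m/(f·m + 1 − m)`, monotone in both arguments and bounded by `m`;
its inverse `m = share/(f + share − f·share)` back-solves the monosome
content implied by an observed share. Puromycin reduces recovered
polysomes by ~5–10%; an optional correction factor on the polysome area
exposes this, default off.

The monosome ribosome fractions behind the observed translation shares
(~38% resting, ~32% activated at f = 0.33 and 0.52) are not directly
measured; the implied values (≈0.65 and ≈0.475) are obtained by
inversion, and the synthetic profile generator uses 0.65 as its default
resting-like condition.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic given (spec, seed) — byte-identical
reruns; seeds are explicit with no global state.

* **RPM events**: per-cell dispersion is multiplicative lognormal with
  log-scale σ = √ln(1+cv²) and median 1, applied to the full
  deterministic signal, so population medians converge exactly to the
  generating curve; the actual dispersion law of per-cell RPM signal is
  not established, and lognormal is a modeling choice (flow
  fluorescence is right-skewed). Background autofluorescence is also
  emitted as its own event population, mirroring unstained /
  pre-treated controls. Default design: t½ 70 s, 10% stalled, cv 0.4,
  8 chase times (0–900 s), 300 cells per timepoint.
* **Electropherograms**: Gaussian peaks at fixed abstract migration
  positions 1000/1800/4000 (no ladder calibration model); areas are in
  ng of RNA directly (the fluorescence→mass calibration is not
  modeled). Defaults put the 28S at 88% of the 18S copy number, inside
  the typical 75–90% range, with 80% purification yield.
* **Trp plates**: fluorescence strictly linear in Trp with additive
  Gaussian noise; default lysate 36.3 pg protein/cell.
* **Polysome profiles**: Gaussian peaks with geometrically decaying
  polysome weights; the monosome area fraction is the ground truth.
* **CFSE**: mean generation `g(t) = max(0, (t − lag)/T_d)` with
  median-preserving lognormal per-cell noise; defaults T_d 6.8 h, lag
  24 h. No death, precursor heterogeneity, or peak broadening is
  modeled — doubling-time recovery here validates the estimator's
  arithmetic, not its robustness to those real-data features.

None of the generators models instrument drift, spectral compensation,
gating error, donor-to-donor heterogeneity, RNA degradation, or blot
densitometry nonlinearity. Passing round-trip tests therefore
demonstrates estimator correctness under the stated noise model, not
performance on raw instrument files.

## Problem sizes and tolerances

Round-trip tolerances: zero-noise recovery to ≤1e−6 relative for all
generators (Gaussian peak truncation at ≥6σ windows and trapezoidal
integration on a fine grid keep discretization error below this);
with default noise, rRNA copies ±2%, protein mass ±3%, monosome
fraction ±0.02, doubling time ±5%, stalled fraction ±0.03. The
Monte-Carlo validation of the decay fit uses 50 replicate simulated
experiments at the default design with 200-replicate bootstrap CIs per
experiment (median |t½ error| < 10%, 95% CI coverage ≥ 90%); the
closed-form corrected duplication time is checked against forward ODE
integration (rtol 1e−12) on 100 random feasible parameter sets to
≤1e−6 relative. Analysis drivers use 500 bootstrap replicates.

## Known limitations

* Doubling times from published CFSE experiments (6.8 h day 1–2,
  7.7 h by day 2) cannot be recomputed from raw histograms here; they
  enter the accounting as fixed inputs.
* The per-sample eluate volumes and cell inputs behind real census
  measurements are not available; censuses are exercised on synthetic
  data only.
* Printed, rounded inputs do not always reproduce downstream printed
  values exactly (e.g. 1017 × 472 / 7.8 aa/s ≈ 17.1 h rather than a
  reported 15.5 h); the package computes from stated inputs at full
  internal precision and applies rounding only at report boundaries,
  surfacing rather than hiding such residual discrepancies.
* No Cyton-style death/precursor modeling, no CFSE peak deconvolution,
  no cell-cycle-resolved synthesis model, and no modeling of
  exogenous protein acquisition mechanisms that might resolve the
  paradox.
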