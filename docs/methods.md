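# Methods

This note records the models, numerical choices, and open design decisions
behind the package, and what the synthetic-data studies do and do not show
about real assay data.

## Chromatogram allele quantification

A Sanger chromatogram is modelled as four fluorescence channels sampled on a
common scan axis with one called base per peak. At a diagnostic SNP in a pooled
sample, the two allele channels carry peaks whose areas are proportional to the
two strains' template abundance; the primary-allele fraction is
`area_A / (area_A + area_C)`.

Two rules are not dictated by the assay itself and are this package's own:

- **Integration window.** The half-open scan window between the midpoints to
  the neighbouring basecall peaks (trace ends clamp to the array bounds).
  Midpoints are deterministic and parameter-free, and robust to modest
  peak-width variation.
- **Baseline correction.** Each channel's within-window minimum is subtracted
  before summation. This removes additive floor/cross-talk signal that would
  otherwise inflate the minor-allele area near 0% or 100% mixtures.

Both rules preserve two exact invariances that the tests enforce: swapping the
two allele channels maps a fraction f to 1−f, and rescaling all intensities by
any positive constant leaves the fraction unchanged.

Calibration is a straight line (ordinary least squares of measured on true
fraction over the nine-point mixture design 0–100%), inverted and clamped to
[0, 1] with a flag when clamping occurs. Nonlinear calibration is out of scope:
on both synthetic traces and the published behaviour of this assay class the
response is linear across the full range.

The primary trace format is a plain-text TSV (documented in `trace_io`);
standard ABI `.ab1` files are read through Biopython's ABIF parser (channels
DATA9–12 ordered by the FWO_1 tag, basecalls PBAS, peak locations PLOC) behind
the same `TraceSignal` contract. Base-calling, quality scores, and >2-allele
loci are out of scope.

## Competition fitness

The fitness readout for a two-strain competition is the log2 change in the
**odds** of strain A between mixing (t = 0) and the end point, i.e.
`log2[(f_t/(1−f_t)) / (f_0/(1−f_0))]`. Odds rather than raw fractions make the
two-strain ratio well defined and exactly antisymmetric under strain
relabelling, and dividing by the t0 odds normalizes away an imperfect 1:1
start. Fractions of exactly 0 or 1 are errors (a strain extinct or fixed at
measurement resolution), not pseudo-counted: the assay's operating regime is
far from fixation. Replicate log2 ratios are summarized as mean ± SEM;
division by elapsed generations (duration / doubling time) gives an optional
selection coefficient per generation, an extension beyond the raw log2
readout and labelled as such.

## Mark persistence model

Nucleosomes are assumed to segregate randomly between the daughter chromatids
at replication, so an unreplenished locus-level mark halves each division:
signal half-life = doubling time T_d. The reader–writer extension formalizes
maintenance — a reader complex binds the mark on retained old nucleosomes and
recruits the writer to re-methylate adjacent new ones — as a single
per-division probability m that a newly unmarked nucleosome is re-marked.
The marked fraction then picks up a factor (1+m)/2 per division; treating
replication as a continuous-rate process (matching asynchronous cultures and
the smooth dilution expectation usually drawn through such data) and adding a
first-order active-removal (demethylase) rate k per minute:

    f(t) = ((1+m)/2)^(t/T_d) · exp(−k·t),   signal(t) = background + s0·f(t)

- m = 0, k = 0: passive dilution, half-life = T_d.
- m = 1, k = 0: perfect inheritance, flat signal.
- half-life = ln2 / (k + ln(2/(1+m))/T_d), infinite when m = 1, k = 0.

The per-division parametrization is this package's formalization of a verbal
mechanism; no equation exists in the assay literature it emulates. It nests
both limiting behaviours that are actually drawn in such figures (the
dilution dashed line and a flat maintained signal). A discrete stochastic
simulator (`simulate_locus_divisions`: retain each marked nucleosome w.p. 1/2,
re-mark each newly unmarked position w.p. m) provides an independent check
that the closed form is the correct mean-field limit.

**Assumption:** ChIP recovery relative to input is taken as linear in the
marked-nucleosome fraction. This is standard but unverified; saturation or
epitope masking would bias fitted m downward.

### Fitting

T_d is measured from the culture (growth curves) and supplied, never fitted.
For fixed (m, k) the model is linear in (s0, background), so the fit profiles
the linear part by nonnegative weighted least squares (weights 1/SEM² when all
SEMs are positive, else unweighted) and searches the nonlinear part over a
deterministic grid (m in steps of 0.1; k on a log-spaced grid up to 0.1/min)
followed by L-BFGS-B refinement; RSS ties resolve to the smaller m, then the
smaller k, so the fit is reproducible bit-for-bit.

**Background identifiability.** With both s0 and background free, a flat time
course is unidentifiable: background can absorb the entire signal with s0 = 0,
which would make perfect maintenance indistinguishable from no signal. ChIP
experiments in this domain always carry a negative-control locus (a repressed
coding sequence), so when the time course includes control-locus signals the
background is fixed to their mean; otherwise it remains a free nonnegative
parameter. The synthetic generator emits the control by default.

### Model selection and regime calling

The three nested models are compared by small-sample-corrected AIC,
AICc = n·ln(RSS/n) + 2K + 2K(K+1)/(n−K−1), with K the number of free
mean-model parameters; a model whose correction denominator is ≤ 0 for the
available n gets +inf (it cannot be selected at that design size). The regime
label is: *heritable* if the selected model's m ≥ 0.5 (at least half of lost
marks are re-deposited per division — the signal outlives two passive
half-lives); *active_removal* if the selected k > 0 and the implied half-life
is shorter than T_d; else *passive_dilution*. The 0.5 cutoff and the
persistence threshold rule below are documented defaults, overridable by
argument.

**Persistence in generations** is the last timepoint at which the signal is
detectably above background — by default `signal − SEM ≥ background`, or
`signal − background ≥ threshold` with an explicit detection threshold —
divided by T_d. Detection thresholds in the source assays are never stated;
this SEM rule is the package's own. Note that under this rule a high
signal-to-background time course can remain "detected" for several
generations even while decaying passively; persistence and regime
classification are therefore reported together, not interchangeably.

## Localization baseline

The random-localization expectation treats the nucleus as a sphere and scores
a locus as peripheral when it lies within a shell of thickness f·R under the
envelope: P = 1 − (1−f)³. The shell fraction is an explicit parameter
defaulting to 0.1, which gives 27.1% — the conventional ~27% dashed line. The
3D-volume model (rather than a 2D optical-section geometry) is a modeling
choice; the Monte-Carlo estimator (uniform radius via U^(1/3)) exists purely
as an independent cross-check of the closed form. Enrichment and loss are
tested on replicate-level percentages (not pooled cells), matching
replicate-averaged ± SEM reporting, with one-tailed one-sample or Welch
two-sample t-tests; degenerate zero-variance data exactly at the null return
t = 0, p = 0.5 rather than NaN.

## qPCR arithmetic

Relative expression uses the comparative-Ct form E^(Ct_ref − Ct_target) with a
default amplification efficiency of 2.0 (perfect doubling; efficiencies are
rarely reported and the arithmetic is exposed per sample). ChIP recovery
relative to input is input_fraction · E^(Ct_input − Ct_ip). The two-sample
test is Welch's (unequal variances) — the safer default when the pooled-vs-
Welch choice is unstated. No multiple-testing correction is applied, matching
per-comparison reporting. Ct values are modelled, not derived from
fluorescence curves.

## Synthetic-data generators and study conditions

The generators define the study conditions under which every claim in the
test suite and the analysis scripts is evaluated:

- **Traces:** 41-base context with the SNP at basecall 20, flanks free of the
  allele bases so the SNP window contains only the two allele peaks; spacing
  10 scan indices/base, Gaussian peak sd 1.8, amplitude 1000, multiplicative
  peak-amplitude noise sd 5%. The noise level of real chromatograms is
  unreported; 5% makes the calibration visibly quantitative without being
  trivial, and is config-exposed.
- **Competitions:** 1:1 start, 180 min duration, T_d = 120 min, 3 biological
  replicates, additive Gaussian noise sd 0.02 on measured fractions (clamped
  inside (0,1)).
- **ChIP time courses:** 6 timepoints over 8 hr (0–480 min), 3 replicates,
  5% multiplicative noise, s0 = 10 over background 1 (a typical ChIP dynamic
  range), control locus included. Regimes: passive (m = 0, k = 0), maintained
  (m = 0.9–0.95), active removal (k = 0.03/min).
- **Localization:** binomial counts, ≥ 30 cells per replicate, 3 replicates.

Ground truth is returned alongside (or written as a sidecar manifest by
`make_fixture_suite`), never embedded in the data files. What the generators
do **not** emulate: dye blobs and mobility shifts in real traces, PCR
amplification bias, ChIP day effects and non-multiplicative noise, or
segmentation error in localization scoring. Passing tests therefore show that
the estimators are correct and well calibrated under the stated noise models,
not that those noise models exhaust real-data pathologies.

## Problem sizes

The standard-curve study uses 10 traces per design point (100 traces for the
1:1 recovery estimate); the null-competition study 200 simulated competitions
through the full trace pipeline; regime classification 100 time courses per
regime; the Monte-Carlo baseline 10⁶ points; the type-I study 2000 simulated
datasets. These sizes give Monte-Carlo errors comfortably below the effect
sizes being checked.

## Known limitations

- The maintenance parametrization is locus-lumped: no nucleosome-position
  resolution, no spreading kinetics, no distinction between maintenance by
  copying and re-establishment by sequence-targeted writing.
- Active removal is a single first-order rate; demethylase saturation or
  cell-cycle gating are not modelled (cell-cycle arrest is treated
  qualitatively, not fitted).
- Competitions are two-strain only; NGS-based multi-strain pool designs are
  out of scope.
- AICc on 6 timepoints is a coarse selector; with fewer points the
  maintenance-plus-removal model becomes unselectable by design.
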