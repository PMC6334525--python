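# Methods

`pluristate` models a common experimental motif in stem-cell biology: a
fluorescent pluripotency reporter (e.g. a Nanog-GFP knock-in) whose
population distribution is trimodal, a transient chemical perturbation
followed by wash-off and daily flow-cytometry monitoring, and a
single-cell qPCR panel read in treated vs control cells. The package
implements four linked analyses — mixture gating, transition-rate
fitting, expression-noise statistics and differential network inference —
plus a synthetic-data generator that provides ground truth for all of
them.

## Reporter-state mixture model

Log10 fluorescence of the pooled "virtual ensemble" (equal random draws
from every condition × day × replicate sample) is modeled as a
three-component Gaussian mixture; the components, ordered by ascending
mean, are the LN (low), MN (mid) and HN (high) reporter states. Fitting
uses EM with k-means initialization, 10 restarts, and a component-sd
floor of 1e-3 (via the covariance regularizer); model order is checked by
BIC over k = 1..5. The mixture is fit **once** on the pool and then
frozen: every cell in every sample is assigned a posterior over
(LN, MN, HN) by Bayes' rule under the shared model, computed in log
space so far-tail values remain well-defined. Freezing the model keeps
state definitions comparable across conditions and days; per-sample
refits would not.

Per-sample state fractions default to the mean posterior responsibility
("soft"); an argmax ("hard") mode is provided, and the two agree to
< 0.01 when components are well separated. Argmax ties break toward MN,
the transient state (a measure-zero event in practice). Nonpositive
intensities (instrument artifacts) are dropped before the log transform,
with a logged count.

## Transition kinetics

States form a linear chain HN ⇌ MN ⇌ LN with four first-order rates
(per day): A1 HN→MN, A2 MN→HN, A3 MN→LN, A4 LN→MN; there is no direct
HN↔LN transition. The composition p = (p_HN, p_MN, p_LN) evolves as
dp/dt = Q·p with the column-conservative generator Q, propagated exactly
by the matrix exponential — continuous time makes timepoint spacing
irrelevant and is the natural reading of "rates". No proliferation or
death terms are included: states are assumed to differ only by
switching. The propagator semantics are pinned by oracle tests against
explicit Euler integration (dt = 1e-4, agreement to 1e-4 for rates up to
2/day) and the closed-form two-step cascade p_LN(t) = 1 − e^{−t} −
t·e^{−t}.

Fitting minimizes the unweighted sum of squared deviations between
observed and predicted fractions over replicates, timepoints and states,
with rates constrained nonnegative. The initial composition is fixed to
the replicate-averaged day-0 observation by default (`p0_mode="measured"`,
removing two free parameters) or co-estimated (`"free"`). The search is
multi-start: 24 Latin-hypercube starts over [0, 3]/day plus a
deterministic all-zero start (which keeps no-flux optima reachable when
the data are constant); near-equal residuals are tie-broken toward the
smaller rate vector. Rates whose fluxes are unobservable (a state never
populated) are flagged unidentifiable. 95% intervals come from
case-resampling bootstrap over replicates (B = 200 by default); bootstrap
refits start from the point estimate rather than rerunning the full
multi-start, a deliberate economy that is accurate because the resampled
objective is a small perturbation of the original.

The **reversibility index** (A2 + A4)/(A1 + A3) summarizes reverse vs
forward flux; it is scale-invariant under rescaling all rates and is
reported per condition together with its ratio to a reference condition.

### Identifiability and the recovery experiment

Not every design identifies all four rates. A linearized
(Cramér–Rao-style) analysis under multinomial sampling noise shows that
starting from a composition dominated by HN with little LN (e.g.
p0 = (0.8, 0.15, 0.05)), the LN→MN rate A4 carries a relative sd near
0.7 at 4 replicates × 5,000 cells/day × days 0–5 — no estimator can
recover it accurately from such data. The package's end-to-end recovery
experiment therefore uses the **mid-state-sorted relaxation design**
(p0 = (0, 1, 0)): releasing a pure MN population exercises both forward
and both reverse transitions and brings the expected median relative
errors of all four rates below 15% at the same sample sizes. This
mirrors the sorting experiment such studies perform alongside wash-off
monitoring.

## Synthetic data

The generator defines the study conditions the tests probe.

* **Flow arm.** True state fractions from the exact propagator feed
  per-cell draws from the three-component log10 mixture (default truth:
  means 1.0/3.0/5.0, sds 0.4 — the same well-separated trimodal geometry
  used by the mixture-recovery checks); stored linear, gated on log.
  Default 10,000 cells/sample (per-day acquisition depth is rarely
  reported; this is a typical cytometer yield), 4 replicates, days 0–5;
  replicate scatter arises only from finite sampling.
* **Expression arm.** Cells × genes log2 expression via a Gaussian
  copula: planted Spearman correlations are converted to latent Pearson
  correlations (r = 2 sin(πρ/6)), the correlation matrix repaired by
  eigenvalue clipping if conflicting plants make it indefinite, and the
  latent values scaled per gene. Condition-specific **CV inflation**
  multiplies the sd at unchanged mean, so a gene's CV scales by exactly
  that factor. Independent per-entry dropout with gene × condition
  detection probability thins the matrix (leaving rank correlations
  among co-detected cells intact). Spike-ins are always detected at a
  constant level with technical sd 0.25 log2 units (a plausible
  plate-qPCR floor; configurable). The default panel is 40 genes, means
  uniform in 4–10 log2 units, CVs 0.3–0.5, detection 0.85, 35 cells per
  condition — the scale of a two-condition single-cell qPCR study.

What the generator does **not** emulate: cell-cycle or apoptosis
structure, mean–variance coupling beyond the planted CVs, amplification
bias, batch effects, or doublets. Passing tests demonstrate correctness
of the estimators under the stated generative model, not robustness to
those real-data features.

## Noise statistics

Per gene and condition: detection frequency, and over **detected cells
only** the mean, sample (n−1) sd, CV = sd/mean and CV². Genes with fewer
than 5 detected cells (configurable) or nonpositive mean are flagged
CV-undefined and excluded from CV contrasts; dropout is instead tested
directly as a frequency change by a two-sided Fisher exact test,
BH-adjusted across the panel (raw p drives the significance flag, the
adjusted value is reported alongside). Treating zeros as expression
values would conflate frequency with level noise, which are reported
separately. Ct-scale input converts as log2 expression = LOD − Ct
(default LOD 28; values at or beyond the LOD are undetected).

Spike-in QC removes cells whose mean spike-in signal deviates from the
cohort median by more than 3 MAD-scaled robust deviations, or with any
undetected spike-in; no value normalization to spike-ins is performed.

Condition contrasts are paired two-sided t tests across the gene panel,
run separately on CV and on mean; the per-gene **CV gain**
(CV_alt − CV_ref)/CV_ref quantifies relative noise change and is NaN
when the reference CV is undefined or nonpositive.

## Network inference

For every unordered pair of panel genes within a condition two
associations are computed: (i) a **binary** Fisher exact test on the 2×2
joint-detection table, with the Haldane–Anscombe +0.5 correction applied
to the odds ratio only when a cell is zero, flagged undefined when a
gene is detected in all or no cells; and (ii) **Spearman rank
correlation** over cells detecting both genes, requiring ≥ 10 co-detected
cells, so level correlation is not driven by joint dropout (which the
binary test already captures). P values are BH-adjusted separately per
family across the condition's pairs; an edge is kept when either
family's q < 0.05 (the disjunctive rule maximizes sensitivity when
co-detection counts are small; a conjunctive rule is available).

Networks from two conditions over the same node universe are compared by
partitioning the edge-pair union into common / A-only / B-only. Edge
counts incident to annotated target vs nontarget nodes quantify where
remodeling concentrates. The CV-gain contrast assigns each edge a gain —
the non-center endpoint's gain for subnetworks centered on chosen genes
(`mode="partner"`), or the mean of both endpoints (`mode="mean"`) — and
compares classes by two-sided Welch t tests (reported with class sizes;
classes under 2 usable gains are skipped with a flag).

A note on calibration: exact tests on discrete 2×2 tables are
conservative — their null rejection rate is bounded above by α but can
sit below it, most visibly at unbalanced margins. The calibration checks
therefore hold the correlation family to a two-sided binomial band
around α and the binary family to the one-sided bound.

## Numerical choices and limitations

* Proportion vectors are validated to sum to 1 within 1e-9 (inputs) and
  renormalized after propagation to absorb ~1e-16 round-off.
* Mixture fits with coincident component means (data not supporting k
  modes) raise rather than silently returning a degenerate model.
* The degenerate "all gains equal" contrast returns p = 1 (no evidence)
  instead of NaN.
* Problem sizes in the recovery experiments — 10–20 seeded repeats,
  5,000 cells/day, 35–100 cells per expression condition — are the
  package's chosen desk-scale study conditions; estimates of power and
  error quoted by the acceptance script carry the Monte-Carlo error of
  those sizes.
* Dose–response modeling across inhibitor concentrations, per-cell
  trajectory inference (hidden Markov), noise decomposition and
  causal/directed network inference are out of scope.
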