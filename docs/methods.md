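# Methods

This note records the models, conventions and numerical choices behind
`spliceindex`, and what the bundled synthetic cohorts do and do not
establish about real data.

## The Splice Index

Each panel event *z* is a cassette exon whose inclusion level Ψ ∈ [0, 1]
is estimated from targeted amplicon reads as
inclusion / (inclusion + exclusion) over unambiguously assigned,
junction-spanning read pairs. Per-sample scores are built in three steps:

1. **Normalization.** Ψ is rescaled between two normative anchors:
   `norm_z(Ψ) = (Ψ − Ψ_MedianControl,z) / (Ψ_DM95,z − Ψ_MedianControl,z)`.
   `Ψ_MedianControl,z` is the per-event median over unaffected adult
   controls. `Ψ_DM95,z` is the *severity-oriented* 95th percentile of the
   DM1 cohort: the literal 95th percentile of Ψ when the DM1 median lies
   above the control median, and the 5th percentile when it lies below.
   The orientation is required for the anchor to mark the severe end of
   both up- and down-shifted events (so that `norm(Ψ_DM95) = 1` always);
   a flag (`oriented=False`) provides literal 95th percentiles for
   comparison. Percentiles interpolate linearly between order statistics
   (1-based position (n − 1)p + 1); the convention is pinned for
   reproducibility.
2. **Averaging.** The score is the unweighted mean of normalized values
   over QC-passing events. Event-level values are deliberately *not*
   clamped before averaging — only the final mean is clamped into [0, 1]
   (healthy samples can sit slightly below 0 through sampling noise, and
   clamping per event would bias the mean upward).
3. **QC.** A sample needs `min_events` (default 18 of 22) QC-passing
   events for a score; per-event QC requires `min_depth` informative
   reads (default 100, which keeps the binomial SE of Ψ at or below
   0.05). Wilson 95% intervals accompany every Ψ estimate.

## Read classification contract

Reads are never spliced-aligned or soft-clipped: each mate is aligned
end-to-end (substitutions and indels as unit edits) against both isoform
amplicons of an event, in both orientations, using edit distance
(edlib's infix mode supplies the distance primitive).

* A mate is discarded as *unaligned* if its best distance to both
  isoforms exceeds `max_edit_frac` of read length (default 0.1).
* A mate is *informative* only if an optimal alignment covers a
  discriminating junction — flank→cassette or cassette→flank for the
  inclusion isoform, flank→flank for exclusion — with at least `anchor`
  nt on both sides (default 6 nt; the panel's smallest cassette is 15 nt,
  so the two inclusion junctions remain separable).
* The mate votes for the isoform with the strictly smaller distance;
  equal distances (e.g. a read entirely within a shared flank) yield no
  vote. Pairs whose mates disagree, or with no votes, are *ambiguous*;
  ambiguous and unaligned pairs never enter Ψ.
* Across the panel, a pair is attributed to the best-scoring event only
  if its advantage over the runner-up is at least `event_margin` edits
  (default 1); cross-event ties go to an unassigned tally, so every pair
  is counted exactly once.

Junction coverage is judged over the optimal alignment locations the
aligner reports. Degenerate ties between distinct optimal spans could in
principle flip a coverage call, but cannot occur at the sequence
diversity of real or simulated panels; the exhaustive reference
classifier used in the tests enumerates *all* optimal spans and agrees
exactly on every simulated library.

## Dose-response model

Event sensitivity to free MBNL activity x is modeled by a 4-parameter
logistic, `Ψ(x) = bottom + (top − bottom)/(1 + (EC50/x)^slope)`, with
`bottom` the asymptote as x → 0 (the disease end) and `top` the healthy
asymptote; events gaining inclusion in disease simply have
bottom > top. Fitting is bounded least squares (bottom, top ∈ [0, 1],
EC50 ∈ [10⁻³, 10²], slope ∈ [0.1, 10]) restarted from 8 log-spaced EC50
initializations across the observed activity range; flat fits
(|top − bottom| ≤ 0.02) are flagged non-identifiable because a constant
curve carries no EC50 information. The activity covariate is an external
input (e.g. an inferred free-MBNL estimate); it is not derived here.

Responder classes use EC50 quartiles at 1-based positions p(n + 1) with
strict tail membership: events strictly above Q3 are *early* (mis-spliced
after a small activity loss), strictly below Q1 *late*, the interquartile
range *intermediate*. This convention is chosen because it splits any 22
distinct EC50s exactly 5/12/5, matching the published panel composition;
interpolation at (n − 1)p + 1 would give 6/10/6.

## Cohort statistics

* **ICC** — two-way, absolute-agreement, *single-measure* coefficient
  (McGraw–Wong ICC(A,1)), computed from the ANOVA mean squares with the
  F-based 95% CI; single-measure because each time point contributes one
  measurement. Absolute agreement penalizes systematic shifts, so a pure
  offset yields ICC < 1.
* **Correlation** — Pearson (CI via Fisher z, tanh(atanh r ± z*/√(n−3)))
  or Spearman on mid-ranked data (CI via Fisher z with Fieller's
  rank-based standard error 1.03/√(n−3)); two-tailed p throughout.
* **Bland–Altman** — bias = mean(y − x), limits = bias ± 1.96·SD (sample
  SD, ddof 1).
* **Regression** — OLS with adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1);
  rank-deficient designs are rejected naming the collinear columns;
  Shapiro–Wilk p reported for residual normality.
* **Group comparisons** — paired t (identical vectors return t = 0,
  p = 1 rather than 0/0), or one-way ANOVA with Tukey's HSD; groups with
  n < 2 are excluded with a warning (mirroring the exclusion of a
  single-sample disease-control group from the source cohort's ANOVA).
* **LCA** — finite mixture of independent Bernoulli indicators fitted by
  EM: 300 random restarts (flat-Dirichlet weights, item probabilities
  uniform on (0.05, 0.95)), up to 5,000 iterations per restart,
  convergence at an absolute log-likelihood change below 10⁻¹⁰; the best
  restart is kept and classes are reported in descending-weight order
  (metrics are invariant to relabeling). AIC = −2ℓ + 2p and
  BIC = −2ℓ + p·ln n with p = K·d + (K − 1). Model search over
  increasing K stops once any modal class falls below 10% of the sample;
  among interpreted models the best BIC is reported. Indicators are
  chosen greedily under a pairwise |correlation| cap (default 0.8),
  preferring the five published indicator events when present, and are
  dichotomized at strictly-greater-than the cohort mean (values equal to
  the mean code 0).
* **Stratification** — fixed thresholds Mild ≤ 0.4 < Moderate ≤ 0.75 <
  Severe ≤ 1.0 (boundaries in the lower stratum), or 1-D k-means (50
  seeded restarts) with clusters relabeled by ascending center and
  per-cluster min/max reported as empirical bounds; if the data hold
  fewer distinct values than k, k is reduced with a warning.

## Synthetic cohort generator

The generator emulates the statistical structure the method assumes, with
defaults fixed at the study's conditions: 95 DM1 + 22 control samples,
control activity ~ Normal(1.0, 0.05) truncated positive, DM1 activity ~
Uniform(0.05, 1.0), 10,000 informative pairs per event, truncated-Gaussian
event noise (SD 0.02) on the 4PL mean. Per-event 4PL parameters span the
published EC50 range (0.263–1.03, median 0.619, five events in each
tail); the shipped panel's reference values are those curves evaluated at
healthy (x = 1.0) and severe (5th-percentile DM1) activity, so truth and
references are mutually consistent.

**Underdetection bias.** Amplicon sequencing preferentially amplifies the
shorter exclusion isoform. The generator models the inclusion isoform's
relative amplification efficiency as a decreasing logistic in cassette
length, β(L) = 1 − A/(1 + e^(−k(L − L₀))), and observes
p′ = pβ/(pβ + 1 − p) (exactly p at β = 1). The constants
(A = 0.55, L₀ = 60 nt, k = 0.11 nt⁻¹) were calibrated once against the
published characterization — near-zero bias for 15–33 nt cassettes,
strongest (~17%) for the 120–123 nt cassettes, panel-mean ≈ 7% over a
DM1-like Ψ distribution — and then frozen.

**Longitudinal drift.** At the follow-up time point DM1 activities drift
by Normal(−0.065, 0.03); the mean was calibrated once so that the
moderate stratum's expected change in SI is ≈ +0.1, and frozen. The same
activity drift applied to severe samples moves their SI by ≤ 0.05 on
average because their events sit on the 4PL plateaus — the ceiling is a
consequence of curve shape, not special-casing, and the test suite
verifies it in the noise-free limit where the mechanism is isolated.

**Outcomes.** Strength (%-predicted ankle dorsiflexion, hand grip, knee
extension) and 10 m run/walk speed rise monotonically (linearly) with
activity plus Gaussian noise; myotonia time falls quadratically with
activity. Knee extension carries deliberately larger noise (a proximal
muscle, weaker association with distal-muscle mis-splicing). These links
reproduce the *signs and ordering* of the published associations, not
their magnitudes.

**Reads.** Amplicon fragments span the whole isoform, so R1 is its 5′
prefix and R2 the reverse complement of its 3′ suffix (both
junction-covering by panel design, as in the real assay where the
amplicon is the fragment), with per-base substitution errors.

What passing tests show: the estimators are correct against independent
oracles under the generative model, and the pipeline is internally
consistent end-to-end (simulate → quantify → score recovers the
generative SI). What they do not show: robustness to features absent
from the generator — indel sequencing errors, PCR chimeras/duplicates,
RNA degradation, primer failure, batch effects, and real biological
deviation from 4PL dose-response shapes. The shipped panel's sequences
and reference values are synthetic placeholders; analyses of real data
must load the actual assay panel and cohort-derived references.

## Problem sizes and tolerances

The test suite and the acceptance script scale simulations to desk size
as the package's own choice: read-level checks use a 5-event toy panel
(40 nt flanks, 60 nt reads, 2,000 pairs at 1% error) where the
brute-force classifier is exhaustive yet fast; count-level round trips
use 50 samples at depth 10,000; 4PL recovery uses 120 samples per event
at Ψ noise SD 0.04; LCA replication uses 20 seeded datasets (n = 150,
5 indicators) with 4 restarts — the well-separated class profiles
converge in a few hundred EM iterations, so large restart counts are
unnecessary there, while the 300-restart default remains for real
analyses. Item-probability recovery is summarized as the mean absolute
error over the 15 profile entries (< 0.1), the noise-appropriate summary
at ~50 samples per class where single-entry binomial error alone
approaches 0.1. Closed-form statistics are checked to 10⁻¹⁰; 4PL
noiseless recovery to 10⁻⁴.

## Known limitations

* The read classifier is quality-score-agnostic and has no UMI or
  duplicate handling; demultiplexing is out of scope.
* EC50 uncertainty is reported only through fit RMSE, not confidence
  bands.
* The severity-oriented DM95 percentile and the treatment of missing
  events reflect documented package choices where published procedure is
  ambiguous; both are flagged and configurable.
* k-means stratification is applied to whichever score vector the caller
  supplies (baseline-only or pooled time points); the package does not
  impose one.
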