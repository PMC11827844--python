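# spliceindex

Tools for the **Myotonic Dystrophy Splice Index (SI)** — a composite RNA
mis-splicing biomarker for myotonic dystrophy type 1 (DM1).

In DM1, expanded CUG-repeat RNA sequesters the MBNL splicing factors, and a
characteristic panel of cassette exons reverts toward fetal inclusion
patterns as free MBNL activity falls. The SI distills a 22-event panel,
measured by targeted amplicon RNA-seq of tibialis anterior muscle, into a
single 0–1 severity score that tracks muscle strength and mobility. This
package implements the full analysis pipeline for researchers working with
such panels:

* **Ψ quantification** — classify paired-end amplicon reads to exon
  inclusion/exclusion isoforms under an unambiguous, junction-anchored
  alignment contract and estimate percent-spliced-in (Ψ) with Wilson
  confidence intervals;
* **SI scoring** — normalize each event's Ψ between normative anchors,

  `norm_z(Ψ) = (Ψ_y,z − Ψ_MedianControl,z) / (Ψ_DM95,z − Ψ_MedianControl,z)`,

  where `Ψ_MedianControl,z` is the median in unaffected adults and
  `Ψ_DM95,z` the severity-oriented 95th percentile of the DM1 cohort, then
  average over events and clamp into [0, 1];
* **dose-response classification** — fit each event's Ψ against an MBNL
  activity covariate with a four-parameter logistic,
  `Ψ(x) = bottom + (top − bottom) / (1 + (EC50/x)^slope)`, and classify
  events as early / intermediate / late responders by EC50 quartile;
* **cohort analysis** — fixed-threshold and k-means severity strata,
  latent class analysis (Bernoulli-mixture EM with AIC/BIC selection and a
  10% class-size stopping rule), test-retest ICC (two-way,
  absolute-agreement, single-measure), Pearson/Spearman correlation with
  Fisher-z intervals, Bland–Altman agreement, and OLS regression with
  adjusted R²;
* **synthetic cohorts** — a generator that emulates the statistical
  structure the method assumes (activity gradients, 4PL event responses,
  length-dependent amplicon underdetection bias, longitudinal drift,
  activity-linked outcomes), down to FASTQ emission, so the entire
  pipeline is testable without patient data.

Fit/transform-shaped pieces are scikit-learn estimators
(`SpliceIndexScorer`, `FourParamLogistic`, `BernoulliMixtureLCA`,
`KMeansStratifier`) and compose with sklearn pipelines; everything is also
reachable through plain functions and a `spliceindex` command-line
interface (`simulate`, `quantify`, `reference`, `score`,
`classify-events`, `stratify`, `stats`).

The shipped default panel names the published 22 events (CLCN1 e7a,
CACNA1S e29, INSR e11, ATP2A1 e22, MBNL1 e5, BIN1 e11, RYR1, KIF13A,
NFIX, …) with *synthetic placeholder sequences and reference values*;
real assay sequences, coordinates and normative anchors are supplied by
the user (`load_panel`, `derive_reference`).

## Worked example

Simulate a small cohort, score it, and stratify:

```python
import spliceindex as si

panel = si.default_panel()
cfg = si.SimulationConfig(seed=42, n_dm1=12, n_controls=4, depth=10_000)
cohort = si.simulate_cohort(cfg, panel)

ref = si.NormativeReference.from_panel(panel)
scorer = si.SpliceIndexScorer(min_events=18).set_reference(ref)
scores = scorer.score_samples(cohort.psi_obs)
table = scores.join(cohort.samples[["group", "si_true"]])
table["stratum"] = [si.stratify_fixed(v).value for v in table["si"]]
print(table.round(3).head(8).to_string())
```

```
              si  si_raw  events_used  qc_pass    group  si_true stratum
sample_id
CTRL000    0.000  -0.008           22     True  control    0.000    Mild
CTRL001    0.014   0.014           22     True  control    0.002    Mild
CTRL002    0.000  -0.003           22     True  control    0.000    Mild
CTRL003    0.007   0.007           22     True  control    0.000    Mild
DM1000     0.921   0.921           22     True      DM1    0.936  Severe
DM1001     0.036   0.036           22     True      DM1    0.025    Mild
DM1002     0.152   0.152           22     True      DM1    0.147    Mild
DM1003     0.122   0.122           22     True      DM1    0.118    Mild
```

Each row is one participant: `si` is the clamped composite score (controls
sit at ~0, the most severely mis-spliced DM1 samples near 1), `si_raw` the
unclamped event mean, and `events_used` the number of QC-passing panel
events behind the score. `si_true` is the generator's ground truth — the
scored values recover it to a few thousandths at this depth.

Dose-response classification against the (here, simulated) MBNL activity
covariate:

```python
fits = [si.fit_4pl(cohort.samples["activity"], cohort.psi_obs[eid], event_id=eid)
        for eid in panel.event_ids]
classes = si.classify_panel(fits)
```

On a full-size simulated cohort (95 DM1 + 22 controls) this prints
per-event fits such as `CLCN1_e7a: EC50=0.636 slope=2.24 rmse=0.020` and
splits the panel 5 early / 12 intermediate / 5 late with a median EC50 of
0.599 — early responders (highest EC50) mis-splice after only a small
loss of MBNL activity, late responders only at the severe end.

The same pipeline from the shell:

```bash
spliceindex simulate --out-dir run/ --seed 7 --fastq-samples 2
spliceindex quantify --r1 run/CTRL000_R1.fastq --r2 run/CTRL000_R2.fastq \
    --panel-config run/panel.json --panel-fasta run/panel_isoforms.fasta \
    --out run/counts.tsv
spliceindex score --psi run/psi_obs_baseline.tsv --reference run/reference.tsv \
    --out run/si.tsv
```

Every command writes a JSON run manifest (parameters, input checksums,
seed, version); replaying a manifest reproduces its outputs byte for byte.

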