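# screenref

Decision-referral evaluation for AI-assisted double-reader cancer
screening.

In population breast-cancer screening every exam is read by radiologists,
and an AI classifier can emit a continuous malignancy score *s* ∈ [0, 1].
Rather than replacing the reader, a **decision-referral** system acts only
where the AI is confident, using two thresholds fitted on a validation
split:

* *s* < θ_low — **normal triage**: the exam is auto-reported negative and
  leaves the reader's worklist;
* *s* > θ_high — **safety net**: the exam is auto-flagged positive,
  overriding a reader miss;
* θ_low ≤ *s* ≤ θ_high — **referral**: the reader's recall decision stands.

θ_low is the largest observed score keeping an NT-target fraction (e.g.
97%) of validation cancer mass above it; θ_high the smallest score keeping
an SN-target fraction (e.g. 98%) of validation normal mass below it.
`screenref` evaluates this combined system against the unaided reader and
against standalone AI (single threshold, positive iff *s* ≥ θ) on
retrospective cohorts with two independent reader decisions per exam.

Because study datasets oversample cancers, all metrics are
inverse-probability weighted back to the population prevalence π:
w_i = target-proportion(label_i) / sample-proportion(label_i). Reported
quantities are weighted sensitivity Se, specificity Sp, triaging
performance (weighted fraction of all exams that are truly normal *and*
triaged — the automatable share of the worklist), and weighted
ROC curves with AUROC as the Mann–Whitney statistic (ties ½), on the full
cohort and on the confident subset outside [θ_low, θ_high]. Uncertainty
comes from a two-step bootstrap (sample one of the two readers per study,
then resample studies with replacement; percentile 95% CIs) and pathway
differences are tested with an exact paired sign-flip permutation test
(mid-p tie handling).

A synthetic cohort generator with closed-form oracles makes every stage
testable without any real imaging data: class-conditional binormal AI
latents (AUROC = Φ(μ/√(1+σ²))), two reader latents correlated with the AI
latent and each other, exact quantile calibration of reader Se/Sp, and
configurable cancer enrichment.

## Worked example

```python
from screenref import DecisionReferral, GeneratorParams, generate_cohort

validation, _ = generate_cohort(GeneratorParams(
    n_studies=20_000, split="VALIDATION", seed=3))
test, _ = generate_cohort(GeneratorParams(n_studies=50_000, seed=4))

model = DecisionReferral(validation, test, nt_target=0.97, sn_target=0.98)
results = model.fit(inference=False)   # inference=True adds CIs + p-values
print(results.summary())
```

```
Decision-referral evaluation
================================================================
Configuration           NT@0.97+SN@0.98   (thresholds 0.6913 / 0.9791)
Standalone threshold    0.8866 (Se target 0.872)
Validation fitting      weighted
Test cohort             n=50000 (cancers=2978), pi=0.006, ESS=47564.0
----------------------------------------------------------------
pathway                 Se %    Sp %   dSe pp   dSp pp     p(Se)
RADIOLOGIST             87.2    93.4
STANDALONE_AI           86.5    88.7     -0.7     -4.8
DECISION_REFERRAL       90.3    94.9     +3.1     +1.5
----------------------------------------------------------------
Triaging performance    68.6% of studies auto-negative and truly normal
AUROC (all studies)     0.949
AUROC (confident set)   0.981 on 35358 studies
```

Reading the table: standalone AI is *less* accurate than the average
unaided reader on both axes, yet the same scores used in referral mode
improve the reader by +3.1 sensitivity points and +1.5 specificity points
while removing 68.6% of exams from the worklist — because on the
confident subset (where the AI acts alone) its ranking is much sharper
(AUROC 0.981) than overall (0.949). `results.plot_roc()` draws the curve
with the three operating points; `operating_point_grid` sweeps a whole
NT × SN target grid, and `stratified_report` breaks sensitivity down by
density, finding type, lesion-size bin, site or manufacturer.

The same pipeline runs from the shell:

```bash
screenref simulate --n 20000 --seed 3 --out validation.csv
screenref fit --validation validation.csv --prevalence 0.006 \
    --nt 0.97 --sn 0.98 --out config.json
screenref route --cohort test.csv --prevalence 0.006 \
    --operating-config config.json --reader average --out routed.csv
screenref evaluate --config run.yaml --out-dir artifacts/
```

`evaluate` writes the operating-point grid, per-study ROC points,
subgroup tables and a manifest (config snapshot, input digests, seeds,
timings) so a run is reproducible from its artifacts alone.

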