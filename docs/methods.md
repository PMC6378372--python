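# Methods

This note documents the models, defaults and numerical choices behind
`fingercue`, and what its synthetic-data tests do and do not establish.

## Task model and error measure

One trial is a sense-then-match sequence: the subject experiences a vertical
fingertip offset `d_y` (thumb minus index, mm) under one of six force
conditions, then reproduces it from memory. The matching error is
`hold_dy - sense_dy`. The six conditions cross tangential (shear) force
direction on the two digits — both up (`TUP_IUP`), both down (`TDN_IDN`),
opposite (`TUP_IDN`, `TDN_IUP`) — plus a no-force control (`NULL`) and a
normal-force-only control (`FN_ONLY`). Only the opposite-direction
conditions are expected to bias matching. Three experiments vary the
available input: combined tactile + non-tactile (1), tactile-only via
wearable finger-pad stimulators (2), non-tactile-only via voluntary force
against a grounded haptic device (3), each with its own group of subjects.

## Synthetic-data generator

`synthetic_data.generate_experiment` draws, per trial,

```
hold_dy = sense_dy + baseline_s + effect(experiment, condition) + noise
```

- `baseline_s ~ N(0, subject_baseline_sd²)`, one constant per subject
  (default sd 2 mm): the idiosyncratic offset the Null correction removes.
- `effect` defaults to the study's headline medians in the two
  opposite-direction conditions (Exp 1: +9.2 / −9.9 mm; Exp 2: +7.9 / −5.1;
  Exp 3: +5.7 / −3.5) and 0 in the same-direction, Null and Fn-only
  conditions, whose observed medians are statistically indistinguishable
  from zero.
- `noise` is trial-level with **median exactly zero** (default Gaussian,
  sd 3 mm). The skewed families use a skew-normal re-centred by its median
  and rescaled to the requested sd, so the configured effect remains the
  *median* of the generated errors under any skew — every summary in the
  analysis is a median. `trial_noise_sd` accepts a per-experiment mapping
  (used, e.g., to place the combined-cue experiment at the optimal-fusion
  noise level `1/σ₁² = 1/σ₂² + 1/σ₃²`).
- Design sizes follow the protocol: 10 subjects per experiment, 6
  conditions, 5 repetitions (Exps 1–2) or 6 (Exp 3).
- Sense-phase positions and forces are drawn uniformly inside the
  compliance windows (`sense_dy` within ±2 mm by default, comfortably
  inside the ±3 mm tolerance; aperture 65 ± 2 mm; normal force 4–5 N;
  tangential magnitude 2.5–3.5 N signed by condition). A
  `noncompliance_rate` fraction of trials instead violates one randomly
  chosen window (Null trials violate by carrying force).
- Forces are per-trial scalars (sense-phase summaries): the analysis uses
  no time-resolved traces.
- A single integer seed drives everything; per-experiment substreams are
  spawned from a `SeedSequence`, so output tables are byte-identical across
  reruns.

What the generator does **not** emulate: within-trial dynamics, skew and
heavy tails of real matching errors (configurable but off by default),
learning/fatigue trends across repetitions, and any dependence between
force magnitude and error size. Passing recovery tests therefore shows the
*pipeline* is correct and well-calibrated under the design's nominal
statistical structure, not that real data meet these assumptions.

## Compliance checking

`check_trial` is a pure per-trial predicate over the windows above, with a
0.25 N zero-tolerance for "no force" in Null/Fn-only trials (the protocol
gives no explicit threshold; configurable). Non-compliant trials are
dropped before analysis by default (`drop=False` keeps them flagged).
`group_compliance_tests` mirrors the study's pooled verification: per
condition and variable, two one-sided Wilcoxon signed-rank tests against
the window bounds; a cell passes when neither test is significant at
α = 0.05, i.e. the pooled values neither systematically exceed the upper
bound nor undershoot the lower. All-degenerate cells (every value on a
bound) report p = 1 and a `degenerate` flag.

## Baseline correction

Per subject × experiment, the baseline is the **mean** of that subject's
Null raw errors (the median is available via `stat="median"`), subtracted
from all conditions including Null. The correction is idempotent, and each
subject's corrected Null errors average exactly zero by construction.

## Condition summaries and the bootstrap CI

Each (experiment, condition) cell is summarised by the pooled median, a
seeded percentile-bootstrap 95% CI, a one-tailed Wilcoxon signed-rank test
against zero with the tail chosen by the sign of the observed median, and
Cohen's `r = |z|/√n` with the cell's actual n.

The bootstrap resamples **subjects, then trials within subject** (two-stage)
by default. Corrected errors within a subject are positively correlated:
they share that subject's Null-baseline estimation error, whose variance is
`σ²/m` for m Null repetitions (1.8 mm² against 9 mm² trial variance at the
defaults, intraclass correlation ≈ 0.17). A plain i.i.d. trial bootstrap
ignores this and undercovers — at the default design we measure ≈ 90%
coverage of the true effect for a nominal 95% interval versus ≈ 98% for the
two-stage scheme. `bootstrap_unit="trial"` restores the i.i.d. variant.

Because the tail of the Wilcoxon test follows the observed median's sign,
its null-hypothesis rejection rate is ~2α rather than α, further inflated
by the same within-subject correlation (the pooled test treats the 50
trials as independent, as the original analysis did). Zero-effect cells
are therefore flagged "significant" in roughly 15–20% of simulated
datasets at α = 0.05 — a property of the pooled directional testing scheme
itself, visible in the calibration tests, and worth remembering when
reading the non-headline cells of any single run. The NULL cell is immune:
mean-correction centres each subject exactly, which makes its test
conservative.

## Nonparametric kernel

- **Wilcoxon signed-rank**: zeros dropped (flagged); mid-ranks for tied
  magnitudes. Exact p by dynamic-programming enumeration of the 2^n sign
  assignments when n ≤ 12 and the magnitudes are tie-free; otherwise a
  normal approximation with tie-corrected variance and 0.5 continuity
  correction. `z` is always reported, signed by the effect direction, so
  effect sizes are computable on either path.
- **Kruskal-Wallis** delegates to `scipy.stats.kruskal` (tie-corrected H,
  χ² reference with k−1 df); tests verify it against the hand-rank formula.
- **Post-hoc**: Dunn's z contrasts on pooled ranks with tie correction;
  Holm adjustment by default (Bonferroni / none switchable).
- **Fatigue check**: Pearson r and slope-test p of corrected error against
  repetition index, trials ordered by repetition across subjects.

## Cue summation

The two single-cue error samples come from different subject groups, so
the sum in the linear-summation test needs a pairing policy:
`subject_rank_pairing` (default) sorts both samples and pairs
quantile-matched positions, `random_pairing` is a seeded random bijection,
`all_pairs` the full cross sum. Rank pairing makes the summed sample's
spread the *sum* of the component spreads (comonotonic coupling) — a
conservative, deterministic choice; the policy is recorded in every output
so sensitivity is visible. The summation test is a two-sided Wilcoxon
rank-sum of the combined-cue sample against the summed sample.

Contribution weights use ε = 10⁻⁶ mm on the denominator `b_t + b_nt`;
within ε of zero the weights are flagged undefined rather than returned.
Reliability is `1/s²` (ddof = 1) of each corrected-error sample, classified
as optimal (`r₁ ≥ r₂ + r₃`, boundary inclusive), rejected
(`r₁ < min(r₂, r₃)`) or sub-optimal linear summation otherwise.

## Strength of bias

Null quartiles are computed **pooled** across subjects per experiment
(numpy's linear / R type-7 interpolation; switchable, since quartiles of
~50 values are definition-sensitive), while exceedance fractions and their
baseline subtraction are per subject, then averaged. Both the
subject-averaged and the pooled-trial variants are reported, since either
reading is defensible; the signed residual is `p_pos − p_neg` in both. In
the residual the two baseline subtractions largely cancel for a symmetric
Null sample, so the residual directly reflects the condition's directional
exceedance. Under the default noise a 7.9 mm effect drives the residual
near its ceiling of 1; comparisons across effect sizes are therefore
ordinal, not proportional.

## Pipeline and problem sizes

`run_pipeline` chains the stages deterministically under one seed and
writes CSV/JSON artifacts plus a manifest with SHA-256 checksums of every
output (`verify_manifest` re-hashes them). Default problem sizes
everywhere follow the study design (300–360 trials per experiment);
simulation-based tests use 20–100 replicate datasets and bootstrap sizes of
1000–2000, which keep every Monte-Carlo standard error at least an order of
magnitude below the asserted margins. `scripts/acceptance.py` averages each
recovered cell median over 100 replicate datasets, giving a standard error
of ≈ 0.06 mm on the reported values.

## Known limitations

- Published CI bounds cannot be matched digit-for-digit: the original CI
  method is unspecified, and the bootstrap here is a package choice.
- The published summed-bias medians (10.3 / −10.8 mm) depend on an
  unstated cross-group pairing and on the skew of the real data; the
  package reports them only as reference display values.
- Real printed effect sizes imply n ≈ 55 rather than the pooled 50; the
  effect-size operation takes n explicitly and the pipeline uses the true
  cell size.
- The generator's independence and symmetry defaults are idealisations;
  all conclusions from synthetic runs are about pipeline correctness and
  calibration under those conditions.
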