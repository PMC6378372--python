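# fingercue

Analysis pipeline for a haptic psychophysics question: **how do tactile and
non-tactile force signals bias our sense of where our fingertips are relative
to each other?**

In a precision-grip matching task, a subject senses the vertical offset
`d_y` between thumb and index fingertip (thumb minus index, mm; positive =
thumb higher) while digit forces are present, then reproduces that offset
from memory. Tangential (shear) forces of *opposite* direction on the two
digits induce a systematic matching error — the reproduced offset drifts in
the direction the forces pushed. The error carries two separable
components: a **tactile** one (finger-pad compression and skin stretch,
deliverable by a wearable haptic device without any voluntary force) and a
**non-tactile** one (efference copy and muscle/joint proprioception from
voluntary force production against a grounded device). Three experiments
isolate them: both cues together (Exp 1), tactile only (Exp 2), non-tactile
only (Exp 3).

`fingercue` implements the complete trial-level analysis of that design, and
a seeded synthetic-trial generator that emulates the design's statistical
structure so the whole pipeline is testable without the original recordings.

## The statistics at the core

Writing `Dyer_t`, `Dyer_nt`, `Dyer_comb` for the median baseline-corrected
matching errors with tactile-only, non-tactile-only and combined cues:

- **Linear cue summation** — the hypothesis `Dyer_comb = Dyer_t + Dyer_nt`,
  tested by a rank-sum comparison of the combined-cue error sample against a
  sample of tactile + non-tactile sums (paired by rank across the two
  subject groups by default).
- **Contribution weights** — `alpha_t = Dyer_t / (Dyer_t + Dyer_nt)` and
  `alpha_nt = 1 - alpha_t`: the fraction of the combined bias each input
  accounts for.
- **Reliability classification** — treating the inverse variance `r = 1/s²`
  of each error distribution as the reliability of the position estimate:
  `r_comb ≥ r_t + r_nt` is optimal (maximum-likelihood) fusion,
  `r_comb < min(r_t, r_nt)` rejects summation, anything between is
  sub-optimal linear summation.
- **Strength of bias** — the probability that a condition's errors escape
  the interquartile range of the Null (no-force) error distribution, each
  subject's own Null exceedance subtracted; the signed residual
  `p_pos - p_neg` is ~0 without a consistent bias.
- All inference is nonparametric: one-tailed Wilcoxon signed-rank tests
  (exact by 2^n enumeration for small samples), Kruskal-Wallis across
  groups, Dunn post-hoc contrasts, effect size `r = |z|/√n`.

Before any of that, trials pass sense-phase compliance checks (fingertips
collinear within ±3 mm, aperture 65 ± 3 mm, normal force 4–5 N, tangential
2.5–3.5 N in the prescribed direction), and each subject's idiosyncratic
offset is removed by subtracting the mean error of their Null trials.

## Worked example

```python
from fingercue import (GeneratorConfig, generate_experiment, apply_qc,
                       raw_errors, baseline_correct, summarize_condition,
                       cue_weights)

cfg = GeneratorConfig()                      # ten subjects, default effects
trials = apply_qc(generate_experiment(cfg, 1, seed=1), drop=True)
errors = baseline_correct(raw_errors(trials))
s = summarize_condition(errors, 1, "TUP_IDN", n_boot=2000, seed=1)
print(f"Exp 1, TUP-IDN: median {s.median:.2f} mm "
      f"(95% CI [{s.ci_low:.2f}, {s.ci_high:.2f}]), "
      f"z = {s.wilcoxon_z:.2f}, p = {s.p_value:.2g}, r = {s.effect_r:.2f}")
w = cue_weights(7.9, 5.7)
print(f"tactile contribution alpha_t = {w.alpha_t:.2f}, "
      f"non-tactile alpha_nt = {w.alpha_nt:.2f}")
```

prints

```
Exp 1, TUP-IDN: median 9.06 mm (95% CI [7.92, 11.32]), z = 6.15, p = 3.9e-10, r = 0.87
tactile contribution alpha_t = 0.58, non-tactile alpha_nt = 0.42
```

The simulated opposite-direction condition recovers its configured 9.2 mm
bias (the CI brackets it), the bias is overwhelmingly significant with a
large effect size, and the contribution weights say the tactile input
carries ~58% of the combined bias.

The same analysis runs from the shell:

```
fingercue run --seed 1 --out results_run
fingercue report --out results_run --reference   # adds published benchmarks
```

which chains simulate → qc → errors → summaries → cues → strength, writes
CSV/JSON artifacts plus a checksummed manifest, and renders `report.md`.

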