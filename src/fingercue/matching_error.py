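"""Matching errors, Null-baseline correction, and condition summaries.

The bias measure of the task is the matching error: the vertical fingertip
offset reproduced from memory (hold phase) minus the offset actually sensed
(sense phase).  Because each subject carries an idiosyncratic constant offset
(finger geometry, personal perceptual bias), the mean error of that subject's
Null (no-force) trials is subtracted from all of their errors before any
group statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fingercue.conditions import CONDITIONS, EXPERIMENTS
from fingercue.nonparam_stats import effect_size_r, wilcoxon_signed_rank

ERROR_COLUMNS = (
    "subject_id",
    "experiment",
    "condition",
    "repetition",
    "raw_error",
    "corrected_error",
)


def raw_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial raw matching error: ``hold_dy - sense_dy``.

    Returns one row per input trial with ``corrected_error`` unset (NaN).
    """
    for col in ("hold_dy", "sense_dy"):
        if trials[col].isna().any():
            raise ValueError(f"missing {col} values")
    out = trials.loc[
        :, ["subject_id", "experiment", "condition", "repetition"]
    ].copy()
    out["raw_error"] = trials["hold_dy"].to_numpy(float) - trials[
        "sense_dy"
    ].to_numpy(float)
    out["corrected_error"] = np.nan
    return out


def baseline_correct(errors: pd.DataFrame, stat: str = "mean") -> pd.DataFrame:
    """Subtract each subject's Null-condition baseline within each experiment.

    The baseline is the ``stat`` ("mean", the default, or "median") of that
    subject's Null raw errors.  The correction is applied to *all* conditions
    including Null itself, so with the mean statistic each subject's corrected
    Null errors average exactly zero.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    out = errors.copy()
    null_rows = out[out["condition"] == "NULL"]
    agg = null_rows.groupby(["subject_id", "experiment"])["raw_error"].agg(stat)

    missing = (
        out.set_index(["subject_id", "experiment"]).index.unique().difference(agg.index)
    )
    if len(missing):
        subj, exp = missing[0]
        raise ValueError(
            f"subject {subj!r} has no Null trials in experiment {exp}; "
            "baseline correction impossible"
        )
    baseline = out.set_index(["subject_id", "experiment"]).index.map(agg)
    out["corrected_error"] = out["raw_error"].to_numpy(float) - np.asarray(baseline)
    return out


@dataclass
class ConditionSummary:
    """Median, bootstrap CI, and one-tailed Wilcoxon result for one cell."""

    experiment: int
    condition: str
    n: int
    median: float
    ci_low: float
    ci_high: float
    wilcoxon_z: float
    p_value: float
    effect_r: float
    alternative: str
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median <= self.ci_high:
            raise ValueError("CI must bracket the median")

    def to_dict(self) -> dict:
        return {
            "experiment": int(self.experiment),
            "condition": self.condition,
            "n": int(self.n),
            "median": float(self.median),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "wilcoxon_z": float(self.wilcoxon_z),
            "p_value": float(self.p_value),
            "effect_r": float(self.effect_r),
            "alternative": self.alternative,
            "flags": list(self.flags),
        }


def bootstrap_median_ci(
    values: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    subjects: np.ndarray | None = None,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap CI for the median.

    With ``subjects`` given, resampling is two-stage (subjects with
    replacement, then that subject's trials with replacement), which respects
    the within-subject correlation the Null-baseline estimate induces;
    without it, trials are resampled i.i.d.
    """
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    n = values.size
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    if subjects is None:
        idx = rng.integers(0, n, size=(n_boot, n))
        medians = np.median(values[idx], axis=1)
    else:
        subjects = np.asarray(subjects)
        uniq = np.unique(subjects)
        groups = [values[subjects == s] for s in uniq]
        k = len(groups)
        medians = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, k, size=k)
            sample = np.concatenate(
                [groups[g][rng.integers(0, groups[g].size, size=groups[g].size)]
                 for g in pick]
            )
            medians[b] = np.median(sample)
    return float(np.quantile(medians, lo_q)), float(np.quantile(medians, hi_q))


def summarize_condition(
    errors: pd.DataFrame,
    experiment: int,
    condition: str,
    n_boot: int = 2000,
    seed: int = 0,
    bootstrap_unit: str = "subject",
    min_n: int = 6,
) -> ConditionSummary:
    """Summarise one (experiment, condition) cell of corrected errors.

    Reports the pooled median with a seeded percentile-bootstrap 95% CI
    (two-stage over subjects by default, since errors within a subject share
    the estimated baseline; ``bootstrap_unit='trial'`` gives the plain i.i.d.
    bootstrap), a one-tailed Wilcoxon signed-rank test against zero with the
    direction set by the sign of the observed median, and Cohen's
    ``r = |z|/sqrt(n)``.
    """
    if bootstrap_unit not in ("subject", "trial"):
        raise ValueError("bootstrap_unit must be 'subject' or 'trial'")
    cell = errors[
        (errors["experiment"] == experiment) & (errors["condition"] == condition)
    ]
    values = cell["corrected_error"].to_numpy(float)
    if values.size < min_n:
        raise ValueError(
            f"cell (exp {experiment}, {condition}) has {values.size} errors; "
            f"need >= {min_n}"
        )
    median = float(np.median(values))
    flags: list[str] = []
    if np.allclose(values, values[0]):
        ci_low = ci_high = median
        flags.append("degenerate_constant_errors")
    else:
        subjects = (
            cell["subject_id"].to_numpy() if bootstrap_unit == "subject" else None
        )
        ci_low, ci_high = bootstrap_median_ci(
            values, n_boot=n_boot, seed=seed, subjects=subjects
        )
        ci_low, ci_high = min(ci_low, median), max(ci_high, median)

    alternative = "greater" if median >= 0 else "less"
    test = wilcoxon_signed_rank(values, mu=0.0, alternative=alternative)
    z = test.z or 0.0
    return ConditionSummary(
        experiment=int(experiment),
        condition=condition,
        n=int(values.size),
        median=median,
        ci_low=ci_low,
        ci_high=ci_high,
        wilcoxon_z=z,
        p_value=test.p_value,
        effect_r=effect_size_r(z, values.size),
        alternative=alternative,
        flags=flags + list(test.flags),
    )


def summarize_all(
    errors: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    bootstrap_unit: str = "subject",
) -> list[ConditionSummary]:
    """Summaries for every experiment x condition cell present in ``errors``."""
    summaries = []
    for exp in EXPERIMENTS:
        if not (errors["experiment"] == exp).any():
            continue
        for i, cond in enumerate(CONDITIONS):
            summaries.append(
                summarize_condition(
                    errors,
                    exp,
                    cond,
                    n_boot=n_boot,
                    seed=seed + 97 * exp + i,
                    bootstrap_unit=bootstrap_unit,
                )
            )
    return summaries
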