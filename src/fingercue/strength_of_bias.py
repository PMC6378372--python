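"""Strength-of-bias statistic: Null-IQR exceedance probabilities.

For each force condition the statistic asks how often a trial's corrected
matching error escapes the interquartile range of the Null (no-force)
condition, i.e. how often the force combination produced an error larger
than the task's intrinsic variability.  Quartiles of the Null errors are
computed pooled across subjects per experiment; exceedance fractions are
computed per subject, the subject's own Null exceedance fractions are
subtracted (so a subject who is intrinsically variable does not inflate the
statistic), and the subject values are averaged.  The signed residual
``p_pos - p_neg`` summarises whether the condition pushes errors
consistently in one direction: ~0 means no consistent bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: numpy quantile interpolation used for the Null quartiles.  With only
#: ~50 Null trials the quartiles are definition-sensitive, so this is
#: deliberately switchable; "linear" is numpy's default (R type 7).
DEFAULT_QUANTILE_METHOD = "linear"


def null_quartiles(
    null_errors, method: str = DEFAULT_QUANTILE_METHOD
) -> tuple[float, float]:
    """First and third quartile of the pooled Null corrected errors."""
    arr = np.asarray(null_errors, dtype=float)
    if arr.size < 4:
        raise ValueError("need >= 4 Null errors for quartiles")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method=method)
    return float(q1), float(q3)


@dataclass
class BiasStrength:
    """Exceedance probabilities for one condition (baseline-subtracted)."""

    experiment: int
    condition: str
    q1_null: float
    q3_null: float
    p_pos: float  # subject-averaged, Null-subtracted
    p_neg: float
    residual: float  # p_pos - p_neg
    pooled_p_pos: float  # pooled-trial variant (no per-subject averaging)
    pooled_p_neg: float
    pooled_residual: float
    n_trials: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.residual <= 1.0:
            raise ValueError("residual must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "experiment": int(self.experiment),
            "condition": self.condition,
            "q1_null": float(self.q1_null),
            "q3_null": float(self.q3_null),
            "p_pos": float(self.p_pos),
            "p_neg": float(self.p_neg),
            "residual": float(self.residual),
            "pooled_p_pos": float(self.pooled_p_pos),
            "pooled_p_neg": float(self.pooled_p_neg),
            "pooled_residual": float(self.pooled_residual),
            "n_trials": int(self.n_trials),
        }


def _exceedance(values: np.ndarray, q1: float, q3: float) -> tuple[float, float]:
    if values.size == 0:
        return 0.0, 0.0
    return float(np.mean(values > q3)), float(np.mean(values < q1))


def bias_strength(
    cond_errors: pd.DataFrame,
    null_errors: pd.DataFrame,
    quantile_method: str = DEFAULT_QUANTILE_METHOD,
) -> BiasStrength:
    """Strength of bias of one condition against the Null distribution.

    Both inputs are matching-error tables (``subject_id``, ``experiment``,
    ``condition``, ``corrected_error``) restricted to a single experiment:
    ``cond_errors`` holds the force condition of interest, ``null_errors``
    the Null trials.  Every subject present in the condition must also have
    Null trials.
    """
    exps = set(cond_errors["experiment"]) | set(null_errors["experiment"])
    if len(exps) != 1:
        raise ValueError("condition and Null errors must come from one experiment")
    experiment = exps.pop()
    conds = set(cond_errors["condition"].unique())
    if len(conds) != 1:
        raise ValueError("cond_errors must hold a single condition")
    condition = conds.pop()

    null_values = null_errors["corrected_error"].to_numpy(float)
    q1, q3 = null_quartiles(null_values, method=quantile_method)

    null_by_subject = dict(tuple(null_errors.groupby("subject_id")))
    p_pos_list, p_neg_list = [], []
    for subject, sub in cond_errors.groupby("subject_id"):
        if subject not in null_by_subject:
            raise ValueError(f"subject {subject!r} has no Null trials")
        vals = sub["corrected_error"].to_numpy(float)
        nvals = null_by_subject[subject]["corrected_error"].to_numpy(float)
        pp, pn = _exceedance(vals, q1, q3)
        bp, bn = _exceedance(nvals, q1, q3)
        p_pos_list.append(pp - bp)
        p_neg_list.append(pn - bn)
    p_pos = float(np.mean(p_pos_list))
    p_neg = float(np.mean(p_neg_list))

    cond_values = cond_errors["corrected_error"].to_numpy(float)
    pooled_pp, pooled_pn = _exceedance(cond_values, q1, q3)
    base_pp, base_pn = _exceedance(null_values, q1, q3)
    pooled_p_pos = pooled_pp - base_pp
    pooled_p_neg = pooled_pn - base_pn

    return BiasStrength(
        experiment=int(experiment),
        condition=str(condition),
        q1_null=q1,
        q3_null=q3,
        p_pos=p_pos,
        p_neg=p_neg,
        residual=p_pos - p_neg,
        pooled_p_pos=pooled_p_pos,
        pooled_p_neg=pooled_p_neg,
        pooled_residual=pooled_p_pos - pooled_p_neg,
        n_trials=int(cond_values.size),
    )


def bias_strength_all(
    errors: pd.DataFrame, quantile_method: str = DEFAULT_QUANTILE_METHOD
) -> list[BiasStrength]:
    """Strength of bias for every non-Null condition of every experiment."""
    results = []
    for exp, sub in errors.groupby("experiment"):
        null_rows = sub[sub["condition"] == "NULL"]
        for cond in sub["condition"].unique():
            if cond == "NULL":
                continue
            results.append(
                bias_strength(
                    sub[sub["condition"] == cond],
                    null_rows,
                    quantile_method=quantile_method,
                )
            )
    return results
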