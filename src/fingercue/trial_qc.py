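"""Sense-phase compliance checks.

The protocol constrains the sense phase of every trial: fingertips collinear
(|d_y| <= 3 mm), grip aperture 65 +/- 3 mm, normal digit force 4-5 N, and
tangential force magnitude 2.5-3.5 N in the direction the condition
prescribes.  Null trials must carry no force at all and normal-force-only
trials no tangential force (both up to a small zero-tolerance).

Two layers of checking mirror the study's procedure: a per-trial predicate
(:func:`check_trial`) used to flag and optionally drop non-compliant trials,
and pooled group-level tests (:func:`group_compliance_tests`) verifying with
one-tailed Wilcoxon signed-rank tests that the pooled sense-phase values do
not systematically exceed either window bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fingercue.conditions import TANGENTIAL_SIGNS, validate_condition
from fingercue.nonparam_stats import wilcoxon_signed_rank


@dataclass
class ComplianceLimits:
    """Sense-phase windows, in the units of the trial table (mm, N)."""

    dy_tol: float = 3.0
    dz_nominal: float = 65.0
    dz_tol: float = 3.0
    fn_range: tuple[float, float] = (4.0, 5.0)
    ft_range_abs: tuple[float, float] = (2.5, 3.5)
    #: magnitude below which a force counts as "no force" (Null / Fn-only)
    zero_tol: float = 0.25

    def __post_init__(self) -> None:
        if self.dy_tol <= 0 or self.dz_tol <= 0:
            raise ValueError("tolerances must be > 0")
        for name in ("fn_range", "ft_range_abs"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} lower bound must be < upper bound")


def compute_dy(thumb_y: float, index_y: float) -> float:
    """Vertical fingertip offset: thumb coordinate minus index coordinate.

    Positive d_y means the thumb contact point sits above the index one.
    """
    if not (math.isfinite(thumb_y) and math.isfinite(index_y)):
        raise ValueError("coordinates must be finite")
    return thumb_y - index_y


def check_trial(trial, limits: ComplianceLimits | None = None) -> tuple[bool, list[str]]:
    """Evaluate one trial against every applicable window.

    ``trial`` is a mapping (e.g. a DataFrame row) with the trial-table
    fields.  Returns ``(qc_pass, violations)``; the violation labels name the
    breached window and digit.
    """
    limits = limits or ComplianceLimits()
    cond = validate_condition(trial["condition"])
    violations: list[str] = []

    if abs(trial["sense_dy"]) > limits.dy_tol:
        violations.append("sense_dy_out_of_window")
    if abs(trial["sense_dz"] - limits.dz_nominal) > limits.dz_tol:
        violations.append("sense_dz_out_of_window")

    fn_lo, fn_hi = limits.fn_range
    ft_lo, ft_hi = limits.ft_range_abs
    t_sign, i_sign = TANGENTIAL_SIGNS[cond]

    if cond == "NULL":
        for digit, fn, ft in (
            ("thumb", trial["thumb_fn"], trial["thumb_ft"]),
            ("index", trial["index_fn"], trial["index_ft"]),
        ):
            if abs(fn) > limits.zero_tol or abs(ft) > limits.zero_tol:
                violations.append("force_in_null")
                break
        return (not violations, violations)

    for digit, fn in (("thumb", trial["thumb_fn"]), ("index", trial["index_fn"])):
        if fn < fn_lo:
            violations.append(f"normal_below_range({digit})")
        elif fn > fn_hi:
            violations.append(f"normal_above_range({digit})")

    if cond == "FN_ONLY":
        for digit, ft in (("thumb", trial["thumb_ft"]), ("index", trial["index_ft"])):
            if abs(ft) > limits.zero_tol:
                violations.append(f"tangential_in_fn_only({digit})")
    else:
        for digit, ft, sign in (
            ("thumb", trial["thumb_ft"], t_sign),
            ("index", trial["index_ft"], i_sign),
        ):
            directed = sign * ft  # positive when the force points the required way
            if directed < ft_lo:
                violations.append(f"tangential_below_range({digit})")
            elif directed > ft_hi:
                violations.append(f"tangential_above_range({digit})")

    return (not violations, violations)


def apply_qc(
    trials: pd.DataFrame,
    limits: ComplianceLimits | None = None,
    drop: bool = False,
) -> pd.DataFrame:
    """Fill ``qc_pass`` for every trial; optionally drop failing trials.

    Returns a copy.  Dropping (the default downstream policy is to drop
    before error analysis) keeps the flags of the surviving rows.
    """
    limits = limits or ComplianceLimits()
    out = trials.copy()
    flags = [check_trial(row, limits)[0] for _, row in out.iterrows()]
    out["qc_pass"] = pd.array(flags, dtype="boolean")
    if drop:
        out = out[out["qc_pass"].fillna(False)].reset_index(drop=True)
    return out


@dataclass
class GroupCheckResult:
    """Pooled two-one-sided-tests outcome for one variable in one condition."""

    variable: str
    condition: str
    statistic: float
    p_value: float  # the smaller of the two one-sided p-values
    p_upper: float  # H1: values exceed the upper bound
    p_lower: float  # H1: values fall below the lower bound
    n: int
    passed: bool
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "condition": self.condition,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "p_upper": float(self.p_upper),
            "p_lower": float(self.p_lower),
            "n": int(self.n),
            "passed": bool(self.passed),
            "flags": list(self.flags),
        }


def _two_one_sided(values: np.ndarray, lo: float, hi: float, alpha: float):
    """One-tailed Wilcoxon tests against both window bounds.

    The cell passes when neither test is significant, i.e. the pooled values
    neither systematically exceed the upper bound nor undershoot the lower.
    """
    flags: list[str] = []
    if np.allclose(values, lo) or np.allclose(values, hi):
        return 0.0, 1.0, 1.0, True, ["degenerate"]
    upper = wilcoxon_signed_rank(values, mu=hi, alternative="greater")
    lower = wilcoxon_signed_rank(values, mu=lo, alternative="less")
    if "degenerate" in upper.method or "degenerate" in lower.method:
        flags.append("degenerate")
    passed = upper.p_value > alpha and lower.p_value > alpha
    worse = upper if upper.p_value <= lower.p_value else lower
    return worse.z or 0.0, upper.p_value, lower.p_value, passed, flags


def group_compliance_tests(
    trials: pd.DataFrame,
    limits: ComplianceLimits | None = None,
    alpha: float = 0.05,
    min_n: int = 6,
) -> list[GroupCheckResult]:
    """Group-level window tests, pooled across subjects per condition.

    For each condition and each applicable variable (sense d_y and d_z for
    every condition; normal forces for force conditions; directed tangential
    forces for tangential conditions) two one-sided Wilcoxon signed-rank
    tests are run against the window bounds.  A cell passes iff both
    p-values exceed ``alpha``.
    """
    limits = limits or ComplianceLimits()
    results: list[GroupCheckResult] = []
    for cond, cell in trials.groupby("condition", sort=False):
        validate_condition(str(cond))
        t_sign, i_sign = TANGENTIAL_SIGNS[str(cond)]
        variables: list[tuple[str, np.ndarray, float, float]] = [
            (
                "sense_dy",
                cell["sense_dy"].to_numpy(float),
                -limits.dy_tol,
                limits.dy_tol,
            ),
            (
                "sense_dz",
                cell["sense_dz"].to_numpy(float),
                limits.dz_nominal - limits.dz_tol,
                limits.dz_nominal + limits.dz_tol,
            ),
        ]
        if cond != "NULL":
            fn_lo, fn_hi = limits.fn_range
            variables.append(("thumb_fn", cell["thumb_fn"].to_numpy(float), fn_lo, fn_hi))
            variables.append(("index_fn", cell["index_fn"].to_numpy(float), fn_lo, fn_hi))
        if t_sign and i_sign:
            ft_lo, ft_hi = limits.ft_range_abs
            variables.append(
                ("thumb_ft", t_sign * cell["thumb_ft"].to_numpy(float), ft_lo, ft_hi)
            )
            variables.append(
                ("index_ft", i_sign * cell["index_ft"].to_numpy(float), ft_lo, ft_hi)
            )
        for name, values, lo, hi in variables:
            if values.size < min_n:
                raise ValueError(
                    f"cell ({cond}, {name}) has {values.size} trials; need >= {min_n}"
                )
            stat, p_up, p_lo, passed, flags = _two_one_sided(values, lo, hi, alpha)
            results.append(
                GroupCheckResult(
                    variable=name,
                    condition=str(cond),
                    statistic=stat,
                    p_value=min(p_up, p_lo),
                    p_upper=p_up,
                    p_lower=p_lo,
                    n=int(values.size),
                    passed=passed,
                    flags=flags,
                )
            )
    return results
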