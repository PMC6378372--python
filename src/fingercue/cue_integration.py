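"""Linear cue-summation analysis and reliability classification.

Writing ``b_t`` and ``b_nt`` for the median matching biases measured with
only the tactile cue (tactile-only experiment) or only the non-tactile cue
(non-tactile-only experiment), linear summation predicts that the bias with
both cues present equals ``b_t + b_nt``.  The fractional contributions are

    alpha_t  = b_t  / (b_t + b_nt)
    alpha_nt = b_nt / (b_t + b_nt)        (alpha_t + alpha_nt = 1)

A second, reliability-based view treats each error distribution's inverse
variance as the reliability of the underlying position estimate.  Under
optimal (maximum-likelihood) fusion reliabilities add, so comparing the
combined-cue reliability with the two single-cue reliabilities classifies
the integration regime: at least additive (optimal), between the better
single cue and additive (sub-optimal but consistent with linear summation),
or below both single cues (linear summation rejected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from fingercue.nonparam_stats import TestResult

EPS_DENOMINATOR = 1e-6  # mm; |b_t + b_nt| below this leaves weights undefined

PAIRING_POLICIES = ("subject_rank_pairing", "random_pairing", "all_pairs")


@dataclass
class CueWeights:
    alpha_t: float
    alpha_nt: float
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "alpha_t": None if not self.defined else float(self.alpha_t),
            "alpha_nt": None if not self.defined else float(self.alpha_nt),
            "defined": bool(self.defined),
        }


def cue_weights(dyer_t: float, dyer_nt: float, eps: float = EPS_DENOMINATOR) -> CueWeights:
    """Fractional tactile / non-tactile contributions to the combined bias.

    Undefined (flagged, NaN weights) when the two single-cue biases cancel
    to within ``eps``, where the ratio is meaningless.
    """
    denom = dyer_t + dyer_nt
    if abs(denom) <= eps:
        return CueWeights(alpha_t=float("nan"), alpha_nt=float("nan"), defined=False)
    alpha_t = dyer_t / denom
    return CueWeights(alpha_t=float(alpha_t), alpha_nt=float(1.0 - alpha_t))


def summed_bias_distribution(
    errors_t,
    errors_nt,
    pairing_policy: str = "subject_rank_pairing",
    seed: int | None = None,
) -> np.ndarray:
    """Sample of tactile + non-tactile error sums under a pairing policy.

    The two error samples come from different subject groups, so no natural
    pairing exists; the policy decides one:

    - ``subject_rank_pairing``: sort both samples and pair by rank
      (quantile-matched positions when sizes differ); output size
      ``min(n_t, n_nt)``.
    - ``random_pairing``: seeded random bijection between the first
      ``min(n_t, n_nt)`` elements of independent shuffles.
    - ``all_pairs``: every cross pair; output size ``n_t * n_nt``.
    """
    if pairing_policy not in PAIRING_POLICIES:
        raise ValueError(f"pairing_policy must be one of {PAIRING_POLICIES}")
    a = np.asarray(errors_t, dtype=float)
    b = np.asarray(errors_nt, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both error samples must be non-empty")

    if pairing_policy == "all_pairs":
        return np.add.outer(a, b).ravel()

    n = min(a.size, b.size)
    if pairing_policy == "subject_rank_pairing":
        a_s, b_s = np.sort(a), np.sort(b)
        ia = np.round(np.linspace(0, a.size - 1, n)).astype(int)
        ib = np.round(np.linspace(0, b.size - 1, n)).astype(int)
        return a_s[ia] + b_s[ib]

    rng = np.random.default_rng(seed)
    return rng.permutation(a)[:n] + rng.permutation(b)[:n]


def test_linear_summation(
    summed_sample, exp1_errors, alpha: float = 0.05
) -> TestResult:
    """Rank-sum comparison of the summed single-cue biases with the
    combined-cue biases.

    A non-significant difference (p > ``alpha``) is consistent with linear
    summation of the two cues.
    """
    s = np.asarray(summed_sample, dtype=float)
    c = np.asarray(exp1_errors, dtype=float)
    if s.size < 6 or c.size < 6:
        raise ValueError("both samples need >= 6 values")
    flags = []
    if np.allclose(s, s[0]) and np.allclose(c, c[0]):
        flags.append("degenerate_constant_samples")
        z, p = 0.0, 1.0
    else:
        z, p = stats.ranksums(c, s)
    result = TestResult(
        name="linear_summation_ranksum",
        statistic=float(z),
        z=float(z),
        p_value=float(p),
        n=int(s.size + c.size),
        method="normal_approx",
        flags=flags,
    )
    result.flags.append(
        "consistent_with_linear_summation" if p > alpha else "summation_rejected"
    )
    return result


test_linear_summation.__test__ = False  # not a pytest test, despite the name


@dataclass
class ReliabilityTriple:
    """Inverse-variance reliabilities of the three error distributions."""

    condition: str
    r_exp1: float
    r_exp2: float
    r_exp3: float
    classification: str = field(init=False)

    def __post_init__(self) -> None:
        if min(self.r_exp1, self.r_exp2, self.r_exp3) <= 0:
            raise ValueError("reliabilities must be positive")
        self.classification = classify_reliability(
            self.r_exp1, self.r_exp2, self.r_exp3
        )

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "r_exp1": float(self.r_exp1),
            "r_exp2": float(self.r_exp2),
            "r_exp3": float(self.r_exp3),
            "classification": self.classification,
        }


def classify_reliability(r1: float, r2: float, r3: float) -> str:
    """Integration regime implied by combined vs single-cue reliabilities.

    - ``optimal_summation``: the combined reliability reaches (or exceeds)
      the additive maximum-likelihood prediction ``r2 + r3``.
    - ``reject_summation``: the combined estimate is *less* reliable than
      both single cues, incompatible with using both.
    - ``suboptimal_linear_summation``: anything in between.
    """
    if r1 >= r2 + r3:
        return "optimal_summation"
    if r1 < min(r2, r3):
        return "reject_summation"
    return "suboptimal_linear_summation"


def reliability_analysis(
    errors_exp1, errors_exp2, errors_exp3, condition: str = ""
) -> ReliabilityTriple:
    """Reliability triple from the three corrected-error samples.

    Reliability is the inverse of the sample variance (ddof=1) of the
    baseline-corrected errors; variance-based, so invariant to adding any
    constant to a sample.
    """
    rs = []
    for label, sample in (
        ("exp1", errors_exp1),
        ("exp2", errors_exp2),
        ("exp3", errors_exp3),
    ):
        arr = np.asarray(sample, dtype=float)
        if arr.size < 6:
            raise ValueError(f"{label} sample needs >= 6 values")
        var = float(np.var(arr, ddof=1))
        if var == 0.0:
            raise ValueError(f"{label} sample has zero variance")
        rs.append(1.0 / var)
    return ReliabilityTriple(condition=condition, r_exp1=rs[0], r_exp2=rs[1], r_exp3=rs[2])


@dataclass
class CueDecomposition:
    """Full per-condition summation analysis, serialisable to JSON."""

    condition: str
    dyer_t: float
    dyer_nt: float
    dyer_comb: float
    weights: CueWeights
    summed_median: float
    summed_ci: tuple[float, float]
    summation_test: TestResult
    pairing_policy: str

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "dyer_t": float(self.dyer_t),
            "dyer_nt": float(self.dyer_nt),
            "dyer_comb": float(self.dyer_comb),
            "weights": self.weights.to_dict(),
            "summed_median": float(self.summed_median),
            "summed_ci": [float(self.summed_ci[0]), float(self.summed_ci[1])],
            "summation_test": self.summation_test.to_dict(),
            "pairing_policy": self.pairing_policy,
        }


def decompose_condition(
    errors_exp1,
    errors_exp2,
    errors_exp3,
    condition: str,
    pairing_policy: str = "subject_rank_pairing",
    seed: int = 0,
    n_boot: int = 2000,
) -> CueDecomposition:
    """Run the whole summation analysis for one force condition."""
    from fingercue.matching_error import bootstrap_median_ci

    e1 = np.asarray(errors_exp1, dtype=float)
    e2 = np.asarray(errors_exp2, dtype=float)
    e3 = np.asarray(errors_exp3, dtype=float)
    summed = summed_bias_distribution(e2, e3, pairing_policy, seed=seed)
    ci = bootstrap_median_ci(summed, n_boot=n_boot, seed=seed)
    return CueDecomposition(
        condition=condition,
        dyer_t=float(np.median(e2)),
        dyer_nt=float(np.median(e3)),
        dyer_comb=float(np.median(e1)),
        weights=cue_weights(float(np.median(e2)), float(np.median(e3))),
        summed_median=float(np.median(summed)),
        summed_ci=ci,
        summation_test=test_linear_summation(summed, e1),
        pairing_policy=pairing_policy,
    )
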