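"""Nonparametric test kernel used throughout the pipeline.

The one-sample Wilcoxon signed-rank test is implemented here rather than
delegated, because the analysis needs behaviour scipy does not expose in one
place: exact enumeration of the signed-rank distribution for small samples,
a tie- and continuity-corrected normal approximation with the z statistic
signed by the direction of the effect, and degenerate-sample flagging.  The
Kruskal-Wallis H test wraps :func:`scipy.stats.kruskal`; Dunn's post-hoc
z contrasts on pooled ranks are implemented here (no installed package
provides them) with Holm/Bonferroni adjustment via statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_CUTOFF = 12  # full 2^n enumeration is cheap up to here

ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class TestResult:
    """Outcome of a single nonparametric test."""

    name: str
    statistic: float
    p_value: float
    n: int
    z: float | None = None
    tails: str = "two"
    method: str = "normal_approx"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p_value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": float(self.statistic),
            "z": None if self.z is None else float(self.z),
            "p_value": float(self.p_value),
            "n": int(self.n),
            "tails": self.tails,
            "method": self.method,
            "flags": list(self.flags),
        }


def _signed_rank_exact_distribution(ranks: np.ndarray) -> np.ndarray:
    """Counts of W+ over all sign assignments, by dynamic programming.

    ``ranks`` must be positive integers; entry ``k`` of the result is the
    number of the ``2**n`` assignments with rank-sum ``k``.
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    values,
    mu: float = 0.0,
    alternative: str = "two-sided",
    exact_cutoff: int = EXACT_CUTOFF,
) -> TestResult:
    """One-sample Wilcoxon signed-rank test of median == ``mu``.

    Zero differences are dropped (flagged).  With at most ``exact_cutoff``
    non-zero differences and no ties among their magnitudes, the p-value is
    exact by full enumeration of the 2^n sign assignments; otherwise a normal
    approximation with mid-rank tie correction and a 0.5 continuity
    correction is used.  The reported ``z`` always carries the sign of the
    effect (positive when values tend to exceed ``mu``).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    d = np.asarray(values, dtype=float) - mu
    if not np.all(np.isfinite(d)):
        raise ValueError("values must be finite")
    flags: list[str] = []
    nz = d[d != 0.0]
    n_zero = d.size - nz.size
    if n_zero:
        flags.append(f"dropped_{n_zero}_zero_differences")
    n = nz.size
    if n == 0:
        return TestResult(
            name="wilcoxon_signed_rank",
            statistic=0.0,
            z=0.0,
            p_value=1.0,
            n=0,
            tails="one" if alternative != "two-sided" else "two",
            method="degenerate",
            flags=flags + ["degenerate_all_zero"],
        )

    absd = np.abs(nz)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[nz > 0].sum())
    mean_w = n * (n + 1) / 4.0

    # z from the normal approximation (reported even on the exact path, for
    # effect-size computation), signed by the effect direction.
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var_w <= 0:
        return TestResult(
            name="wilcoxon_signed_rank",
            statistic=w_plus,
            z=0.0,
            p_value=1.0,
            n=n,
            tails="one" if alternative != "two-sided" else "two",
            method="degenerate",
            flags=flags + ["degenerate_zero_variance"],
        )
    diff = w_plus - mean_w
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var_w) if diff != 0.0 else 0.0

    has_ties = tie_counts.size != n
    if n <= exact_cutoff and not has_ties:
        counts = _signed_rank_exact_distribution(ranks)
        total = 2.0**n
        w_int = int(round(w_plus))
        p_ge = counts[w_int:].sum() / total
        p_le = counts[: w_int + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        method = "exact"
    else:
        if alternative == "greater":
            p = stats.norm.sf(z)
        elif alternative == "less":
            p = stats.norm.cdf(z)
        else:
            p = 2.0 * stats.norm.sf(abs(z))
        p = float(min(1.0, p))
        method = "normal_approx"

    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=w_plus,
        z=float(z),
        p_value=float(p),
        n=n,
        tails="one" if alternative != "two-sided" else "two",
        method=method,
        flags=flags,
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) across independent groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(
            name="kruskal_wallis",
            statistic=0.0,
            p_value=1.0,
            n=pooled.size,
            method="degenerate",
            flags=["degenerate_constant_data"],
        )
    h, p = stats.kruskal(*groups)
    return TestResult(
        name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        n=int(pooled.size),
        method="chi2_approx",
    )


def posthoc_pairwise(groups, method: str = "holm") -> list[TestResult]:
    """Dunn's pairwise z contrasts on pooled ranks after Kruskal-Wallis.

    ``method`` selects the multiplicity adjustment: ``holm`` (default),
    ``bonferroni``, or ``none``.
    """
    if method not in ("holm", "bonferroni", "none"):
        raise ValueError("method must be 'holm', 'bonferroni' or 'none'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    raw: list[tuple[int, int, float, float]] = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            raw.append((i, j, z, min(1.0, p)))

    pvals = [r[3] for r in raw]
    if method == "none":
        adj = pvals
    else:
        adj = multipletests(pvals, method=method)[1]

    results = []
    for (i, j, z, _), p_adj in zip(raw, adj):
        results.append(
            TestResult(
                name=f"dunn[{i}-{j}]",
                statistic=float(z),
                z=float(z),
                p_value=float(p_adj),
                n=sizes[i] + sizes[j],
                method=f"dunn_{method}",
            )
        )
    return results


def effect_size_r(z: float, n: int) -> float:
    """Cohen's r for a rank test: ``|z| / sqrt(n)``, clipped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(np.clip(abs(z) / np.sqrt(n), 0.0, 1.0))


@dataclass
class FatigueCorrelation:
    """Pearson correlation of corrected error against repetition index."""

    condition: str
    experiment: int
    r: float
    p_value: float
    slope: float
    n: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "experiment": int(self.experiment),
            "r": float(self.r),
            "p_value": float(self.p_value),
            "slope": float(self.slope),
            "n": int(self.n),
            "flags": list(self.flags),
        }


def fatigue_correlation(errors, condition: str, experiment: int) -> FatigueCorrelation:
    """Trial-level error-versus-repetition regression for one condition.

    ``errors`` is a matching-error table (see :mod:`fingercue.matching_error`)
    with ``corrected_error`` filled.  Trials are ordered by repetition (all
    subjects' first repetitions, then all second repetitions, ...), and the
    Pearson r together with the slope-test p of corrected error on repetition
    index is returned.  A significant positive slope would indicate bias
    growing over the session, the signature of muscle fatigue.
    """
    cell = errors[
        (errors["condition"] == condition) & (errors["experiment"] == experiment)
    ].sort_values(["repetition", "subject_id"])
    if cell["repetition"].nunique() < 3:
        raise ValueError("need at least 3 distinct repetitions")
    x = cell["repetition"].to_numpy(dtype=float)
    y = cell["corrected_error"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return FatigueCorrelation(
            condition, experiment, 0.0, 1.0, 0.0, x.size, ["degenerate_constant_errors"]
        )
    fit = stats.linregress(x, y)
    return FatigueCorrelation(
        condition=condition,
        experiment=experiment,
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        n=int(x.size),
    )
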