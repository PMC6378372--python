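"""Seeded generator of synthetic matching-task trial tables.

The generator emulates the between-group design of the three experiments:
ten subjects per experiment, six force conditions presented five times
(Experiments 1 and 2) or six times (Experiment 3).  Each trial draws

``hold_dy = sense_dy + subject_baseline + condition_effect + noise``

where ``subject_baseline`` is a constant idiosyncratic offset per subject
(what the Null-condition correction later removes), ``condition_effect`` is
the configured median bias of the force combination, and ``noise`` is
trial-level noise with median zero.  Sense-phase positions and digit forces
are drawn inside the protocol compliance windows except for a configurable
fraction of deliberately non-compliant trials.

All randomness flows from a single integer seed; per-experiment streams are
derived deterministically with :class:`numpy.random.SeedSequence`, so a given
``(config, seed)`` pair always produces a byte-identical CSV.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from fingercue.conditions import (
    CONDITIONS,
    EXPERIMENTS,
    TANGENTIAL_SIGNS,
    validate_experiment,
)

#: Column order of the on-disk trial table.
TRIAL_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "experiment",
    "condition",
    "repetition",
    "sense_dy",
    "hold_dy",
    "sense_dz",
    "thumb_fn",
    "index_fn",
    "thumb_ft",
    "index_ft",
    "qc_pass",
)

KEY_COLUMNS: tuple[str, ...] = ("subject_id", "experiment", "condition", "repetition")

NOISE_FAMILIES: tuple[str, ...] = ("symmetric", "right-skewed", "left-skewed")


def default_condition_effects() -> dict[tuple[int, str], float]:
    """Median biases (mm) encoded by the default configuration.

    Opposite-direction tangential forces produce the headline biases observed
    in the three experiments; same-direction, Null and normal-force-only
    conditions are unbiased (their observed medians are statistically
    indistinguishable from zero).
    """
    effects = {(exp, cond): 0.0 for exp in EXPERIMENTS for cond in CONDITIONS}
    effects[(1, "TUP_IDN")] = 9.2
    effects[(1, "TDN_IUP")] = -9.9
    effects[(2, "TUP_IDN")] = 7.9
    effects[(2, "TDN_IUP")] = -5.1
    effects[(3, "TUP_IDN")] = 5.7
    effects[(3, "TDN_IUP")] = -3.5
    return effects


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-trial generator.

    Attributes
    ----------
    n_subjects
        Subjects per experiment (a fresh group per experiment, as in the
        between-group design).
    reps_per_condition
        Repetitions of each force condition, keyed by experiment.
    condition_effect
        Median bias in mm keyed by ``(experiment, condition)``.
    subject_baseline_sd
        SD (mm) of the constant per-subject idiosyncratic offset.
    trial_noise_sd
        SD (mm) of trial-level noise; a scalar applies to all experiments, a
        mapping ``{experiment: sd}`` sets them individually.
    noise_family, noise_skew
        ``symmetric`` draws Gaussian noise; the skewed families draw a
        skew-normal re-centred so its *median* is zero, keeping the configured
        effect a median regardless of skew.
    sense_dy_jitter
        Half-width (mm) of the uniform sense-phase vertical offset; must stay
        within the 3 mm compliance tolerance.
    dz_nominal, dz_jitter
        Grip aperture (mm) and half-width of its uniform jitter.
    fn_range, ft_range_abs
        Compliance windows for normal force and tangential-force magnitude (N).
    noncompliance_rate
        Probability that a trial deliberately violates at least one window.
    seed
        Base seed; per-experiment streams are spawned from it.
    """

    n_subjects: int = 10
    reps_per_condition: dict[int, int] = field(
        default_factory=lambda: {1: 5, 2: 5, 3: 6}
    )
    condition_effect: dict[tuple[int, str], float] = field(
        default_factory=default_condition_effects
    )
    subject_baseline_sd: float = 2.0
    trial_noise_sd: float | dict[int, float] = 3.0
    noise_family: str = "symmetric"
    noise_skew: float = 4.0
    sense_dy_jitter: float = 2.0
    dz_nominal: float = 65.0
    dz_jitter: float = 2.0
    fn_range: tuple[float, float] = (4.0, 5.0)
    ft_range_abs: tuple[float, float] = (2.5, 3.5)
    noncompliance_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def noise_sd(self, experiment: int) -> float:
        if isinstance(self.trial_noise_sd, dict):
            return float(self.trial_noise_sd[experiment])
        return float(self.trial_noise_sd)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for exp in EXPERIMENTS:
            if self.reps_per_condition.get(exp, 0) < 1:
                raise ValueError(f"reps_per_condition must be >= 1 for experiment {exp}")
        for exp in EXPERIMENTS:
            for cond in CONDITIONS:
                if (exp, cond) not in self.condition_effect:
                    raise ValueError(
                        f"condition_effect missing entry for ({exp}, {cond!r})"
                    )
        for name in ("subject_baseline_sd", "sense_dy_jitter", "dz_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        sds = (
            list(self.trial_noise_sd.values())
            if isinstance(self.trial_noise_sd, dict)
            else [self.trial_noise_sd]
        )
        if any(sd < 0 for sd in sds):
            raise ValueError("trial_noise_sd must be >= 0")
        if not 0.0 <= self.noncompliance_rate <= 1.0:
            raise ValueError("noncompliance_rate must be in [0, 1]")
        if self.noise_family not in NOISE_FAMILIES:
            raise ValueError(
                f"noise_family must be one of {NOISE_FAMILIES}, got {self.noise_family!r}"
            )
        for name in ("fn_range", "ft_range_abs"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} lower bound must be < upper bound")

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML/JSON-friendly keys for the (experiment, condition) mapping.
        d["condition_effect"] = {
            f"{exp}:{cond}": eff for (exp, cond), eff in self.condition_effect.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "condition_effect" in d:
            eff = {}
            for key, val in d["condition_effect"].items():
                exp_s, cond = key.split(":")
                eff[(int(exp_s), cond)] = float(val)
            base = default_condition_effects()
            base.update(eff)
            d["condition_effect"] = base
        if "reps_per_condition" in d:
            d["reps_per_condition"] = {
                int(k): int(v) for k, v in d["reps_per_condition"].items()
            }
        if isinstance(d.get("trial_noise_sd"), dict):
            d["trial_noise_sd"] = {
                int(k): float(v) for k, v in d["trial_noise_sd"].items()
            }
        for name in ("fn_range", "ft_range_abs"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# -- noise ---------------------------------------------------------------


def _draw_noise(
    rng: np.random.Generator, family: str, sd: float, skew: float, size: int
) -> np.ndarray:
    """Trial noise with median exactly zero and SD ``sd``."""
    if sd == 0.0:
        return np.zeros(size)
    if family == "symmetric":
        return rng.normal(0.0, sd, size)
    a = abs(skew) if family == "right-skewed" else -abs(skew)
    delta = a / np.hypot(1.0, a)
    omega = sd / np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
    draws = stats.skewnorm.rvs(a, scale=omega, size=size, random_state=rng)
    return draws - stats.skewnorm.ppf(0.5, a, scale=omega)


def _experiment_rng(seed: int, experiment: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(experiment,)))


# -- generation ----------------------------------------------------------


def generate_experiment(
    config: GeneratorConfig, experiment: int, seed: int | None = None
) -> pd.DataFrame:
    """Generate the full trial table of one experiment.

    Returns one row per (subject, condition, repetition), with sense-phase
    positions and forces drawn inside the compliance windows except for a
    ``noncompliance_rate`` fraction of trials that violate at least one
    window.  ``qc_pass`` is left unset (NA) for :mod:`fingercue.trial_qc` to
    fill.  Deterministic for a given ``(config, seed)``.
    """
    config.validate()
    experiment = validate_experiment(experiment)
    base_seed = config.seed if seed is None else seed
    rng = _experiment_rng(base_seed, experiment)

    n_sub = config.n_subjects
    reps = config.reps_per_condition[experiment]
    sd = config.noise_sd(experiment)
    fn_lo, fn_hi = config.fn_range
    ft_lo, ft_hi = config.ft_range_abs

    baselines = rng.normal(0.0, config.subject_baseline_sd, n_sub)

    rows: list[dict] = []
    for s in range(n_sub):
        subject = f"S{experiment}{s + 1:02d}"
        for cond in CONDITIONS:
            effect = config.condition_effect[(experiment, cond)]
            t_sign, i_sign = TANGENTIAL_SIGNS[cond]
            noise = _draw_noise(rng, config.noise_family, sd, config.noise_skew, reps)
            for rep in range(1, reps + 1):
                sense_dy = rng.uniform(-config.sense_dy_jitter, config.sense_dy_jitter)
                sense_dz = config.dz_nominal + rng.uniform(
                    -config.dz_jitter, config.dz_jitter
                )
                if cond == "NULL":
                    thumb_fn = index_fn = 0.0
                else:
                    thumb_fn = rng.uniform(fn_lo, fn_hi)
                    index_fn = rng.uniform(fn_lo, fn_hi)
                thumb_ft = t_sign * rng.uniform(ft_lo, ft_hi) if t_sign else 0.0
                index_ft = i_sign * rng.uniform(ft_lo, ft_hi) if i_sign else 0.0

                violate = rng.random() < config.noncompliance_rate
                if violate:
                    sense_dy, sense_dz, thumb_fn, thumb_ft = _inject_violation(
                        rng, cond, config, sense_dy, sense_dz, thumb_fn, thumb_ft
                    )

                rows.append(
                    {
                        "subject_id": subject,
                        "experiment": experiment,
                        "condition": cond,
                        "repetition": rep,
                        "sense_dy": sense_dy,
                        "hold_dy": sense_dy + baselines[s] + effect + noise[rep - 1],
                        "sense_dz": sense_dz,
                        "thumb_fn": thumb_fn,
                        "index_fn": index_fn,
                        "thumb_ft": thumb_ft,
                        "index_ft": index_ft,
                        "qc_pass": pd.NA,
                    }
                )
    table = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    table["qc_pass"] = table["qc_pass"].astype("boolean")
    return table


def _inject_violation(
    rng: np.random.Generator,
    cond: str,
    config: GeneratorConfig,
    sense_dy: float,
    sense_dz: float,
    thumb_fn: float,
    thumb_ft: float,
) -> tuple[float, float, float, float]:
    """Overwrite one sense-phase variable so the trial breaches a window."""
    dy_tol, dz_tol = 3.0, 3.0
    if cond == "NULL":
        # any force at all breaches the no-force requirement
        return sense_dy, sense_dz, rng.uniform(1.0, 3.0), thumb_ft
    kind = rng.integers(0, 4)
    if kind == 0:
        sense_dy = rng.choice([-1.0, 1.0]) * rng.uniform(dy_tol + 0.5, dy_tol + 3.0)
    elif kind == 1:
        sense_dz = config.dz_nominal + rng.choice([-1.0, 1.0]) * rng.uniform(
            dz_tol + 0.5, dz_tol + 3.0
        )
    elif kind == 2:
        lo, hi = config.fn_range
        thumb_fn = rng.choice([lo - 1.5, hi + 1.5]) + rng.uniform(0.0, 0.5)
    else:
        if cond == "FN_ONLY":
            thumb_ft = rng.uniform(1.0, 2.0)  # tangential force where none allowed
        else:
            sign = np.sign(thumb_ft) or 1.0
            thumb_ft = sign * (config.ft_range_abs[0] - rng.uniform(0.5, 1.5))
    return sense_dy, sense_dz, thumb_fn, thumb_ft


def generate_all(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Concatenated trial tables of all three experiments."""
    return pd.concat(
        [generate_experiment(config, exp, seed=seed) for exp in EXPERIMENTS],
        ignore_index=True,
    )


# -- CSV round-trip ------------------------------------------------------


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as UTF-8 CSV with the canonical column order."""
    _require_columns(table)
    out = table.loc[:, list(TRIAL_COLUMNS)]
    out.to_csv(path, index=False, encoding="utf-8")


def read_trials(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`.

    Raises on missing or extra columns, non-numeric values, or duplicated
    (subject, experiment, condition, repetition) keys.  Structural-invariant
    breaches (e.g. force in a Null trial) do not fail the read; use
    :func:`validate_trials` to surface them.
    """
    table = pd.read_csv(
        path,
        dtype={
            "subject_id": str,
            "condition": str,
            "qc_pass": "boolean",
        },
        encoding="utf-8",
        keep_default_na=False,  # "NULL" is a condition label, not missing data
        na_values=[""],
    )
    _require_columns(table)
    numeric = [
        c for c in TRIAL_COLUMNS if c not in ("subject_id", "condition", "qc_pass")
    ]
    if table.empty:
        for col in numeric:
            table[col] = table[col].astype(float)
        table["experiment"] = table["experiment"].astype(int)
        table["repetition"] = table["repetition"].astype(int)
        return table
    for col in numeric:
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise ValueError(f"column {col!r} contains non-numeric values")
    if table[numeric].isna().any().any():
        raise ValueError("numeric trial fields contain missing values")
    dup = table.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        keys = table.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
        raise ValueError(f"duplicate trial key {tuple(keys)}")
    table["experiment"] = table["experiment"].astype(int)
    table["repetition"] = table["repetition"].astype(int)
    return table


def validate_trials(table: pd.DataFrame) -> list[str]:
    """Return human-readable structural-invariant breaches (empty if none)."""
    breaches: list[str] = []
    forces = ["thumb_fn", "index_fn", "thumb_ft", "index_ft"]
    null_rows = table[table["condition"] == "NULL"]
    bad = null_rows[(null_rows[forces] != 0.0).any(axis=1)]
    for _, row in bad.iterrows():
        breaches.append(
            f"NULL trial {row['subject_id']}/exp{row['experiment']}"
            f"/rep{row['repetition']} has nonzero force"
        )
    fn_rows = table[table["condition"] == "FN_ONLY"]
    bad = fn_rows[(fn_rows[["thumb_ft", "index_ft"]] != 0.0).any(axis=1)]
    for _, row in bad.iterrows():
        breaches.append(
            f"FN_ONLY trial {row['subject_id']}/exp{row['experiment']}"
            f"/rep{row['repetition']} has nonzero tangential force"
        )
    unknown = set(table["condition"].unique()) - set(CONDITIONS)
    for cond in sorted(unknown):
        breaches.append(f"unknown condition label {cond!r}")
    if (table["repetition"] < 1).any():
        breaches.append("repetition indices must be >= 1")
    return breaches


def _require_columns(table: pd.DataFrame) -> None:
    have, want = list(table.columns), list(TRIAL_COLUMNS)
    missing = [c for c in want if c not in have]
    extra = [c for c in have if c not in want]
    if missing or extra:
        raise ValueError(
            f"trial table columns mismatch: missing={missing}, extra={extra}"
        )


def iter_cells(table: pd.DataFrame) -> Iterable[tuple[int, str, pd.DataFrame]]:
    """Yield (experiment, condition, sub-table) cells in canonical order."""
    for exp in EXPERIMENTS:
        sub_exp = table[table["experiment"] == exp]
        for cond in CONDITIONS:
            yield exp, cond, sub_exp[sub_exp["condition"] == cond]
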