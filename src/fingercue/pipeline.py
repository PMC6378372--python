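"""End-to-end orchestration: simulate -> qc -> errors -> stats -> cues -> strength.

Every stage writes a plain-text artifact (CSV for trial-level data, JSON for
results) into the output directory, and a manifest records the configuration,
seed, package version and SHA-256 checksum of each artifact so a run can be
reproduced and verified bit-for-bit (the manifest's timestamp is the only
non-deterministic field).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

import fingercue
from fingercue.conditions import EXPERIMENTS, OPPOSITE_CONDITIONS
from fingercue.cue_integration import decompose_condition, reliability_analysis
from fingercue.matching_error import baseline_correct, raw_errors, summarize_all
from fingercue.nonparam_stats import fatigue_correlation
from fingercue.strength_of_bias import bias_strength_all
from fingercue.synthetic_data import GeneratorConfig, generate_all, write_trials
from fingercue.trial_qc import ComplianceLimits, apply_qc, group_compliance_tests

log = logging.getLogger("fingercue")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", "utf-8")


def run_pipeline(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir: str | Path = "fingercue_run",
    limits: ComplianceLimits | None = None,
    drop_noncompliant: bool = True,
    n_boot: int = 2000,
    pairing_policy: str = "subject_rank_pairing",
) -> dict:
    """Run the whole analysis on synthetic data and write all artifacts.

    Returns the manifest dictionary.  Stage failures raise
    :class:`StageError` naming the stage.
    """
    config = config or GeneratorConfig()
    limits = limits or ComplianceLimits()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        stage("simulate")
        trials = generate_all(config, seed=seed)
        write_trials(trials, out / "trials.csv")
        artifacts["trials.csv"] = out / "trials.csv"
        log.info("simulate: %d trials", len(trials))
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc

    try:
        stage("qc")
        trials_qc = apply_qc(trials, limits, drop=drop_noncompliant)
        write_trials(trials_qc, out / "trials_qc.csv")
        artifacts["trials_qc.csv"] = out / "trials_qc.csv"
        group_checks = group_compliance_tests(trials_qc, limits)
        _write_json(out / "qc.json", [g.to_dict() for g in group_checks])
        artifacts["qc.json"] = out / "qc.json"
        log.info("qc: %d/%d trials kept", len(trials_qc), len(trials))
    except Exception as exc:  # noqa: BLE001
        raise StageError("qc", str(exc)) from exc

    try:
        stage("errors")
        errors = baseline_correct(raw_errors(trials_qc))
        errors.to_csv(out / "errors.csv", index=False)
        artifacts["errors.csv"] = out / "errors.csv"
    except Exception as exc:  # noqa: BLE001
        raise StageError("errors", str(exc)) from exc

    try:
        stage("summaries")
        summaries = summarize_all(errors, n_boot=n_boot, seed=seed)
        fatigue = [
            fatigue_correlation(errors, cond, exp).to_dict()
            for exp in (2, 3)
            for cond in OPPOSITE_CONDITIONS
        ]
        _write_json(
            out / "summary.json",
            {
                "table": [s.to_dict() for s in summaries],
                "fatigue": fatigue,
            },
        )
        artifacts["summary.json"] = out / "summary.json"
    except Exception as exc:  # noqa: BLE001
        raise StageError("summaries", str(exc)) from exc

    try:
        stage("cues")
        cues = analyze_cues(errors, pairing_policy=pairing_policy, seed=seed, n_boot=n_boot)
        _write_json(out / "cues.json", cues)
        artifacts["cues.json"] = out / "cues.json"
    except Exception as exc:  # noqa: BLE001
        raise StageError("cues", str(exc)) from exc

    try:
        stage("strength")
        strength = [b.to_dict() for b in bias_strength_all(errors)]
        _write_json(out / "strength.json", strength)
        artifacts["strength.json"] = out / "strength.json"
    except Exception as exc:  # noqa: BLE001
        raise StageError("strength", str(exc)) from exc

    manifest = {
        "config": config.to_dict(),
        "seed": int(seed),
        "version": fingercue.__version__,
        "pairing_policy": pairing_policy,
        "n_boot": int(n_boot),
        "drop_noncompliant": bool(drop_noncompliant),
        "limits": dataclasses.asdict(limits),
        "checksums": {name: _sha256(path) for name, path in artifacts.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


def analyze_cues(
    errors: pd.DataFrame,
    conditions=OPPOSITE_CONDITIONS,
    pairing_policy: str = "subject_rank_pairing",
    seed: int = 0,
    n_boot: int = 2000,
) -> list[dict]:
    """Cue decomposition + reliability triple per condition, as JSON rows."""
    rows = []
    for cond in conditions:
        samples = {}
        for exp in EXPERIMENTS:
            cell = errors[
                (errors["experiment"] == exp) & (errors["condition"] == cond)
            ]
            samples[exp] = cell["corrected_error"].to_numpy(float)
        deco = decompose_condition(
            samples[1],
            samples[2],
            samples[3],
            condition=cond,
            pairing_policy=pairing_policy,
            seed=seed,
            n_boot=n_boot,
        )
        rel = reliability_analysis(samples[1], samples[2], samples[3], condition=cond)
        rows.append({"decomposition": deco.to_dict(), "reliability": rel.to_dict()})
    return rows


def verify_manifest(out_dir: str | Path) -> list[str]:
    """Re-hash the artifacts of a finished run; return mismatched names."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text("utf-8"))
    bad = []
    for name, digest in manifest["checksums"].items():
        path = out / name
        if not path.exists() or _sha256(path) != digest:
            bad.append(name)
    return bad
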