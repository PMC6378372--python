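"""Markdown rendering of a finished pipeline run.

Reads the JSON artifacts of :func:`fingercue.pipeline.run_pipeline` and
renders the condition-summary table, cue weights, reliability classification
and strength-of-bias residuals.  With ``reference=True`` the published
benchmark values from the original study are shown in comparison columns;
otherwise no external numbers appear.
"""

from __future__ import annotations

import json
from pathlib import Path

from fingercue import reference
from fingercue.conditions import CONDITIONS, EXPERIMENTS


def _load(out_dir: Path, name: str):
    path = out_dir / name
    if not path.exists():
        raise FileNotFoundError(f"missing pipeline output {name!r} in {out_dir}")
    return json.loads(path.read_text("utf-8"))


def render_report(out_dir: str | Path, reference_mode: bool = False) -> str:
    """Render the run report; also writes ``report.md`` into ``out_dir``."""
    out = Path(out_dir)
    summary = _load(out, "summary.json")
    cues = _load(out, "cues.json")
    strength = _load(out, "strength.json")
    manifest = _load(out, "manifest.json")

    lines: list[str] = []
    lines.append("# Fingertip-distance matching: synthetic-run report")
    lines.append("")
    lines.append(f"Seed: {manifest['seed']}  |  package version {manifest['version']}")
    lines.append("")

    lines.append("## Condition medians (baseline-corrected, mm)")
    lines.append("")
    header = "| Experiment | Condition | n | median | 95% CI | z | p | r |"
    sep = "|---|---|---|---|---|---|---|---|"
    if reference_mode:
        header += " reference median | reference CI |"
        sep += "---|---|"
    lines.append(header)
    lines.append(sep)
    by_cell = {(row["experiment"], row["condition"]): row for row in summary["table"]}
    for exp in EXPERIMENTS:
        for cond in CONDITIONS:
            row = by_cell.get((exp, cond))
            if row is None:
                continue
            cells = (
                f"| {exp} | {cond} | {row['n']} | {row['median']:.2f} "
                f"| [{row['ci_low']:.2f}, {row['ci_high']:.2f}] "
                f"| {row['wilcoxon_z']:.2f} | {row['p_value']:.3g} "
                f"| {row['effect_r']:.2f} |"
            )
            if reference_mode:
                lo, med, hi = reference.TABLE1[(exp, cond)]
                cells += f" {med:.2f} | [{lo:.2f}, {hi:.2f}] |"
            lines.append(cells)
    lines.append("")

    lines.append("## Cue summation and contribution weights")
    lines.append("")
    for row in cues:
        deco, rel = row["decomposition"], row["reliability"]
        cond = deco["condition"]
        w = deco["weights"]
        alpha = "undefined" if not w["defined"] else f"{w['alpha_t']:.2f}"
        lines.append(f"### {cond}")
        lines.append("")
        lines.append(
            f"- single-cue medians: tactile {deco['dyer_t']:.2f} mm, "
            f"non-tactile {deco['dyer_nt']:.2f} mm; combined {deco['dyer_comb']:.2f} mm"
        )
        ref_alpha = (
            f" (reference: {reference.ALPHA_T[cond]:.2f})"
            if reference_mode and cond in reference.ALPHA_T
            else ""
        )
        lines.append(f"- tactile contribution alpha_t = {alpha}{ref_alpha}")
        test = deco["summation_test"]
        verdict = (
            "consistent with linear summation"
            if "consistent_with_linear_summation" in test["flags"]
            else "linear summation rejected"
        )
        summed_line = (
            f"- summed single-cue bias median {deco['summed_median']:.2f} mm "
            f"(CI [{deco['summed_ci'][0]:.2f}, {deco['summed_ci'][1]:.2f}]); "
            f"rank-sum vs combined: z = {test['z']:.2f}, p = {test['p_value']:.3g} "
            f"({verdict})"
        )
        if reference_mode and cond in reference.SUMMED_BIAS:
            lo, med, hi = reference.SUMMED_BIAS[cond]
            summed_line += f"; reference summed median {med:.1f} mm [{lo:.1f}, {hi:.1f}]"
        lines.append(summed_line)
        lines.append(
            f"- reliabilities (1/mm^2): combined {rel['r_exp1']:.4f}, "
            f"tactile {rel['r_exp2']:.4f}, non-tactile {rel['r_exp3']:.4f} "
            f"-> {rel['classification']}"
        )
        lines.append("")

    lines.append("## Strength of bias (signed residual exceedance probability)")
    lines.append("")
    header = "| Experiment | Condition | residual | pooled residual |"
    sep = "|---|---|---|---|"
    if reference_mode:
        header += " reference % |"
        sep += "---|"
    lines.append(header)
    lines.append(sep)
    for row in strength:
        cells = (
            f"| {row['experiment']} | {row['condition']} "
            f"| {row['residual']:.3f} | {row['pooled_residual']:.3f} |"
        )
        if reference_mode:
            ref = reference.STRENGTH_PCT.get((row["experiment"], row["condition"]))
            cells += f" {ref:.0f} |" if ref is not None else " - |"
        lines.append(cells)
    lines.append("")

    text = "\n".join(lines)
    (out / "report.md").write_text(text, "utf-8")
    return text
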