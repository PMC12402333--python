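"""Run-directory summaries in the style of per-cohort results tables."""

from __future__ import annotations

import json
import os

import pandas as pd


def summarize(run_dir: str) -> dict:
    """Aggregate a completed run directory into JSON + markdown summaries.

    Collects per-cohort AUC/OR (mean ± sample SD), calibration
    thresholds, repertoire and trend tests; missing stage outputs are
    flagged rather than fatal.  Idempotent: re-running on an unchanged
    directory reproduces the same files.
    """
    summary: dict = {"run_dir": os.path.basename(os.path.normpath(run_dir)), "flags": []}

    def _load(name):
        path = os.path.join(run_dir, name)
        if not os.path.exists(path):
            summary["flags"].append(f"missing {name}")
            return None
        with open(path) as fh:
            return json.load(fh)

    run_log = _load("run_log.json")
    if run_log:
        summary["stages"] = run_log.get("stages", [])

    eval_path = os.path.join(run_dir, "evaluation.tsv")
    if os.path.exists(eval_path):
        ev = pd.read_csv(eval_path, sep="\t")
        defined = ev[ev.get("or_defined", pd.Series(dtype=bool)) == True]  # noqa: E712
        summary["evaluation"] = {
            "n_cohorts": int(len(ev)),
            "auc_mean": float(ev["auc"].mean()),
            "auc_sd": float(ev["auc"].std(ddof=1)) if len(ev) > 1 else 0.0,
            "or_mean": float(defined["odds_ratio"].mean()) if len(defined) else None,
            "or_sd": float(defined["odds_ratio"].std(ddof=1)) if len(defined) > 1 else 0.0,
        }
    else:
        summary["flags"].append("missing evaluation.tsv")

    for name, key in (
        ("calibration.json", "calibration"),
        ("repertoire_tests.json", "repertoire"),
        ("dynamics.json", "dynamics"),
        ("survival.json", "survival"),
    ):
        data = _load(name)
        if data is not None:
            summary[key] = data

    with open(os.path.join(run_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_markdown(summary, os.path.join(run_dir, "summary.md"))
    return summary


def _write_markdown(summary: dict, path: str) -> None:
    lines = [f"# Run summary: {summary['run_dir']}", ""]
    ev = summary.get("evaluation")
    if ev:
        lines += [
            "## Validation performance",
            "",
            "| metric | value |",
            "|---|---|",
            f"| cohorts | {ev['n_cohorts']} |",
            f"| AUC (mean ± SD) | {ev['auc_mean']:.3f} ± {ev['auc_sd']:.3f} |",
        ]
        if ev.get("or_mean") is not None:
            lines.append(f"| OR (mean ± SD) | {ev['or_mean']:.2f} ± {ev['or_sd']:.2f} |")
        lines.append("")
    cal = summary.get("calibration")
    if cal:
        lines += ["## Fixed thresholds", ""]
        for modality, c in sorted(cal.items()):
            lines.append(
                f"- {modality}: threshold {c['threshold']:.3f} "
                f"(training OR {c['or_at_threshold']:.2f})"
            )
        lines.append("")
    if summary.get("flags"):
        lines += ["## Flags", ""] + [f"- {f}" for f in summary["flags"]] + [""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
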