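"""Config-driven end-to-end pipeline over synthetic cohorts.

``run_pipeline`` chains the stages the analysis consists of —
simulate, qc, signature, score, repertoire, dynamics, calibrate,
evaluate, survival, report — writing each stage's outputs as
TSV/JSON into a run directory and echoing every effective parameter
into a machine-readable run log.  Runs are deterministic: the same
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import build_profiles, elbow_select, fuzzy_cmeans, trend_per_type
from .errors import DependencyError
from .evaluate import calibrate_threshold, cross_cohort_eval, roc_auc
from .preprocess import (
    cell_type_fractions,
    filter_genes,
    normalize_lognorm,
    pseudobulk_mean,
    qc_filter_cells,
)
from .repertoire import (
    clonality,
    clone_sizes,
    compare_clonality,
    expansion_enrichment,
    unit_expansion_flags,
)
from .scoring import score_samples
from .signature import (
    SignatureSet,
    cross_cohort_filter,
    derive_markers,
    map_orthologs,
    markers_to_signature,
)
from .simulate import SimConfig, simulate_human_cohort, simulate_mouse_timecourse
from .survival import cox_fit, km_estimate, logrank_test, split_by_mean

log = logging.getLogger("libio")

ALL_STAGES = [
    "simulate", "qc", "signature", "score", "repertoire",
    "dynamics", "calibrate", "evaluate", "survival", "report",
]

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ALL_STAGES,
    "generator": {},            # SimConfig overrides
    "signature_time_point": "D9",
    "signature_fdr_max": 0.01,
    "signature_fc_min": 1.5,
    "n_cohorts_per_modality": 3,   # 1 training + 2 validation
    "n_samples_per_cohort": 40,
    "elbow_k_range": [2, 8],
    "write_inputs": False,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    return str(x)


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


class PipelineRun:
    """Holds stage products and writes them to the run directory."""

    def __init__(self, config: dict, outdir: str):
        self.config = config
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.state: dict = {}
        self.run_log: dict = {"version": __version__, "parameters": {}, "stages": []}

    def need(self, key: str, stage: str):
        if key not in self.state:
            raise DependencyError(
                f"stage {stage!r} requires {key!r}; run its producing stage first"
            )
        return self.state[key]

    def record(self, stage: str, **params) -> None:
        self.run_log["stages"].append(stage)
        self.run_log["parameters"][stage] = params


def run_pipeline(config: dict | str, outdir: str) -> PipelineRun:
    """Execute the configured stages; returns the populated run."""
    if isinstance(config, (str, os.PathLike)):
        config = load_config(config)
    else:
        merged = dict(DEFAULT_CONFIG)
        merged.update(config)
        config = merged
    run = PipelineRun(config, outdir)
    stages = config["stages"]
    for stage in stages:
        if stage not in ALL_STAGES:
            raise DependencyError(f"unknown stage {stage!r}")
        globals()[f"_stage_{stage}"](run)
    _dump_json(run.run_log, os.path.join(outdir, "run_log.json"))
    return run


def _sim_config(run: PipelineRun, offset: int = 0) -> SimConfig:
    kw = dict(run.config.get("generator", {}))
    kw["seed"] = int(run.config["seed"]) + offset
    return SimConfig(**kw)


def _stage_simulate(run: PipelineRun) -> None:
    cfg = _sim_config(run)
    counts, ann, clonotypes, manifest, truth = simulate_mouse_timecourse(cfg)
    run.state.update(
        mouse_counts=counts, mouse_ann=ann, mouse_clonotypes=clonotypes,
        mouse_manifest=manifest, truth=truth, sim_cfg=cfg,
    )
    _write_tsv(manifest, os.path.join(run.outdir, "mouse_manifest.tsv"))
    _dump_json(
        {k: truth[k] for k in ("planted_markers", "qc_fail_cells", "response_labels")},
        os.path.join(run.outdir, "ground_truth.json"),
    )
    if run.config.get("write_inputs"):
        from .matrix import write_mtx_triplet
        from .tables import write_annotations, write_clonotypes

        write_mtx_triplet(counts, os.path.join(run.outdir, "mouse_counts"))
        write_annotations(ann, os.path.join(run.outdir, "mouse_annotations.tsv"))
        write_clonotypes(clonotypes, os.path.join(run.outdir, "mouse_clonotypes.tsv"))
    run.record("simulate", **dataclasses.asdict(cfg))


def _stage_qc(run: PipelineRun) -> None:
    counts = run.need("mouse_counts", "qc")
    ann = run.need("mouse_ann", "qc")
    filtered, ann_f, report = qc_filter_cells(counts, ann)
    filtered = filter_genes(filtered)
    lognorm = normalize_lognorm(filtered)
    fractions = cell_type_fractions(ann_f, by=["sample_id"])
    run.state.update(mouse_lognorm=lognorm, mouse_ann_qc=ann_f, fractions=fractions)
    _dump_json({k: v for k, v in report.items() if k != "removed_cell_ids"},
               os.path.join(run.outdir, "qc_report.json"))
    _write_tsv(fractions.reset_index(), os.path.join(run.outdir, "cell_type_fractions.tsv"))
    run.record("qc", max_mito=0.25, min_genes=500, min_cells=3, scale=1e4)


def _identity_ortholog_map(genes) -> pd.DataFrame:
    return pd.DataFrame({"mouse": list(genes), "human": [f"h{g}" for g in genes]})


def _stage_signature(run: PipelineRun) -> None:
    lognorm = run.need("mouse_lognorm", "signature")
    ann = run.need("mouse_ann_qc", "signature")
    tp = run.config["signature_time_point"]
    fdr_max = run.config["signature_fdr_max"]
    fc_min = run.config["signature_fc_min"]
    signatures = {}
    for name, target in (("Tem", "Tem"), ("Bcell", "B")):
        table = derive_markers(lognorm, ann, target, time_point=tp,
                               fdr_max=fdr_max, fc_min=fc_min)
        _write_tsv(table, os.path.join(run.outdir, f"markers_{name}.tsv"))
        signatures[name] = markers_to_signature(
            table, name, time_point=tp, fdr_max=fdr_max, fc_min=fc_min, epsilon=1.0
        )
    omap = _identity_ortholog_map(lognorm.gene_ids)
    signatures = {k: map_orthologs(s, omap) for k, s in signatures.items()}
    run.state["signatures_premap"] = signatures
    run.record("signature", time_point=tp, fdr_max=fdr_max, fc_min=fc_min)


def _stage_score(run: PipelineRun) -> None:
    sigs = run.need("signatures_premap", "score")
    n_cohorts = int(run.config["n_cohorts_per_modality"])
    n_samples = int(run.config["n_samples_per_cohort"])
    cohorts = {}
    offset = 1
    for modality in ("sc", "bulk"):
        for i in range(n_cohorts):
            cfg = _sim_config(run, offset=offset)
            offset += 1
            name = f"{modality}_cohort{i}"
            expr, manifest, truth = simulate_human_cohort(
                cfg, modality, n_samples, sigs["Tem"], sigs["Bcell"], cohort_name=name
            )
            cohorts[name] = {"expr": expr, "manifest": manifest, "truth": truth,
                             "modality": modality, "role": "training" if i == 0 else "validation"}
    # cross-cohort expression filter on the validation cohorts
    sig_tem = cross_cohort_filter(sigs["Tem"], [c["expr"] for c in cohorts.values()])
    sig_b = cross_cohort_filter(sigs["Bcell"], [c["expr"] for c in cohorts.values()])
    _dump_json(
        {
            "Tem": {"genes": list(sig_tem.genes), "provenance": sig_tem.provenance},
            "Bcell": {"genes": list(sig_b.genes), "provenance": sig_b.provenance},
        },
        os.path.join(run.outdir, "signatures.json"),
    )
    all_scores = []
    for name, c in cohorts.items():
        scores = score_samples(c["expr"], sig_tem, sig_b, modality=c["modality"])
        scores.insert(0, "cohort", name)
        c["scores"] = scores
        all_scores.append(scores)
    run.state.update(cohorts=cohorts, signatures={"Tem": sig_tem, "Bcell": sig_b})
    _write_tsv(pd.concat(all_scores, ignore_index=True),
               os.path.join(run.outdir, "scores.tsv"))
    run.record("score", n_cohorts_per_modality=n_cohorts,
               n_samples_per_cohort=n_samples, ssgsea_alpha=0.25, normalize="within-cohort")


def _stage_repertoire(run: PipelineRun) -> None:
    clonotypes = run.need("mouse_clonotypes", "repertoire")
    manifest = run.need("mouse_manifest", "repertoire")
    sizes = clone_sizes(clonotypes)
    clon = clonality(sizes)
    _write_tsv(clon, os.path.join(run.outdir, "clonality.tsv"))
    tests = {}
    for tp in dict.fromkeys(manifest["time_point"]):
        res = compare_clonality(clon, manifest, time_point=tp)
        tests[tp] = {"p": res.p, "u": res.u, "method": res.method, "n_ties": res.n_ties}
    # expansion in T_em vs other CD8 T cells
    tcells = clonotypes[clonotypes["cell_type"].isin(["Tem", "CD8T_naive"])]
    flags = unit_expansion_flags(tcells)
    table, fisher = expansion_enrichment(flags, tcells["cell_type"] == "Tem")
    _dump_json(
        {
            "clonality_responder_vs_non": tests,
            "tem_expansion_enrichment": {
                "table": dataclasses.asdict(table),
                "p": fisher.p,
                "or_sample": fisher.or_sample,
                "or_cmle": fisher.or_cmle,
            },
        },
        os.path.join(run.outdir, "repertoire_tests.json"),
    )
    run.state["clonality"] = clon
    run.record("repertoire", min_expanded=2, simpson="dominance", chain_scope="TRB")


def _stage_dynamics(run: PipelineRun) -> None:
    lognorm = run.need("mouse_lognorm", "dynamics")
    ann = run.need("mouse_ann_qc", "dynamics")
    manifest = run.need("mouse_manifest", "dynamics")
    pseudobulk = pseudobulk_mean(lognorm, ann)
    profiles = build_profiles(pseudobulk, manifest, group="responder")
    k_lo, k_hi = run.config["elbow_k_range"]
    seed = int(run.config["seed"])
    k_star, curve = elbow_select(profiles, range(k_lo, k_hi + 1), seed=seed)
    fcm = fuzzy_cmeans(profiles, k_star, seed=seed)
    _write_tsv(curve, os.path.join(run.outdir, "elbow_objective.tsv"))
    members = pd.DataFrame(
        {
            "gene": profiles.index,
            "cluster": fcm.memberships.argmax(axis=1),
            "max_membership": fcm.memberships.max(axis=1),
        }
    )
    _write_tsv(members, os.path.join(run.outdir, "profile_clusters.tsv"))
    # abundance trends in responders
    resp_samples = manifest.loc[manifest["response_label"] == "responder", "sample_id"]
    ann_resp = ann[ann["sample_id"].isin(set(resp_samples))]
    fractions = cell_type_fractions(ann_resp, by=["subject_id", "time_point"])
    trend = trend_per_type(fractions, "Tem", "increasing",
                           time_order=list(dict.fromkeys(manifest["time_point"])))
    _dump_json(
        {"k_star": k_star, "fcm_converged": fcm.converged,
         "tem_trend": dataclasses.asdict(trend)},
        os.path.join(run.outdir, "dynamics.json"),
    )
    run.state["tem_trend"] = trend
    run.record("dynamics", fuzzifier=2.0, tol=1e-6, max_iter=500,
               k_range=[k_lo, k_hi], trend_test="mann_kendall")


def _stage_calibrate(run: PipelineRun) -> None:
    cohorts = run.need("cohorts", "calibrate")
    calibrations = {}
    for modality in ("sc", "bulk"):
        training = [c for c in cohorts.values()
                    if c["modality"] == modality and c["role"] == "training"]
        scores = pd.concat([c["scores"] for c in training], ignore_index=True)
        manifest = pd.concat([c["manifest"] for c in training], ignore_index=True)
        merged = scores.merge(manifest[["sample_id", "response_label"]], on="sample_id")
        calib = calibrate_threshold(
            merged["libio"], merged["response_label"] == "responder",
            modality_or_cancer=modality,
        )
        calibrations[modality] = calib
    run.state["calibrations"] = calibrations
    _dump_json({m: dataclasses.asdict(c) for m, c in calibrations.items()},
               os.path.join(run.outdir, "calibration.json"))
    run.record("calibrate", grid="score midpoints", rule="max odds ratio",
               predicted_positive="score >= threshold")


def _stage_evaluate(run: PipelineRun) -> None:
    cohorts = run.need("cohorts", "evaluate")
    calibrations = run.need("calibrations", "evaluate")
    results = []
    for modality in ("sc", "bulk"):
        validation = [
            (name, c["scores"], c["manifest"])
            for name, c in cohorts.items()
            if c["modality"] == modality and c["role"] == "validation"
        ]
        table = cross_cohort_eval(calibrations[modality], validation)
        table.insert(0, "modality", modality)
        results.append(table)
    out = pd.concat(results, ignore_index=True)
    run.state["evaluation"] = out
    _write_tsv(out, os.path.join(run.outdir, "evaluation.tsv"))
    metrics = {
        "per_cohort": out.to_dict(orient="records"),
        "auc_mean": float(out["auc"].mean()),
        "or_mean": float(out.loc[out["or_defined"], "odds_ratio"].mean()),
        "or_sd": float(out.loc[out["or_defined"], "odds_ratio"].std(ddof=1)),
    }
    _dump_json(metrics, os.path.join(run.outdir, "metrics.json"))
    run.record("evaluate", auc="pair-counting", or_zero_cells="haldane")


def _stage_survival(run: PipelineRun) -> None:
    cohorts = run.need("cohorts", "survival")
    rows = {}
    for name, c in cohorts.items():
        if c["role"] != "validation" or c["modality"] != "bulk":
            continue
        merged = c["scores"].merge(c["manifest"], on="sample_id")
        records = merged.rename(columns={"survival_time": "time", "libio": "score"})
        groups = split_by_mean(records)
        chi2, p = logrank_test(records, groups)
        km_high = km_estimate(records[groups == "high"])
        km_low = km_estimate(records[groups == "low"])
        fit = cox_fit(records, covariates=("score", "age", "sex"))
        _write_tsv(km_high.assign(group="high").merge(
            km_low.assign(group="low"), how="outer"),
            os.path.join(run.outdir, f"km_{name}.tsv"))
        rows[name] = {
            "logrank_chi2": chi2,
            "logrank_p": p,
            "cox": {
                "covariates": fit.covariates,
                "coef": fit.coef.tolist(),
                "HR": fit.hazard_ratios.tolist(),
                "se": fit.se.tolist(),
                "wald_p": fit.p.tolist(),
                "converged": fit.converged,
                "flags": fit.flags,
            },
        }
    run.state["survival"] = rows
    _dump_json(rows, os.path.join(run.outdir, "survival.json"))
    run.record("survival", ties="efron", dichotomization="mean", covariates=["score", "age", "sex"])


def _stage_report(run: PipelineRun) -> None:
    from .report import summarize

    run.record("report")
    _dump_json(run.run_log, os.path.join(run.outdir, "run_log.json"))
    summarize(run.outdir)
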