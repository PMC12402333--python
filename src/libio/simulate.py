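"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators emulate the study design end to end:

``simulate_mouse_timecourse``
    A blood single-cell time course: mice sampled at a pre-treatment
    day and three on-treatment days (D4/D9/D17/D24), responders showing
    a monotone rise in effector memory CD8 T cell (T_em) abundance and
    clonal expansion concentrated at the early on-treatment day (D9),
    non-responders a modest early rise followed by a decline.  Counts
    are negative-binomial with log-normal gene baselines and planted
    cell-type marker elevation; clonotypes follow a Dirichlet-
    multinomial whose concentration controls expansion; a configurable
    fraction of cells is planted to fail QC.

``simulate_human_cohort``
    A validation cohort: log-normal TPM (bulk) or synthetic cells
    aggregated to pseudobulk (single-cell), with responder samples
    receiving a standardized shift on signature genes, a constant
    additive offset on signature-gene baselines in single-cell
    cohorts (so their scores run systematically higher than bulk), and
    exponential survival times whose hazard scales with the latent
    score.

Every planted structure is returned as machine-readable ground truth.
All randomness flows through one ``numpy`` generator seeded from the
config, so identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matrix import ExpressionMatrix
from .preprocess import normalize_lognorm, pseudobulk_mean
from .signature import SignatureSet

MOUSE_TIME_POINTS = ("D4", "D9", "D17", "D24")
_NT = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Group sizes and the time grid follow the mouse study design
    (7 responders / 9 non-responders, days 4/9/17/24); effect sizes
    (``tem_trend_effect``, ``expansion_concentration``,
    ``signature_effect_d``, ``true_beta``) are the planted signals the
    pipeline is expected to detect.
    """

    seed: int
    n_responders: int = 7
    n_nonresponders: int = 9
    time_points: tuple = MOUSE_TIME_POINTS
    n_genes: int = 300
    n_marker_genes_per_type: int = 15
    marker_fold: float = 8.0
    cell_types: dict = field(default_factory=lambda: {
        "Tem": 0.05, "CD8T_naive": 0.15, "CD4T": 0.20,
        "B": 0.25, "NK": 0.10, "Neutrophil": 0.25,
    })
    # per-time additive increments to the T_em proportion
    tem_trend_effect: tuple = (0.00, 0.05, 0.10, 0.15)
    tem_trend_nonresponder: tuple = (0.00, 0.02, -0.02, -0.01)
    # Dirichlet concentration of the clone-frequency vector per
    # group x time; lower concentration => stronger clonal expansion
    expansion_concentration: dict = field(default_factory=lambda: {
        "responder": {"D4": 40.0, "D9": 3.0, "D17": 15.0, "D24": 25.0},
        "non_responder": {"D4": 40.0, "D9": 40.0, "D17": 40.0, "D24": 40.0},
    })
    n_cells_per_sample: int = 400
    n_clones_per_subject: int = 150
    # T_em cells draw clones size-biased (prob ∝ freq^bias), so expanded
    # clones concentrate in the effector memory compartment
    tem_clone_bias: float = 2.0
    qc_fail_fraction: float = 0.10
    nb_dispersion: float = 0.5
    # human-cohort knobs
    signature_effect_d: float = 1.5
    modality_offset: float = 0.75
    censoring_rate: float = 0.30
    true_beta: float = 0.7

    def __post_init__(self):
        props = np.array(list(self.cell_types.values()))
        if not np.isclose(props.sum(), 1.0) or (props <= 0).any():
            raise ConfigError("cell-type proportions must be a positive simplex")
        if len(self.tem_trend_effect) != len(self.time_points):
            raise ConfigError("tem_trend_effect must have one entry per time point")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ConfigError("qc_fail_fraction must be in [0, 1)")


def _random_cdr3(rng, length: int = 15) -> str:
    return "".join(rng.choice(_NT, size=length))


def _nb_counts(rng, mean, dispersion):
    """Negative binomial with mean `mean` and NB2 dispersion (var = m + m^2*disp)."""
    mean = np.clip(mean, 1e-9, None)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _type_proportions(cfg: SimConfig, response: str, tp_index: int) -> np.ndarray:
    props = np.array(list(cfg.cell_types.values()), dtype=float)
    names = list(cfg.cell_types)
    trend = (cfg.tem_trend_effect if response == "responder"
             else cfg.tem_trend_nonresponder)
    i_tem = names.index("Tem")
    delta = trend[tp_index]
    props = props.copy()
    new_tem = np.clip(props[i_tem] + delta, 1e-3, 0.9)
    scale = (1.0 - new_tem) / (1.0 - props[i_tem])
    props *= scale
    props[i_tem] = new_tem
    return props / props.sum()


def simulate_mouse_timecourse(cfg: SimConfig):
    """Generate (counts, annotations, clonotypes, manifest, truth)."""
    rng = np.random.default_rng(cfg.seed)
    type_names = list(cfg.cell_types)
    n_types = len(type_names)

    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    baselines = np.exp(rng.normal(0.0, 1.0, size=cfg.n_genes))
    # plant markers: disjoint blocks of genes elevated in one type only
    markers = {}
    cursor = 0
    for t in type_names:
        markers[t] = gene_ids[cursor:cursor + cfg.n_marker_genes_per_type]
        cursor += cfg.n_marker_genes_per_type
    type_means = np.tile(baselines, (n_types, 1))
    for ti, t in enumerate(type_names):
        idx = [gene_ids.index(g) for g in markers[t]]
        type_means[ti, idx] *= cfg.marker_fold

    subjects = [("R%d" % (i + 1), "responder") for i in range(cfg.n_responders)] + [
        ("N%d" % (i + 1), "non_responder") for i in range(cfg.n_nonresponders)
    ]
    # per-subject clone pool with fixed CDR3 sequences
    clone_pool = {
        subj: [_random_cdr3(rng) for _ in range(cfg.n_clones_per_subject)]
        for subj, _ in subjects
    }

    cells, ann_rows, clono_rows, manifest_rows = [], [], [], []
    qc_fail_ids, expanded_truth = [], {}
    for subj, response in subjects:
        for tp_i, tp in enumerate(cfg.time_points):
            sample = f"{subj}_{tp}"
            props = _type_proportions(cfg, response, tp_i)
            n_per_type = rng.multinomial(cfg.n_cells_per_sample, props)
            conc = cfg.expansion_concentration[response][tp]
            clone_freqs = rng.dirichlet(
                np.full(cfg.n_clones_per_subject, conc / cfg.n_clones_per_subject)
            )
            tem_freqs = clone_freqs**cfg.tem_clone_bias
            tem_freqs /= tem_freqs.sum()
            sample_clone_counts = {}
            cell_no = 0
            for ti, t in enumerate(type_names):
                for _ in range(n_per_type[ti]):
                    cid = f"{sample}_c{cell_no:04d}"
                    cell_no += 1
                    counts = _nb_counts(rng, type_means[ti], cfg.nb_dispersion)
                    if counts.sum() == 0:
                        counts[rng.integers(cfg.n_genes)] = 1
                    cells.append((cid, counts))
                    fails = rng.random() < cfg.qc_fail_fraction
                    if fails:
                        qc_fail_ids.append(cid)
                        if rng.random() < 0.5:
                            mito, ngenes = rng.uniform(0.26, 0.60), int(rng.integers(600, 3000))
                        else:
                            mito, ngenes = rng.uniform(0.0, 0.20), int(rng.integers(100, 500))
                    else:
                        mito, ngenes = rng.uniform(0.0, 0.20), int(rng.integers(600, 3000))
                    ann_rows.append((cid, sample, subj, tp, t, mito, ngenes))
                    if t in ("Tem", "CD8T_naive", "CD4T"):
                        p = tem_freqs if t == "Tem" else clone_freqs
                        ci = rng.choice(cfg.n_clones_per_subject, p=p)
                        key = clone_pool[subj][ci]
                        sample_clone_counts[key] = sample_clone_counts.get(key, 0) + 1
                        clono_rows.append((cid, sample, subj, "TRB", key, t))
            expanded_truth[sample] = sorted(
                f"TRB:{k}" for k, v in sample_clone_counts.items() if v >= 2
            )
            manifest_rows.append(
                {
                    "sample_id": sample,
                    "subject_id": subj,
                    "response_label": response,
                    "modality": "sc",
                    "timing": "pre" if tp_i == 0 else "post",
                    "cancer_type": "HNSCC_mouse",
                    "time_point": tp,
                }
            )

    values = pd.DataFrame(
        np.column_stack([c for _, c in cells]).astype(float),
        index=gene_ids,
        columns=[cid for cid, _ in cells],
    )
    counts = ExpressionMatrix(values, "counts")
    ann = pd.DataFrame(
        ann_rows,
        columns=["cell_id", "sample_id", "subject_id", "time_point",
                 "cell_type", "mito_fraction", "n_genes_detected"],
    )
    clonotypes = pd.DataFrame(
        clono_rows,
        columns=["unit_id", "sample_id", "subject_id", "chain", "cdr3_nt", "cell_type"],
    )
    clonotypes["clonotype_key"] = "TRB:" + clonotypes["cdr3_nt"]
    manifest = pd.DataFrame(manifest_rows)
    truth = {
        "planted_markers": markers,
        "qc_fail_cells": sorted(qc_fail_ids),
        "expanded_clones": expanded_truth,
        "response_labels": {s: r for s, r in zip(manifest["sample_id"], manifest["response_label"])},
        "config": asdict(cfg),
    }
    return counts, ann, clonotypes, manifest, truth


# ---------------------------------------------------------------------------
# human validation cohorts


def simulate_human_cohort(
    cfg: SimConfig,
    modality: str,
    n_samples: int,
    tem: SignatureSet,
    b: SignatureSet,
    n_background_genes: int = 200,
    cohort_name: str = "cohort",
    cells_per_sample: int = 30,
):
    """Generate (expression, manifest, truth) for one validation cohort.

    Half the samples are responders; their signature genes are shifted
    by ``cfg.signature_effect_d`` standard deviations of the log-scale
    noise.  Single-cell cohorts add ``cfg.modality_offset`` to the
    signature-gene baseline and are delivered as pseudobulk.
    """
    if n_samples < 4:
        raise ConfigError("need at least 4 samples")
    if modality not in ("bulk", "sc"):
        raise ConfigError(f"unknown modality {modality!r}")
    rng = np.random.default_rng(cfg.seed)
    sig_genes = list(dict.fromkeys([*tem.genes, *b.genes]))
    genes = sig_genes + [f"BG{i:04d}" for i in range(n_background_genes)]
    n_genes = len(genes)
    is_sig = np.array([g in set(sig_genes) for g in genes])

    n_resp = n_samples // 2
    labels = np.array(["responder"] * n_resp + ["non_responder"] * (n_samples - n_resp))
    sample_ids = [f"{cohort_name}_{modality}_s{i:03d}" for i in range(n_samples)]

    base = rng.normal(3.0, 1.0, size=n_genes)  # log2 TPM baselines
    if modality == "sc":
        base = base + np.where(is_sig, cfg.modality_offset, 0.0)
    sigma = 1.0
    # latent per-sample responsiveness drives both expression and hazard
    latent = rng.normal(0.0, 1.0, size=n_samples) + np.where(
        labels == "responder", cfg.signature_effect_d, 0.0
    )
    shift = np.where(labels == "responder", cfg.signature_effect_d, 0.0)
    log_expr = (
        base[:, None]
        + np.where(is_sig, 1.0, 0.0)[:, None] * shift[None, :] * sigma
        + rng.normal(0.0, sigma, size=(n_genes, n_samples))
    )
    if modality == "bulk":
        tpm = np.power(2.0, log_expr)
        tpm = tpm / tpm.sum(axis=0) * 1e6
        expr = ExpressionMatrix(
            pd.DataFrame(tpm, index=genes, columns=sample_ids), "tpm"
        )
    else:
        # synthesize cells around each sample's profile, then pseudobulk
        cell_cols, cell_ids, cell_samples = [], [], []
        mean_per_sample = np.power(2.0, log_expr) / 50.0
        for j, s in enumerate(sample_ids):
            for c in range(cells_per_sample):
                counts = _nb_counts(rng, mean_per_sample[:, j], cfg.nb_dispersion)
                if counts.sum() == 0:
                    counts[rng.integers(n_genes)] = 1
                cell_cols.append(counts)
                cell_ids.append(f"{s}_c{c:03d}")
                cell_samples.append(s)
        counts = ExpressionMatrix(
            pd.DataFrame(
                np.column_stack(cell_cols).astype(float), index=genes, columns=cell_ids
            ),
            "counts",
        )
        cell_ann = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "sample_id": cell_samples,
                "subject_id": cell_samples,
                "time_point": "pre",
                "cell_type": "PBMC",
                "mito_fraction": 0.05,
                "n_genes_detected": 1000,
            }
        )
        lognorm = normalize_lognorm(counts)
        expr = pseudobulk_mean(lognorm, cell_ann)
        expr = expr.subset_obs(sample_ids)  # restore cohort order

    # survival: exponential hazard scaling with the latent score
    hazard = 0.05 * np.exp(cfg.true_beta * (latent - latent.mean()) / max(latent.std(), 1e-9))
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        # independent exponential censoring matched to the target rate
        c_scale = np.mean(1.0 / hazard) * (1 - cfg.censoring_rate) / cfg.censoring_rate
        t_cens = rng.exponential(c_scale, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    manifest = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": sample_ids,
            "response_label": labels,
            "modality": modality,
            "timing": "pre",
            "cancer_type": "HNSCC",
            "survival_time": time,
            "event": event,
            "age": rng.normal(60.0, 10.0, size=n_samples).round(1),
            "sex": rng.integers(0, 2, size=n_samples),
        }
    )
    truth = {
        "latent_scores": dict(zip(sample_ids, latent)),
        "signature_genes": sig_genes,
        "true_beta": cfg.true_beta,
        "effect_d": cfg.signature_effect_d,
    }
    return expr, manifest, truth


def simulate_clonotype_cohort(
    cfg: SimConfig,
    n_responders: int | None = None,
    n_nonresponders: int | None = None,
    time_point: str = "D9",
    n_units_per_sample: int = 100,
    null: bool = False,
):
    """Clonotype tables only, one sample per subject at one time point.

    Uses the same Dirichlet-multinomial clone model as the full time
    course; ``null=True`` gives both groups the non-responder
    concentration (no planted expansion difference).  Returns
    (records, manifest).
    """
    rng = np.random.default_rng(cfg.seed)
    n_r = cfg.n_responders if n_responders is None else n_responders
    n_n = cfg.n_nonresponders if n_nonresponders is None else n_nonresponders
    subjects = [("R%d" % (i + 1), "responder") for i in range(n_r)] + [
        ("N%d" % (i + 1), "non_responder") for i in range(n_n)
    ]
    rows, manifest_rows = [], []
    for subj, response in subjects:
        conc_group = "non_responder" if null else response
        conc = cfg.expansion_concentration[conc_group][time_point]
        freqs = rng.dirichlet(
            np.full(cfg.n_clones_per_subject, conc / cfg.n_clones_per_subject)
        )
        counts = rng.multinomial(n_units_per_sample, freqs)
        sample = f"{subj}_{time_point}"
        unit = 0
        for ci in np.nonzero(counts)[0]:
            key = f"clone{ci:04d}"
            for _ in range(counts[ci]):
                rows.append((f"{sample}_u{unit}", sample, subj, "TRB", key, "T"))
                unit += 1
        manifest_rows.append(
            {
                "sample_id": sample, "subject_id": subj, "response_label": response,
                "modality": "sc", "timing": "post", "time_point": time_point,
            }
        )
    records = pd.DataFrame(
        rows, columns=["unit_id", "sample_id", "subject_id", "chain", "cdr3_nt", "cell_type"]
    )
    records["clonotype_key"] = "TRB:" + records["cdr3_nt"]
    return records, pd.DataFrame(manifest_rows)


def simulate_abundance(cfg: SimConfig, null: bool = False) -> pd.DataFrame:
    """Cell-type fraction table only (subject x time multinomial draws).

    Responders follow the configured T_em trend unless ``null``, in
    which case both groups use flat baseline proportions.  Returns a
    fraction table indexed by (subject_id, time_point) with one column
    per cell type plus a ``response_label`` index of truth in attrs.
    """
    rng = np.random.default_rng(cfg.seed)
    type_names = list(cfg.cell_types)
    rows, index = [], []
    labels = {}
    subjects = [("R%d" % (i + 1), "responder") for i in range(cfg.n_responders)] + [
        ("N%d" % (i + 1), "non_responder") for i in range(cfg.n_nonresponders)
    ]
    for subj, response in subjects:
        labels[subj] = response
        for tp_i, tp in enumerate(cfg.time_points):
            if null:
                props = np.array(list(cfg.cell_types.values()))
            else:
                props = _type_proportions(cfg, response, tp_i)
            counts = rng.multinomial(cfg.n_cells_per_sample, props)
            rows.append(counts / counts.sum())
            index.append((subj, tp))
    out = pd.DataFrame(
        rows,
        columns=type_names,
        index=pd.MultiIndex.from_tuples(index, names=["subject_id", "time_point"]),
    )
    out.attrs["response_labels"] = labels
    return out


def simulate_survival(n: int, beta: float, seed: int, censoring_rate: float = 0.0) -> pd.DataFrame:
    """Minimal survival benchmark: exponential hazard on a standard-normal score."""
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n)
    age = rng.normal(60, 10, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    hazard = 0.1 * np.exp(beta * score)
    t = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        c = rng.exponential(np.mean(1 / hazard) * (1 - censoring_rate) / censoring_rate, size=n)
    else:
        c = np.full(n, np.inf)
    return pd.DataFrame(
        {
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "score": score,
            "age": age,
            "sex": sex,
        }
    )
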