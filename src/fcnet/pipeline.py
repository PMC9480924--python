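"""End-to-end orchestration: time series -> networks -> metrics -> inference.

``run_pipeline`` executes the stages in order (connectivity, edge
residualisation, rectification, sparsity selection, thresholding, graph
metrics, group statistics, brain-behavior correlation), persists every
intermediate as delimited text under the configured output directory, and
writes a run manifest (seed, config hash, stage log) so any table can be
regenerated bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from . import network as net
from .behavior import run_brain_behavior
from .config import PipelineConfig
from .metrics import NODAL_METRIC_NAMES, nodal_metrics
from .stats import GroupComparisonReport, run_group_comparison
from .synthetic import CNT_SUBTESTS

__all__ = ["PipelineResult", "run_pipeline", "compute_cohort_metrics", "write_report"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    subjects: pd.DataFrame
    selected_sparsity: float
    min_sparsity: float
    nodal_values: dict[str, np.ndarray]      # metric -> (n_subjects x n_nodes)
    eglob: np.ndarray                        # per subject
    comparison: GroupComparisonReport
    auc_comparison: GroupComparisonReport | None = None
    correlations: pd.DataFrame | None = None
    zdiff: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def compute_cohort_metrics(
    rectified: list[net.ConnectivityMatrix],
    sparsity: float,
    eloc_variant: str = "subgraph",
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Threshold every subject at one sparsity and compute all measures.

    Returns (metric name -> subjects x nodes matrix, per-subject Eglob).
    """
    per_metric = {m: [] for m in NODAL_METRIC_NAMES}
    eglob = []
    for mat in rectified:
        netw = net.threshold_to_sparsity(mat, sparsity)
        nm = nodal_metrics(netw.weights, eloc_variant=eloc_variant)
        for m, v in nm.as_dict().items():
            per_metric[m].append(v)
        eglob.append(nm.eglob)
    return {m: np.stack(v) for m, v in per_metric.items()}, np.asarray(eglob)


def _auc_values(
    rectified: list[net.ConnectivityMatrix],
    grid: list[float],
    eloc_variant: str,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-subject AUC over the sparsity grid for every measure."""
    grid_arr = np.asarray(grid, dtype=float)
    per_level = [compute_cohort_metrics(rectified, s, eloc_variant) for s in grid]
    auc_nodal = {}
    for m in NODAL_METRIC_NAMES:
        stack = np.stack([lvl[0][m] for lvl in per_level])  # (grid, subj, node)
        auc_nodal[m] = np.trapezoid(stack, grid_arr, axis=0)
    eg = np.stack([lvl[1] for lvl in per_level])  # (grid, subj)
    auc_eglob = np.trapezoid(eg, grid_arr, axis=0)
    return auc_nodal, auc_eglob


def _split(values: np.ndarray, is_case: np.ndarray):
    return values[is_case], values[~is_case]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list[str] = []

    node_table = fio.load_node_table(config.node_table)
    subjects = fio.read_subject_table(config.subject_table)
    series = fio.read_timeseries_dir(config.timeseries_dir, node_table)
    sids = [ts.subject_id for ts in series]
    if sids != list(subjects["subject_id"]):
        raise ValueError("time-series files and subject table disagree on subjects")
    stage_log.append(f"loaded {len(series)} subjects, {len(node_table)} nodes")

    def _fail(stage, sid, err):
        raise RuntimeError(f"stage {stage!r} failed for subject {sid}: {err}") from err

    raw = []
    for ts in series:
        try:
            raw.append(net.pearson_connectivity(ts))
        except Exception as err:  # pragma: no cover - error path
            _fail("connectivity", ts.subject_id, err)
    stage_log.append("connectivity done")

    if config.residualize_before_rectify:
        resid = net.residualize_edges(raw, subjects)
        rectified = [net.rectify_negative(m) for m in resid]
    else:
        rectified = net.residualize_edges([net.rectify_negative(m) for m in raw], subjects)
        rectified = [net.rectify_negative(m) for m in rectified]
    stage_log.append("residualize + rectify done")

    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    names = list(node_table["name"])
    for m in rectified:
        fio.write_matrix(m.weights, names, mat_dir / f"{m.subject_id}_rectified.tsv")

    if config.sparsity_mode == "fixed":
        selected = config.fixed_sparsity
        min_s = float("nan")
        stage_log.append(f"fixed sparsity {selected:.3f}")
    else:
        selected, min_s = net.select_group_sparsity(rectified)
        stage_log.append(f"selected sparsity {selected:.3f} (min {min_s:.3f})")

    nodal_values, eglob = compute_cohort_metrics(
        rectified, selected, eloc_variant=config.eloc_variant
    )
    stage_log.append("graph metrics done")

    metrics_dir = out / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    for k, sid in enumerate(sids):
        tab = pd.DataFrame({m: nodal_values[m][k] for m in NODAL_METRIC_NAMES}, index=names)
        tab.to_csv(metrics_dir / f"{sid}.tsv", sep="\t", float_format="%.10g")

    is_case = (subjects["group"] == "case").to_numpy()
    comparison = run_group_comparison(
        {m: _split(v, is_case) for m, v in nodal_values.items()},
        _split(eglob, is_case),
        n_perm=config.n_perm,
        master_seed=config.master_seed,
        global_test=config.global_test,
    )
    stage_log.append("group comparison (single sparsity) done")

    auc_comparison = None
    if config.sparsity_mode == "range":
        auc_nodal, auc_eglob = _auc_values(
            rectified, config.sparsity_grid, config.eloc_variant
        )
        auc_comparison = run_group_comparison(
            {m: _split(v, is_case) for m, v in auc_nodal.items()},
            _split(auc_eglob, is_case),
            n_perm=config.n_perm,
            master_seed=config.master_seed + 1,
            mode="auc_range",
            global_test=config.global_test,
        )
        stage_log.append(f"AUC comparison over {len(config.sparsity_grid)} levels done")

    correlations = zdiff = None
    scores_present = [s for s in CNT_SUBTESTS if s in subjects.columns]
    if scores_present:
        correlations, zdiff = run_brain_behavior(
            nodal_values,
            subjects,
            scores_present,
            n_perm=config.n_perm,
            master_seed=config.master_seed + 2,
            fdr_q=config.fdr_q,
            mad_multiplier=config.mad_multiplier,
        )
        stage_log.append("brain-behavior correlation done")

    manifest = {
        "master_seed": config.master_seed,
        "config_hash": config.content_hash(),
        "n_subjects": len(sids),
        "n_nodes": len(names),
        "selected_sparsity": selected,
        "min_sparsity": min_s,
        "stages": stage_log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    result = PipelineResult(
        config=config,
        subjects=subjects,
        selected_sparsity=selected,
        min_sparsity=min_s,
        nodal_values=nodal_values,
        eglob=eglob,
        comparison=comparison,
        auc_comparison=auc_comparison,
        correlations=correlations,
        zdiff=zdiff,
        manifest=manifest,
    )
    write_report(result, node_table, out)
    return result


METRIC_LABELS = {
    "bc": "Betweenness centrality",
    "strength": "Strength",
    "cc": "Clustering coefficient",
    "eloc": "Local efficiency",
}


def write_report(result: PipelineResult, node_table: pd.DataFrame, out_dir: str | Path) -> None:
    """Human-readable delimited-text tables of the comparison results.

    The significant-nodes table has columns (characteristic, region, lobe,
    direction, t) with direction coded +1 (increased in cases) / -1
    (decreased); the global table lists group mean +/- sd and p per measure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for metric, table in result.comparison.nodal.items():
        sig = table[table["significant"]]
        for _, r in sig.iterrows():
            rows.append(
                {
                    "characteristic": METRIC_LABELS.get(metric, metric),
                    "region": node_table["name"].iloc[int(r["node"])],
                    "lobe": node_table["lobe"].iloc[int(r["node"])],
                    "direction": 1 if r["direction"] == "increased" else -1,
                    "t": round(float(r["t_obs"]), 2),
                }
            )
    cols = ["characteristic", "region", "lobe", "direction", "t"]
    pd.DataFrame(rows, columns=cols).to_csv(
        out / "significant_nodes.tsv", sep="\t", index=False
    )
    result.comparison.node_averaged.to_csv(
        out / "global_comparison.tsv", sep="\t", index=False, float_format="%.4g"
    )
    eg = result.comparison.eglob
    pd.DataFrame(
        [{"t_obs": eg.t_obs, "null_5th": eg.null_lo, "significant": eg.significant,
          "p_emp": eg.p_emp}]
    ).to_csv(out / "eglob_test.tsv", sep="\t", index=False, float_format="%.4g")
    if result.correlations is not None:
        result.correlations.to_csv(
            out / "brain_behavior.tsv", sep="\t", index=False, float_format="%.4g"
        )
    if result.zdiff is not None:
        result.zdiff.to_csv(
            out / "zdiff_tests.tsv", sep="\t", index=False, float_format="%.4g"
        )
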