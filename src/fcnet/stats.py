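"""Permutation-based group comparison of graph measures.

The inferential machinery: pooled-variance two-sample t statistics
(oriented case minus control), label-permutation null distributions with a
nearest-rank percentile decision rule — two-tailed 2.5/97.5 for nodal
measures, one-tailed lower 5th percentile for global efficiency — a
one-sided Wilcoxon rank-sum comparison of node-averaged measures, and the
score-table comparison (clinical scores two-sided t, cognitive t-scores
one-sided t).  Nodal maps are deliberately NOT multiplicity-corrected by
default (an optional FDR switch exists); an empirical p-value
(1 + exceedances) / (n_perm + 1) is reported alongside every percentile
decision.

Reproducibility: one master seed deterministically spawns an independent
random substream for every (metric, node) null via numpy SeedSequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .metrics import NODAL_METRIC_NAMES

__all__ = [
    "PermutationResult",
    "GroupComparisonReport",
    "two_sample_t",
    "permutation_null",
    "nodal_permutation_test",
    "eglob_permutation_test",
    "ranksum_global",
    "compare_score_table",
    "run_group_comparison",
]

DEFAULT_N_PERM = 10_000


@dataclass
class PermutationResult:
    """Outcome of one permutation test (observed t against its null)."""

    t_obs: float
    null_lo: float
    null_hi: float
    n_perm: int
    significant: bool
    direction: str  # {"increased", "decreased", "none"}
    p_emp: float


@dataclass
class GroupComparisonReport:
    """Bundle of nodal and global group-comparison results."""

    nodal: dict[str, pd.DataFrame]          # metric -> per-node table
    eglob: PermutationResult
    node_averaged: pd.DataFrame             # rank-sum (or t) per metric
    mode: str = "single_sparsity"
    master_seed: int | None = None

    def significant_nodes(self, metric: str) -> pd.DataFrame:
        t = self.nodal[metric]
        return t[t["significant"]]


def two_sample_t(a, b) -> float:
    """Pooled-variance two-sample t, oriented as mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        warnings.warn("zero pooled variance; t set to 0")
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def _perm_index_matrix(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    idx = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(idx, axis=1)


def _t_from_perms(pooled: np.ndarray, idx: np.ndarray, na: int) -> np.ndarray:
    """Vectorised pooled t over rows of a permutation index matrix."""
    nb = pooled.size - na
    pa = pooled[idx[:, :na]]
    pb = pooled[idx[:, na:]]
    ma, mb = pa.mean(axis=1), pb.mean(axis=1)
    va = pa.var(axis=1, ddof=1)
    vb = pb.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def permutation_null(a, b, n_perm: int = DEFAULT_N_PERM, seed=0) -> np.ndarray:
    """Null distribution of pseudo t-values from random group relabellings.

    Group sizes are preserved in every shuffle; reproducible under the seed
    (an int or a numpy SeedSequence/Generator).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    idx = _perm_index_matrix(rng, pooled.size, n_perm)
    return _t_from_perms(pooled, idx, a.size)


def nearest_rank_percentile(sorted_null: np.ndarray, q: float) -> float:
    """Nearest-rank percentile of an ascending-sorted sample (q in %)."""
    n = sorted_null.size
    rank = max(1, int(np.ceil(q / 100.0 * n)))
    return float(sorted_null[rank - 1])


def _decide_two_tailed(t_obs: float, null: np.ndarray, n_perm: int) -> PermutationResult:
    null_sorted = np.sort(null)
    lo = nearest_rank_percentile(null_sorted, 2.5)
    hi = nearest_rank_percentile(null_sorted, 97.5)
    sig = bool(t_obs > hi or t_obs < lo)
    direction = "none"
    if sig:
        direction = "increased" if t_obs > hi else "decreased"
    p_emp = float((1 + np.count_nonzero(np.abs(null) >= abs(t_obs))) / (n_perm + 1))
    return PermutationResult(t_obs, lo, hi, n_perm, sig, direction, p_emp)


def nodal_permutation_test(
    case: np.ndarray,
    control: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    fdr: bool = False,
) -> pd.DataFrame:
    """Two-tailed 2.5/97.5 percentile permutation test at every node.

    ``case`` and ``control`` are (n_subjects x n_nodes) metric matrices.
    Each node gets an independent seeded null substream spawned from the
    master seed.  No multiplicity correction is applied unless ``fdr`` is
    set (then BH-adjusted empirical p-values are appended).
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    if case.shape[1] != control.shape[1]:
        raise ValueError("case and control must share the node set")
    n_nodes = case.shape[1]
    na = case.shape[0]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_nodes)
    rows = []
    for node in range(n_nodes):
        rng = np.random.default_rng(children[node])
        pooled = np.concatenate([case[:, node], control[:, node]])
        t_obs = two_sample_t(case[:, node], control[:, node])
        null = _t_from_perms(pooled, _perm_index_matrix(rng, pooled.size, n_perm), na)
        res = _decide_two_tailed(t_obs, null, n_perm)
        rows.append(
            {
                "node": node,
                "t_obs": res.t_obs,
                "null_lo": res.null_lo,
                "null_hi": res.null_hi,
                "significant": res.significant,
                "direction": res.direction,
                "p_emp": res.p_emp,
            }
        )
    out = pd.DataFrame(rows)
    if fdr:
        out["p_fdr"] = multipletests(out["p_emp"], method="fdr_bh")[1]
        out["significant_fdr"] = out["p_fdr"] < 0.05
    return out


def eglob_permutation_test(
    case, control, n_perm: int = DEFAULT_N_PERM, seed: int = 0
) -> PermutationResult:
    """One-tailed (lower) 5th-percentile permutation rule for Eglob.

    Rejects only when the observed case-minus-control t falls below the 5th
    percentile of the permutation null — a case group with HIGHER global
    efficiency can never be flagged under this rule.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    t_obs = two_sample_t(case, control)
    null = permutation_null(case, control, n_perm=n_perm, seed=seed)
    null_sorted = np.sort(null)
    lo = nearest_rank_percentile(null_sorted, 5.0)
    sig = bool(t_obs < lo)
    p_emp = float((1 + np.count_nonzero(null <= t_obs)) / (n_perm + 1))
    return PermutationResult(
        t_obs, lo, float(null_sorted[-1]), n_perm, sig,
        "decreased" if sig else "none", p_emp,
    )


def ranksum_global(case, control, side: str = "less") -> float:
    """One-sided Wilcoxon rank-sum p for node-averaged metric values.

    ``side`` is the alternative for the case group ("less": case < control).
    Exact enumeration for combined n <= 12, otherwise the tie-corrected
    normal approximation.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    method = "exact" if case.size + control.size <= 12 else "asymptotic"
    res = sstats.mannwhitneyu(case, control, alternative=side, method=method)
    return float(res.pvalue)


def compare_score_table(
    subjects: pd.DataFrame,
    score_sides: dict[str, str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Group mean +/- sd and t-test p per score, with per-score sidedness.

    ``score_sides`` maps score column -> {"two-sided", "less", "greater"}
    ("less": case < control alternative, the convention for cognitive
    t-scores).  Subjects missing a score are dropped for that score; scores
    with fewer than two observations in either group are skipped with a
    warning.
    """
    rows = []
    grp = np.asarray(subjects[group_col])
    for score, side in score_sides.items():
        if score not in subjects.columns:
            warnings.warn(f"score {score!r} not in subject table; skipped")
            continue
        vals = pd.to_numeric(subjects[score], errors="coerce")
        a = vals[(grp == "case") & vals.notna()].to_numpy()
        b = vals[(grp == "control") & vals.notna()].to_numpy()
        if a.size < 2 or b.size < 2:
            warnings.warn(f"score {score!r}: fewer than 2 observations in a group; skipped")
            continue
        res = sstats.ttest_ind(a, b, alternative=side)
        rows.append(
            {
                "score": score,
                "case_mean": a.mean(), "case_sd": a.std(ddof=1), "n_case": a.size,
                "control_mean": b.mean(), "control_sd": b.std(ddof=1), "n_control": b.size,
                "side": side,
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def run_group_comparison(
    nodal_values: dict[str, tuple[np.ndarray, np.ndarray]],
    eglob_values: tuple[np.ndarray, np.ndarray],
    n_perm: int = DEFAULT_N_PERM,
    master_seed: int = 0,
    mode: str = "single_sparsity",
    global_test: str = "ranksum",
) -> GroupComparisonReport:
    """Full group comparison: nodal permutation maps + global tests.

    ``nodal_values`` maps metric name -> (case matrix, control matrix), each
    (n_subjects x n_nodes); in AUC mode the matrices hold per-subject AUC
    values over the sparsity grid and identical statistics are applied.
    Node-averaged metrics are compared by one-sided rank-sum by default
    (``global_test="t"`` switches to a one-sided two-sample t).
    """
    if mode not in ("single_sparsity", "auc_range"):
        raise ValueError(f"unknown mode {mode!r}")
    root = np.random.SeedSequence(master_seed)
    metric_seeds = root.spawn(len(NODAL_METRIC_NAMES) + 1)
    nodal = {}
    for k, metric in enumerate(NODAL_METRIC_NAMES):
        if metric not in nodal_values:
            continue
        case, control = nodal_values[metric]
        nodal[metric] = nodal_permutation_test(
            case, control, n_perm=n_perm, seed=metric_seeds[k]
        )
    eg_case, eg_control = eglob_values
    eglob = eglob_permutation_test(
        eg_case, eg_control, n_perm=n_perm, seed=np.random.default_rng(metric_seeds[-1])
    )
    avg_rows = []
    for metric, (case, control) in nodal_values.items():
        ca = np.atleast_2d(case).mean(axis=1)
        co = np.atleast_2d(control).mean(axis=1)
        if global_test == "ranksum":
            p = ranksum_global(ca, co, side="less")
        else:
            p = float(sstats.ttest_ind(ca, co, alternative="less").pvalue)
        avg_rows.append({"metric": metric, "case_mean": ca.mean(), "case_sd": ca.std(ddof=1),
                         "control_mean": co.mean(), "control_sd": co.std(ddof=1),
                         "test": global_test, "p": p})
    return GroupComparisonReport(
        nodal=nodal,
        eglob=eglob,
        node_averaged=pd.DataFrame(avg_rows),
        mode=mode,
        master_seed=master_seed,
    )
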