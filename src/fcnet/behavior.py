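"""Brain-behavior correlation analysis with a Fisher-z difference test.

Per group, each nodal graph measure is correlated (Pearson) with each of
the 16 cognitive subtests; p-values are Benjamini–Hochberg corrected within
the family of 16 subtests for one (node, metric, group).  Associations that
survive FDR proceed to a between-group comparison of correlations:

    z_diff = (atanh(r_case) - atanh(r_control))
             / sqrt(1/(n_case - 3) + 1/(n_control - 3))

whose significance is assessed against a label-permutation null (pseudo
correlations recomputed under shuffled group labels each time), with the
analytic two-sided normal p reported alongside.  A sensitivity rerun with
median-absolute-deviation outlier screening accompanies each flagged pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "ZDiffResult",
    "pearson_r",
    "bh_fdr",
    "fisher_z",
    "z_difference",
    "z_difference_permutation_test",
    "mad_outlier_mask",
    "run_brain_behavior",
]

DEFAULT_MAD_MULTIPLIER = 2.5
_MAD_SCALE = 1.4826  # consistency factor for normal data


@dataclass
class CorrelationResult:
    node: int
    metric: str
    score: str
    group: str
    r: float
    n: int
    p_raw: float
    p_fdr: float
    outliers_removed: int = 0


@dataclass
class ZDiffResult:
    z_case: float
    z_control: float
    n_case: int
    n_control: int
    z_diff: float
    p_perm: float
    p_normal: float
    n_redrawn: int = 0


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    for name, v in (("x", x), ("y", y)):
        if v.std() == 0:
            raise ValueError(f"variable {name!r} has zero variance")
    res = sstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_z(r: float) -> float:
    """Variance-stabilising transform z = atanh(r)."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError("Fisher z is infinite at |r| = 1")
    return float(np.arctanh(r))


def z_difference(
    r_case: float, n_case: int, r_control: float, n_control: int
) -> tuple[float, float]:
    """Two-sample Fisher-z statistic for comparing independent correlations.

    Returns (z_diff, two-sided normal p).  Requires n >= 4 per group so the
    1/(n-3) variance terms are positive.
    """
    if n_case <= 3 or n_control <= 3:
        raise ValueError("each group needs n >= 4")
    z1, z2 = fisher_z(r_case), fisher_z(r_control)
    se = np.sqrt(1.0 / (n_case - 3) + 1.0 / (n_control - 3))
    z = (z1 - z2) / se
    p = 2.0 * sstats.norm.sf(abs(z))
    return float(z), float(p)


def _rowwise_r(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of x with the matching row of y."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def z_difference_permutation_test(
    values: np.ndarray,
    scores: np.ndarray,
    is_case: np.ndarray,
    n_perm: int = 10_000,
    seed=0,
) -> ZDiffResult:
    """Permutation test of whether a metric-score correlation differs by group.

    Subjects (metric, score) pairs are randomly reassigned to pseudo-groups
    of the original sizes; each shuffle yields a pseudo z_diff, and the
    observed statistic is compared two-sidedly against that null with the
    estimator (1 + exceedances) / (n_perm + 1).  Permutations producing a
    degenerate correlation (|r| ~ 1) are redrawn and counted.
    """
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    keep = np.isfinite(values) & np.isfinite(scores)
    values, scores, is_case = values[keep], scores[keep], is_case[keep]
    n_case = int(is_case.sum())
    n_control = int((~is_case).sum())
    r_case, _ = pearson_r(values[is_case], scores[is_case])
    r_control, _ = pearson_r(values[~is_case], scores[~is_case])
    z_obs, p_normal = z_difference(r_case, n_case, r_control, n_control)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = values.size
    null = np.empty(n_perm)
    filled = 0
    n_redrawn = 0
    tol = 1.0 - 1e-12
    while filled < n_perm:
        batch = min(n_perm - filled, n_perm)
        idx = rng.permuted(np.tile(np.arange(n), (batch, 1)), axis=1)
        rc = _rowwise_r(values[idx[:, :n_case]], scores[idx[:, :n_case]])
        rx = _rowwise_r(values[idx[:, n_case:]], scores[idx[:, n_case:]])
        ok = (np.abs(rc) < tol) & (np.abs(rx) < tol)
        n_redrawn += int(batch - ok.sum())
        se = np.sqrt(1.0 / (n_case - 3) + 1.0 / (n_control - 3))
        zd = (np.arctanh(rc[ok]) - np.arctanh(rx[ok])) / se
        take = min(zd.size, n_perm - filled)
        null[filled : filled + take] = zd[:take]
        filled += take
    p_perm = float((1 + np.count_nonzero(np.abs(null) >= abs(z_obs))) / (n_perm + 1))
    return ZDiffResult(
        z_case=fisher_z(r_case),
        z_control=fisher_z(r_control),
        n_case=n_case,
        n_control=n_control,
        z_diff=z_obs,
        p_perm=p_perm,
        p_normal=p_normal,
        n_redrawn=n_redrawn,
    )


def mad_outlier_mask(values, n_mads: float = DEFAULT_MAD_MULTIPLIER) -> np.ndarray:
    """Boolean keep-mask from median-absolute-deviation screening.

    A point is dropped when |x - median| / (1.4826 * MAD) exceeds
    ``n_mads`` (default 2.5).  If the MAD is zero every point is kept and a
    warning is issued.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("MAD screening needs at least 4 values")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged")
        return np.ones(v.size, dtype=bool)
    return np.abs(v - med) / (_MAD_SCALE * mad) <= n_mads


def run_brain_behavior(
    metric_values: dict[str, np.ndarray],
    subjects: pd.DataFrame,
    score_names: list[str],
    nodes: list[int] | None = None,
    n_perm: int = 10_000,
    master_seed: int = 0,
    fdr_q: float = 0.05,
    mad_multiplier: float = DEFAULT_MAD_MULTIPLIER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full correlation workflow over (node, metric, score, group) cells.

    For every node and metric, the 16-score p-value family is FDR-corrected
    within each group; any (node, metric, score) significant after FDR in
    either group proceeds to the z-difference permutation test and a
    MAD-screened sensitivity recomputation of the per-group correlations.

    ``metric_values`` maps metric name -> (n_subjects x n_nodes) array
    aligned with the subject table rows.  Subjects with a missing score are
    dropped for that score before testing or permuting.

    Returns (correlations table, z-difference table).
    """
    group = np.asarray(subjects["group"])
    is_case_all = group == "case"
    corr_rows = []
    zdiff_rows = []
    ss = np.random.SeedSequence(master_seed)
    for metric, mat in metric_values.items():
        mat = np.asarray(mat, dtype=float)
        node_list = list(range(mat.shape[1])) if nodes is None else list(nodes)
        for node in node_list:
            per_group: dict[str, dict] = {}
            for gname, gmask in (("case", is_case_all), ("control", ~is_case_all)):
                ps, rs, ns = [], [], []
                for score in score_names:
                    sv = pd.to_numeric(subjects[score], errors="coerce").to_numpy()
                    ok = gmask & np.isfinite(sv)
                    r, p = pearson_r(mat[ok, node], sv[ok])
                    rs.append(r)
                    ps.append(p)
                    ns.append(int(ok.sum()))
                per_group[gname] = {
                    "r": rs, "p": ps, "n": ns, "p_fdr": bh_fdr(ps),
                }
            for si, score in enumerate(score_names):
                for gname in ("case", "control"):
                    g = per_group[gname]
                    corr_rows.append(
                        {
                            "node": node, "metric": metric, "score": score,
                            "group": gname, "r": g["r"][si], "n": g["n"][si],
                            "p_raw": g["p"][si], "p_fdr": g["p_fdr"][si],
                        }
                    )
                hit = any(per_group[g]["p_fdr"][si] < fdr_q for g in ("case", "control"))
                if not hit:
                    continue
                sv = pd.to_numeric(subjects[score], errors="coerce").to_numpy()
                ok = np.isfinite(sv)
                res = z_difference_permutation_test(
                    mat[ok, node], sv[ok], is_case_all[ok],
                    n_perm=n_perm, seed=np.random.default_rng(ss.spawn(1)[0]),
                )
                sens = {}
                for gname, gmask in (("case", is_case_all), ("control", ~is_case_all)):
                    gok = gmask & ok
                    x, y = mat[gok, node], sv[gok]
                    keep = mad_outlier_mask(x, mad_multiplier) & mad_outlier_mask(
                        y, mad_multiplier
                    )
                    if keep.sum() >= 3 and x[keep].std() > 0 and y[keep].std() > 0:
                        r2, p2 = pearson_r(x[keep], y[keep])
                    else:
                        r2, p2 = np.nan, np.nan
                    sens[gname] = (r2, p2, int((~keep).sum()))
                zdiff_rows.append(
                    {
                        "node": node, "metric": metric, "score": score,
                        "z_case": res.z_case, "z_control": res.z_control,
                        "n_case": res.n_case, "n_control": res.n_control,
                        "z_diff": res.z_diff, "p_perm": res.p_perm,
                        "p_normal": res.p_normal,
                        "r_case_mad": sens["case"][0], "p_case_mad": sens["case"][1],
                        "outliers_case": sens["case"][2],
                        "r_control_mad": sens["control"][0],
                        "p_control_mad": sens["control"][1],
                        "outliers_control": sens["control"][2],
                    }
                )
    return pd.DataFrame(corr_rows), pd.DataFrame(zdiff_rows)
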