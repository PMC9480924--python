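"""Synthetic multi-subject cohort generator for functional-connectivity studies.

Emulates the statistical structure a resting-state connectivity analysis
assumes: a modular node-by-node correlation structure, a case group in
which connectivity of chosen nodes is attenuated, linear age/sex confounds
acting on all edges through a shared latent signal, and cognitive t-scores
(mean 50, sd 10) optionally coupled to a nodal graph metric in the case
group only.  Time samples are i.i.d. multivariate normal draws — the
downstream pipeline only consumes Pearson correlations, so temporal
autocorrelation is deliberately not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ROITimeSeries

__all__ = [
    "BehaviorCoupling",
    "SyntheticCohortConfig",
    "CNT_SUBTESTS",
    "build_covariance",
    "generate_cohort",
    "generate_behavior_scores",
    "attach_score_battery",
    "slope_for_target_r",
]

#: The 16 computerized cognitive subtests reported as t-scores: card sorting,
#: digit span (2), verbal learning (4), visual learning (4), word-color (5).
CNT_SUBTESTS = [
    "card_sorting",
    "digit_span_forward",
    "digit_span_backward",
    "verbal_A1",
    "verbal_A5",
    "verbal_delayed_recall",
    "verbal_A1_A5",
    "visual_A1",
    "visual_A5",
    "visual_delayed_recall",
    "visual_A1_A5",
    "word_black",
    "color_only",
    "color_word",
    "word_of_color_word",
    "color_of_color_word",
]


@dataclass(frozen=True)
class BehaviorCoupling:
    """Linear coupling of one cognitive score to one nodal graph metric.

    score = 50 + slope * standardized(metric at `node`) + Normal(0, noise_sd),
    applied in the case group only when `case_only` is set (controls then get
    pure noise around 50), mirroring an association present in patients but
    absent in controls.
    """

    metric: str
    node: int
    slope: float
    noise_sd: float
    score: str = "verbal_A1"
    case_only: bool = True


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-condition parameters for a two-group synthetic cohort.

    Defaults reproduce a 29-vs-29 cohort over 112 nodes.  Correlation levels
    (within-module 0.45, between-module 0.12) and 150 timepoints are typical
    of ROI-averaged resting-state data after preprocessing; seven modules
    echo the canonical count of large-scale resting-state networks.
    """

    n_nodes: int = 112
    n_modules: int = 7
    t_points: int = 150
    n_per_group: int = 29
    base_within_r: float = 0.45
    base_between_r: float = 0.12
    effect_nodes: tuple[int, ...] = ()
    effect_attenuation: float = 1.0
    confound_age_slope: float = 0.0
    confound_sex_delta: float = 0.0
    behavior_coupling: BehaviorCoupling | None = None
    age_range: tuple[float, float] = (20.0, 70.0)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.base_between_r <= self.base_within_r < 1:
            raise ValueError("require 0 < base_between_r <= base_within_r < 1")
        if self.t_points < 30:
            raise ValueError("t_points must be >= 30")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 <= self.effect_attenuation <= 1:
            raise ValueError("effect_attenuation must be in [0, 1]")
        if any(not 0 <= i < self.n_nodes for i in self.effect_nodes):
            raise ValueError("effect_nodes must be valid node indices")
        if self.n_modules < 1 or self.n_modules > self.n_nodes:
            raise ValueError("n_modules must be in [1, n_nodes]")

    def with_(self, **kw) -> "SyntheticCohortConfig":
        return replace(self, **kw)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["effect_nodes"] = list(d["effect_nodes"])
        d["age_range"] = list(d["age_range"])
        if d["behavior_coupling"] is not None:
            d["behavior_coupling"] = asdict(self.behavior_coupling)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        d["effect_nodes"] = tuple(d.get("effect_nodes", ()))
        d["age_range"] = tuple(d.get("age_range", (20.0, 70.0)))
        if d.get("behavior_coupling") is not None:
            d["behavior_coupling"] = BehaviorCoupling(**d["behavior_coupling"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def module_assignment(config: SyntheticCohortConfig) -> np.ndarray:
    """Contiguous module label per node (sizes as equal as possible)."""
    return np.concatenate(
        [np.full(len(b), i) for i, b in
         enumerate(np.array_split(np.arange(config.n_nodes), config.n_modules))]
    )


def build_covariance(config: SyntheticCohortConfig, group: str) -> np.ndarray:
    """Block-modular unit-diagonal covariance (= correlation) for one group.

    In the case group, every off-diagonal entry in the rows/columns of the
    configured effect nodes is multiplied by ``effect_attenuation`` (applied
    once per entry, also for pairs of effect nodes).  If attenuation breaks
    positive semidefiniteness the matrix is repaired by clipping negative
    eigenvalues at zero and re-normalising the diagonal to one; the repair is
    reported with a warning.
    """
    config.validate()
    if group not in ("case", "control"):
        raise ValueError(f"unknown group {group!r}")
    mod = module_assignment(config)
    same = mod[:, None] == mod[None, :]
    c = np.where(same, config.base_within_r, config.base_between_r).astype(float)
    np.fill_diagonal(c, 1.0)
    if group == "case" and config.effect_nodes and config.effect_attenuation != 1.0:
        idx = np.array(sorted(set(config.effect_nodes)), dtype=int)
        hit = np.zeros(config.n_nodes, dtype=bool)
        hit[idx] = True
        mask = hit[:, None] | hit[None, :]
        np.fill_diagonal(mask, False)
        c = np.where(mask, c * config.effect_attenuation, c)
    eig = np.linalg.eigvalsh(c)
    if eig[0] < -1e-10:
        warnings.warn("covariance repaired by eigenvalue clipping (attenuation broke PSD)")
        vals, vecs = np.linalg.eigh(c)
        c = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        d = np.sqrt(np.clip(np.diag(c), 1e-12, None))
        c = c / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
        c = (c + c.T) / 2
    return c


def _cholesky_factor(cov: np.ndarray) -> np.ndarray:
    # covariance may be PSD but singular after repair; add a whisper of ridge
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))


def generate_cohort(
    config: SyntheticCohortConfig, node_names: list[str] | None = None
) -> tuple[list[ROITimeSeries], pd.DataFrame]:
    """Draw a full two-group cohort of ROI time series plus a subject table.

    Each subject's series is ``t_points`` i.i.d. multivariate-normal samples
    from the group covariance.  Ages are uniform over ``age_range``; sexes
    alternate F/M within each group (near-balanced).  Age/sex confounds mix a
    per-subject latent signal into all nodes with coefficient
    ``confound_age_slope * (age - age_mid) + confound_sex_delta * [sex==M]``,
    producing rank-one edge-level confounding that the edge residualisation
    stage is expected to remove.  Deterministic under the config seed.
    """
    config.validate()
    if node_names is None:
        node_names = [f"node{i:03d}" for i in range(config.n_nodes)]
    if len(node_names) != config.n_nodes:
        raise ValueError("node_names length must equal n_nodes")
    rng = np.random.default_rng(config.seed)
    chol = {g: _cholesky_factor(build_covariance(config, g)) for g in ("case", "control")}
    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])

    series: list[ROITimeSeries] = []
    rows = []
    for group in ("case", "control"):
        for k in range(config.n_per_group):
            sid = f"{group}{k + 1:02d}"
            age = float(rng.uniform(*config.age_range))
            sex = "F" if k % 2 == 0 else "M"
            x = rng.standard_normal((config.t_points, config.n_nodes)) @ chol[group].T
            coef = (
                config.confound_age_slope * (age - age_mid)
                + config.confound_sex_delta * (sex == "M")
            )
            if coef != 0.0:
                latent = rng.standard_normal(config.t_points)
                x = x + coef * latent[:, None]
            else:
                rng.standard_normal(config.t_points)  # keep stream alignment
            series.append(ROITimeSeries(subject_id=sid, data=x, node_names=list(node_names)))
            rows.append({"subject_id": sid, "group": group, "age": age, "sex": sex})
    subjects = pd.DataFrame(rows)
    return series, subjects


def slope_for_target_r(target_r: float, noise_sd: float) -> float:
    """Slope on a standardized metric giving population correlation target_r.

    With score = 50 + b*z + e, e ~ N(0, sd^2) and z standardized, the
    population correlation is b / sqrt(b^2 + sd^2); invert for b.
    """
    if not -1 < target_r < 1:
        raise ValueError("target_r must be in (-1, 1)")
    return target_r * noise_sd / np.sqrt(1.0 - target_r**2)


def generate_behavior_scores(
    subject_metrics: dict[str, np.ndarray],
    subjects: pd.DataFrame,
    coupling: BehaviorCoupling,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cognitive t-scores coupled to a nodal metric of each subject.

    ``subject_metrics`` maps metric name -> (n_subjects x n_nodes) array
    aligned with the subject table.  The metric is standardized within the
    coupled group before applying the slope so the slope/noise pair maps
    directly onto a population correlation (see :func:`slope_for_target_r`).
    """
    if coupling.metric not in subject_metrics:
        raise KeyError(
            f"metric {coupling.metric!r} not available; have {sorted(subject_metrics)}"
        )
    values = np.asarray(subject_metrics[coupling.metric], dtype=float)[:, coupling.node]
    group = np.asarray(subjects["group"])
    scores = 50.0 + rng.normal(0.0, coupling.noise_sd, size=len(values))
    target = group == "case" if coupling.case_only else np.ones(len(values), bool)
    sub = values[target]
    sd = sub.std()
    z = (sub - sub.mean()) / sd if sd > 0 else np.zeros_like(sub)
    scores[target] += coupling.slope * z
    return scores


def attach_score_battery(
    subjects: pd.DataFrame,
    rng: np.random.Generator,
    subject_metrics: dict[str, np.ndarray] | None = None,
    coupling: BehaviorCoupling | None = None,
    group_shift: float = 0.0,
) -> pd.DataFrame:
    """Add the 16-subtest cognitive battery (t-scores, N(50, 10)) to a cohort.

    All subtests are drawn as null t-scores, optionally shifted by
    ``-group_shift`` in the case group (patients scoring lower); if a
    coupling is given, its target subtest is instead generated by
    :func:`generate_behavior_scores`.
    """
    out = subjects.copy()
    case = np.asarray(out["group"]) == "case"
    for name in CNT_SUBTESTS:
        if coupling is not None and name == coupling.score:
            if subject_metrics is None:
                raise ValueError("coupling requires subject_metrics")
            out[name] = generate_behavior_scores(subject_metrics, out, coupling, rng)
        else:
            col = rng.normal(50.0, 10.0, size=len(out))
            col[case] -= group_shift
            out[name] = col
    return out
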