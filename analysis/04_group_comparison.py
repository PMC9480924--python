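"""Compare groups: nodal permutation maps, Eglob rule, node-averaged tests.

Runs the two-tailed 2.5/97.5 percentile permutation test per node for each
measure, the one-tailed 5th-percentile rule for Eglob, and one-sided
rank-sum tests on node-averaged measures — at the selected sparsity and
again on the per-subject AUC values.  Also compares the cognitive score
battery between groups.  Writes report tables under
results/analysis/comparison/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fcnet.io import load_node_table, read_subject_table
from fcnet.metrics import NODAL_METRIC_NAMES
from fcnet.stats import compare_score_table, run_group_comparison
from fcnet.synthetic import CNT_SUBTESTS

MET = Path("results/analysis/metrics")
COHORT = Path("results/analysis/cohort")
OUT = Path("results/analysis/comparison")
N_PERM = 2_000  # reduced from the full 10,000 to keep this driver quick
SEED = 17


def _nodal_arrays(subjects, suffix=""):
    values = {}
    for name in NODAL_METRIC_NAMES:
        if suffix:
            tab = pd.read_csv(MET / f"{suffix}{name}.tsv", sep="\t", index_col=0)
            mat = tab.loc[subjects["subject_id"]].to_numpy()
        else:
            mat = np.stack(
                [
                    pd.read_csv(MET / f"{sid}.tsv", sep="\t", index_col=0)[name].to_numpy()
                    for sid in subjects["subject_id"]
                ]
            )
        values[name] = mat
    return values


def _report(tag, report, node_table):
    rows = []
    for metric, table in report.nodal.items():
        for _, r in table[table["significant"]].iterrows():
            rows.append({
                "characteristic": metric,
                "region": node_table["name"].iloc[int(r["node"])],
                "lobe": node_table["lobe"].iloc[int(r["node"])],
                "direction": 1 if r["direction"] == "increased" else -1,
                "t": round(float(r["t_obs"]), 2),
            })
    out = pd.DataFrame(rows, columns=["characteristic", "region", "lobe",
                                      "direction", "t"])
    out.to_csv(OUT / f"significant_nodes_{tag}.tsv", sep="\t", index=False)
    report.node_averaged.to_csv(OUT / f"global_{tag}.tsv", sep="\t", index=False,
                                float_format="%.4g")
    return out


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    node_table = load_node_table()
    subjects = read_subject_table(COHORT / "subjects.tsv")
    is_case = (subjects["group"] == "case").to_numpy()

    def split(v):
        return v[is_case], v[~is_case]

    # single selected sparsity
    nodal = _nodal_arrays(subjects)
    eglob = pd.read_csv(MET / "eglob.tsv", sep="\t").set_index("subject_id").loc[
        subjects["subject_id"], "eglob"
    ].to_numpy()
    rep = run_group_comparison(
        {m: split(v) for m, v in nodal.items()}, split(eglob),
        n_perm=N_PERM, master_seed=SEED,
    )
    sig = _report("selected", rep, node_table)
    print(f"single-sparsity mode: {len(sig)} significant nodal effects; "
          f"Eglob decreased: {rep.eglob.significant} (t={rep.eglob.t_obs:.2f})")
    print(sig.to_string(index=False) if len(sig) else "  (none)")

    # AUC over the sparsity range
    nodal_auc = _nodal_arrays(subjects, suffix="auc_")
    eglob_auc = pd.read_csv(MET / "auc_eglob.tsv", sep="\t").set_index(
        "subject_id"
    ).loc[subjects["subject_id"], "eglob_auc"].to_numpy()
    rep_auc = run_group_comparison(
        {m: split(v) for m, v in nodal_auc.items()}, split(eglob_auc),
        n_perm=N_PERM, master_seed=SEED + 1, mode="auc_range",
    )
    sig_auc = _report("auc", rep_auc, node_table)
    overlap = set(map(tuple, sig[["characteristic", "region"]].values)) & set(
        map(tuple, sig_auc[["characteristic", "region"]].values)
    )
    print(f"AUC mode: {len(sig_auc)} significant nodal effects; "
          f"{len(overlap)} overlap with single-sparsity mode")

    # cognitive/clinical score comparison (cognitive one-sided, case < control)
    sides = {s: "less" for s in CNT_SUBTESTS if s in subjects.columns}
    scores = compare_score_table(subjects, sides)
    scores.to_csv(OUT / "score_comparison.tsv", sep="\t", index=False,
                  float_format="%.4g")
    print(f"score battery: {(scores['p'] < 0.05).sum()} of {len(scores)} "
          f"subtests lower in cases at p < 0.05")


if __name__ == "__main__":
    main()
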