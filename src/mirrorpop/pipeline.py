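"""End-to-end pipeline: selection → preprocessing → alignment → statistics.

``run_pipeline`` is a pure function of (Dataset, PipelineConfig): given the
same inputs and seed it produces byte-identical result files.  It logs the
unit count surviving each filtering stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datamodel import Dataset, TASKS
from .modulation import (InclusionSet, classify_dataset, paired_preference,
                         select_population, sign_by_epoch)
from .preprocessing import (build_task_matrices, epoch_mean,
                            epoch_trial_values, heatmap_order, net_activity)
from .stats import StatsReport, preference_chisq, rm_anova
from .subspace import AlignmentReport, bootstrap_alignment
from .trajectories import task_trajectories

log = logging.getLogger(__name__)

#: the default bootstrap contrasts: for each reference task (the two used in
#: the trajectory figures) compare the between-task alignments of the other
#: three tasks over it, all pairs.
def default_contrasts() -> list[tuple]:
    out = []
    for ref in ("OBSb", "EXE"):
        keys = [("between", t, ref) for t in TASKS if t != ref]
        out.extend((keys[i], keys[j])
                   for i in range(len(keys)) for j in range(i + 1, len(keys)))
    return out


@dataclass
class PipelineResult:
    inclusion: InclusionSet
    labels: list
    alignment: AlignmentReport
    stats: StatsReport
    trajectories: dict            # reference -> {task -> Trajectory2D}
    epoch_table: pd.DataFrame
    unit_counts: dict
    heatmap_orders: dict


def epoch_table(ds: Dataset, unit_ids: list, cfg: PipelineConfig,
                divisor: np.ndarray) -> pd.DataFrame:
    """Units × tasks table of ring-trial epoch-mean net soft-normalized
    activity (the four-task comparison uses the ring object, identical in
    all tasks)."""
    cols = {}
    for task in TASKS:
        vals = epoch_trial_values(ds, task, "ring", unit_ids, cfg, divisor)
        cols[task] = vals.mean(axis=0)
    return pd.DataFrame(cols, index=unit_ids)


def run_pipeline(cfg: PipelineConfig, ds: Dataset,
                 out_dir: str | Path | None = None,
                 contrasts: list | None = None) -> PipelineResult:
    ds.validate()
    n_bad = int((~ds.trials["correct"]).sum())
    if n_bad:
        log.info("excluding %d incorrect trials", n_bad)
    ds.require_complete(cfg.min_trials)
    n_total = len(ds.unit_ids)
    log.info("stage 0: %d units in dataset", n_total)

    labels = classify_dataset(ds, cfg)
    inclusion = select_population(labels)
    included = inclusion.included_unit_ids
    log.info("stage 1: %d units modulated during OBSb and/or OBSnb "
             "(%d execution-only, %d never active)", len(included),
             sum(1 for r in inclusion.excluded_reason.values() if r == "exe_only"),
             sum(1 for r in inclusion.excluded_reason.values() if r == "never_active"))
    if len(included) < 2:
        raise ValueError(
            f"only {len(included)} unit(s) included; PCA-based analyses "
            "are undefined below 2 units")

    matrices, divisor = build_task_matrices(ds, included, cfg)
    nets = net_activity(ds, included, cfg, divisor=divisor)
    orders = {task: heatmap_order(net, cfg.heatmap_window)
              for task, net in nets.items()}
    signs = sign_by_epoch(ds, included, cfg)

    contrasts = contrasts if contrasts is not None else default_contrasts()
    alignment = bootstrap_alignment(matrices, contrasts,
                                    n_boot=cfg.n_boot,
                                    criterion=cfg.boot_criterion,
                                    seed=cfg.seed)

    trajs = {ref: task_trajectories(matrices, ref) for ref in ("EXE", "OBSb")}

    table = epoch_table(ds, included, cfg, divisor)
    anova, posthoc = rm_anova(table, alpha=cfg.alpha)
    vb = epoch_trial_values(ds, "OBSb", "ring", included, cfg, divisor)
    vn = epoch_trial_values(ds, "OBSnb", "ring", included, cfg, divisor)
    prefs = {u: paired_preference(vb[:, j], vn[:, j], cfg.alpha)
             for j, u in enumerate(included)}
    counts = {
        "prefers_OBSb": sum(1 for v in prefs.values() if v == "prefers_OBSb"),
        "prefers_OBSnb": sum(1 for v in prefs.values() if v == "prefers_OBSnb"),
        "no_difference": sum(1 for v in prefs.values() if v == "no_difference"),
    }
    if counts["prefers_OBSb"] + counts["prefers_OBSnb"] > 0:
        chi2, chi2_p = preference_chisq(counts["prefers_OBSb"],
                                        counts["prefers_OBSnb"])
    else:
        chi2, chi2_p = None, None
    stats_report = StatsReport(anova=anova, posthoc=posthoc,
                               preference_counts=counts,
                               chisq=chi2, chisq_p=chi2_p)

    unit_counts = {
        "total": n_total,
        "included": len(included),
        "exe_only": sum(1 for r in inclusion.excluded_reason.values()
                        if r == "exe_only"),
        "never_active": sum(1 for r in inclusion.excluded_reason.values()
                            if r == "never_active"),
        "facilitated": {t: sum(1 for u in included
                               if signs[t][u] == "facilitated") for t in TASKS},
        "incorrect_trials_excluded": n_bad,
    }

    result = PipelineResult(inclusion=inclusion, labels=labels,
                            alignment=alignment, stats=stats_report,
                            trajectories=trajs, epoch_table=table,
                            unit_counts=unit_counts, heatmap_orders=orders)
    if out_dir is not None:
        write_results(result, cfg, Path(out_dir))
    return result


# ------------------------------------------------------------- serialization

def _key_str(key) -> str:
    if key[0] == "between":
        return f"{key[1]}_over_{key[2]}"
    return f"within_{key[1]}"


def write_results(res: PipelineResult, cfg: PipelineConfig,
                  out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([{"unit_id": l.unit_id, "task": l.task, "label": l.label,
                   "first_sig_bin": l.first_sig_bin} for l in res.labels]
                 ).to_csv(out / "modulation_labels.csv", index=False)

    rows = [{"unit_id": u, "included": True, "reason": ""}
            for u in res.inclusion.included_unit_ids]
    rows += [{"unit_id": u, "included": False, "reason": r}
             for u, r in sorted(res.inclusion.excluded_reason.items())]
    pd.DataFrame(rows).to_csv(out / "inclusion.csv", index=False)

    al = res.alignment
    pd.DataFrame([{"cond_a": f"{a[0]}:{a[1]}", "cond_ref": f"{r[0]}:{r[1]}",
                   "alignment": v} for (a, r), v in sorted(al.pairwise.items())]
                 ).to_csv(out / "alignment_pairwise.csv", index=False)

    summary = []
    for key in sorted(al.estimates):
        b = al.boot[key]
        summary.append({"alignment": _key_str(key),
                        "estimate": al.estimates[key],
                        "boot_p2.5": float(np.percentile(b, 2.5)),
                        "boot_p97.5": float(np.percentile(b, 97.5))})
    pd.DataFrame(summary).to_csv(out / "alignment_summary.csv", index=False)

    contr = []
    for (ka, kb), d in sorted(al.diffs.items()):
        contr.append({"contrast": f"{_key_str(ka)} - {_key_str(kb)}",
                      "mean_diff": float(d.mean()),
                      "frac_positive": float(np.mean(d > 0)),
                      "significant": bool(al.significant[(ka, kb)]),
                      "p_boot": float(al.p_value[(ka, kb)])})
    pd.DataFrame(contr).to_csv(out / "alignment_contrasts.csv", index=False)

    traj_rows = []
    for ref, per_task in res.trajectories.items():
        for task, tr in per_task.items():
            for t, (p1, p2) in zip(tr.bin_times, tr.points):
                traj_rows.append({"reference": ref, "task": task,
                                  "bin_time_s": float(t),
                                  "pc1": float(p1), "pc2": float(p2)})
    pd.DataFrame(traj_rows).to_csv(out / "trajectories.csv", index=False)

    res.epoch_table.rename_axis("unit_id").to_csv(out / "epoch_table.csv")

    st = res.stats
    report = {
        "anova": {"F": st.anova.f, "df": [st.anova.df_effect, st.anova.df_error],
                  "p": st.anova.p, "eta_squared": st.anova.eta_squared,
                  "sphericity_tested": st.anova.sphericity_tested},
        "posthoc": [{"pair": f"{c.task_a}-{c.task_b}",
                     "mean_diff": c.mean_diff, "q": c.q, "p": c.p,
                     "significant": c.significant} for c in st.posthoc],
        "preference_counts": st.preference_counts,
        "chisq": st.chisq, "chisq_p": st.chisq_p,
    }
    (out / "stats_report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1))

    (out / "unit_counts.json").write_text(
        json.dumps(res.unit_counts, sort_keys=True, indent=1))

    manifest = {"seed": cfg.seed, "config_digest": cfg.digest(),
                "config": cfg.to_dict(),
                "bootstrap_redrawn": res.alignment.n_redrawn}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True,
                                                  indent=1))
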