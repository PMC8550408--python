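"""Cohort-level statistics and report generation.

Group differences are assessed with pairwise Kruskal-Wallis rank tests
(chi-square approximation, tie-corrected) at a Bonferroni-adjusted
significance level alpha / n_pairs.  Speed-accuracy and complexity effects
use Pearson correlations, optionally stratified by prompt or setup.
Satisfaction is aggregated per setup with a combined mean taken as the
unweighted mean of the per-setup means.

:func:`make_report` regenerates every figure and table from the scored task
data: per-setup per-axis error scatter with the bias marker, per-task
completion-time boxplots with the mean plateau onset, the log-log position
accuracy vs completion time scatter sized by task difficulty, the
prompt-stratified scatter with group centroids, and satisfaction bars.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from .performance import cohort_plateau_summary, detect_plateau, performance_frame
from .schedule import Phase, TaskSpec
from .telemetry import SubjectSession

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "pairwise_group_test",
    "correlate",
    "summarize_satisfaction",
    "combined_mean_of_setup_means",
    "score_cohort",
    "make_report",
]


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic_h: float
    p_value: float
    adjusted_alpha: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    x_variable: str
    y_variable: str
    stratum: str
    r: float
    p_value: float
    n: int


def pairwise_group_test(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    alpha: float = 0.05,
    variable: str = "value",
) -> list[GroupComparison]:
    """All pairwise Kruskal-Wallis tests with Bonferroni-adjusted alpha.

    A degenerate pair (every pooled observation tied) is reported as
    non-significant with a warning rather than raising.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} needs at least two observations")
    pairs = list(itertools.combinations(sorted(groups), 2))
    adjusted = alpha / len(pairs)
    out: list[GroupComparison] = []
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        pooled = np.concatenate([va, vb])
        if np.all(pooled == pooled[0]):
            warnings.warn(
                f"groups {a!r} and {b!r} are fully tied; reporting H=0, p=1",
                stacklevel=2,
            )
            h, p, degenerate = 0.0, 1.0, True
        else:
            h, p = sps.kruskal(va, vb)
            degenerate = False
        out.append(
            GroupComparison(
                variable=variable,
                group_a=a,
                group_b=b,
                n_a=va.size,
                n_b=vb.size,
                median_a=float(np.median(va)),
                median_b=float(np.median(vb)),
                statistic_h=float(h),
                p_value=float(p),
                adjusted_alpha=adjusted,
                significant=bool(p < adjusted) and not degenerate,
                degenerate=degenerate,
            )
        )
    return out


def correlate(
    x,
    y,
    strata=None,
    x_variable: str = "x",
    y_variable: str = "y",
) -> list[CorrelationResult]:
    """Pearson r with two-sided p, overall and (optionally) per stratum."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    results = []
    labels = {"all": np.ones(x.size, dtype=bool)}
    if strata is not None:
        strata = np.asarray(strata)
        for s in pd.unique(strata):
            labels[str(s)] = strata == s
    for name, mask in labels.items():
        xs, ys = x[mask], y[mask]
        if xs.size < 3:
            raise ValueError(f"stratum {name!r} needs at least 3 pairs")
        if np.std(xs) == 0 or np.std(ys) == 0:
            raise ValueError(f"zero variance in stratum {name!r}: correlation undefined")
        r, p = sps.pearsonr(xs, ys)
        results.append(
            CorrelationResult(x_variable, y_variable, name, float(r), float(p), xs.size)
        )
    return results


def combined_mean_of_setup_means(setup_means) -> float:
    """Unweighted mean of per-setup means, rounded to one decimal for display."""
    return round(float(np.mean(np.asarray(setup_means, dtype=float))), 1)


def summarize_satisfaction(values_by_setup: dict[str, list[int]]) -> dict:
    """Per-setup Likert means (1-5) plus the combined mean across setups."""
    means = {}
    for setup, vals in values_by_setup.items():
        clean = [v for v in vals if v is not None]
        if not clean:
            warnings.warn(f"setup {setup!r} has no satisfaction responses; excluded",
                          stacklevel=2)
            continue
        if any(v not in range(1, 6) for v in clean):
            raise ValueError(f"satisfaction values must be 1..5 in setup {setup!r}")
        means[setup] = float(np.mean(clean))
    if not means:
        raise ValueError("no satisfaction responses in any setup")
    return {
        "per_setup_mean": means,
        "combined_mean": combined_mean_of_setup_means(list(means.values())),
        "n_responses": {
            s: sum(v is not None for v in vals) for s, vals in values_by_setup.items()
        },
    }


def score_cohort(
    sessions: list[SubjectSession], protocols: dict[str, list[TaskSpec]]
) -> pd.DataFrame:
    """Score every session against its setup's protocol into one long table."""
    from .performance import score_session

    frames = []
    for sess in sessions:
        scored = score_session(sess, protocols[sess.setup.value])
        frames.append(
            performance_frame(scored, subject_id=sess.subject_id, setup=sess.setup.value)
        )
    return pd.concat(frames, ignore_index=True)


def _axis_bias_table(plateau: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for setup, grp in plateau.groupby("setup"):
        med = grp[["err_x_norm", "err_y_norm", "err_z_norm"]].median()
        rows.append(
            {
                "setup": setup,
                "median_err_x_norm": med["err_x_norm"],
                "median_err_y_norm": med["err_y_norm"],
                "median_err_z_norm": med["err_z_norm"],
                "bias_norm": float(np.linalg.norm(med.to_numpy())),
            }
        )
    return pd.DataFrame(rows)


def make_report(
    sessions: list[SubjectSession],
    protocols: dict[str, list[TaskSpec]],
    output_dir: str | Path,
) -> dict[str, Path]:
    """Produce all figures (PNG) and tables (CSV/JSON) for a scored cohort.

    Returns the mapping of artifact name to path.  A missing phase yields a
    partial report with a warning instead of failing.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scored = score_cohort(sessions, protocols)
    artifacts: dict[str, Path] = {}

    scored_path = out / "scored_tasks.csv"
    scored.to_csv(scored_path, index=False)
    artifacts["scored_tasks"] = scored_path

    plateau_df = scored[scored["phase"] == Phase.PLATEAU.value]
    ramp_df = scored[scored["phase"] == Phase.RAMP_UP.value]
    setups = sorted(scored["setup"].unique())

    # Per-axis placement error scatter with bias marker
    if plateau_df.empty:
        warnings.warn("no plateau-phase tasks: error scatter omitted", stacklevel=2)
    else:
        bias_table = _axis_bias_table(plateau_df)
        bias_path = out / "axis_bias.csv"
        bias_table.to_csv(bias_path, index=False)
        artifacts["axis_bias"] = bias_path
        fig, axes = plt.subplots(1, len(setups), figsize=(4 * len(setups), 4))
        for ax, setup in zip(np.atleast_1d(axes), setups):
            grp = plateau_df[plateau_df["setup"] == setup]
            ax.scatter(grp["err_x_norm"], grp["err_y_norm"], s=8, alpha=0.5)
            ax.plot(0, 0, "b+", markersize=12)
            row = bias_table[bias_table["setup"] == setup].iloc[0]
            ax.plot(row["median_err_x_norm"], row["median_err_y_norm"], "bo")
            ax.set_title(setup)
            ax.set_xlabel("x error (norm)")
            ax.set_ylabel("y error (norm)")
            ax.axhline(0, lw=0.5, color="gray")
            ax.axvline(0, lw=0.5, color="gray")
        fig.tight_layout()
        p = out / "fig_axis_error_scatter.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        artifacts["fig_axis_error_scatter"] = p

        # Plateau detection per subject and setup
        plateau_summaries = {}
        for setup in setups:
            grp = plateau_df[plateau_df["setup"] == setup]
            per_subject = {
                sid: detect_plateau(
                    sub.sort_values("task_index")["completion_time_s"].to_numpy(),
                    variable="completion_time",
                )
                for sid, sub in grp.groupby("subject_id")
            }
            try:
                plateau_summaries[setup] = cohort_plateau_summary(per_subject)
            except ValueError:
                plateau_summaries[setup] = {"n_reached": 0}
        p = out / "plateau_summary.json"
        p.write_text(json.dumps(plateau_summaries, indent=1))
        artifacts["plateau_summary"] = p

        # Completion-time boxplots with mean plateau onset marker
        fig, axes = plt.subplots(1, len(setups), figsize=(5 * len(setups), 4))
        for ax, setup in zip(np.atleast_1d(axes), setups):
            grp = plateau_df[plateau_df["setup"] == setup]
            data = [
                grp[grp["task_index"] == i]["completion_time_s"].to_numpy()
                for i in sorted(grp["task_index"].unique())
            ]
            ax.boxplot(data, flierprops={"markersize": 2})
            summ = plateau_summaries.get(setup, {})
            if summ.get("n_reached"):
                ax.axvline(summ["mean_onset"], ls="-.", color="k")
            ax.set_title(setup)
            ax.set_xlabel("plateau task")
            ax.set_ylabel("completion time (s)")
        fig.tight_layout()
        p = out / "fig_completion_time_boxplots.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        artifacts["fig_completion_time_boxplots"] = p

    # Log-log accuracy vs time, sized by task difficulty
    if ramp_df.empty:
        warnings.warn("no ramp-up-phase tasks: tradeoff figures omitted", stacklevel=2)
    else:
        fig, ax = plt.subplots(figsize=(6, 5))
        for setup in setups:
            grp = ramp_df[ramp_df["setup"] == setup]
            ax.scatter(
                grp["completion_time_s"],
                grp["position_accuracy_mm"].clip(lower=1e-3),
                s=4 + 40 * grp["task_index"] / grp["task_index"].max(),
                alpha=0.5,
                label=setup,
            )
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("completion time (s)")
        ax.set_ylabel("position accuracy (mm)")
        ax.legend()
        fig.tight_layout()
        p = out / "fig_accuracy_vs_time.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        artifacts["fig_accuracy_vs_time"] = p

        # Prompt-stratified scatter with group centroids
        fig, axes = plt.subplots(1, len(setups), figsize=(5 * len(setups), 4))
        centroid_rows = []
        for ax, setup in zip(np.atleast_1d(axes), setups):
            grp = ramp_df[ramp_df["setup"] == setup]
            for prompt, marker in (("speed", "o"), ("accuracy", "x")):
                sub = grp[grp["prompt"] == prompt]
                if sub.empty:
                    continue
                ax.scatter(
                    sub["completion_time_s"],
                    sub["position_accuracy_mm"],
                    s=8,
                    alpha=0.4,
                    label=prompt,
                )
                cx = sub["completion_time_s"].mean()
                cy = sub["position_accuracy_mm"].mean()
                ax.plot(cx, cy, "b" + marker, markersize=14)
                centroid_rows.append(
                    {
                        "setup": setup,
                        "prompt": prompt,
                        "mean_completion_time_s": cx,
                        "mean_position_accuracy_mm": cy,
                    }
                )
            ax.set_title(setup)
            ax.set_xlabel("completion time (s)")
            ax.set_ylabel("position accuracy (mm)")
            ax.legend()
        fig.tight_layout()
        p = out / "fig_prompt_tradeoff.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        artifacts["fig_prompt_tradeoff"] = p
        cpath = out / "prompt_centroids.csv"
        pd.DataFrame(centroid_rows).to_csv(cpath, index=False)
        artifacts["prompt_centroids"] = cpath

    # Satisfaction bars
    by_setup: dict[str, list[int]] = {}
    for sess in sessions:
        by_setup.setdefault(sess.setup.value, []).append(sess.satisfaction)
    have_any = any(v is not None for vals in by_setup.values() for v in vals)
    if have_any:
        summary = summarize_satisfaction(by_setup)
        p = out / "satisfaction_summary.json"
        payload = dict(summary)
        payload["test"] = "pairwise Kruskal-Wallis, Bonferroni-adjusted alpha"
        counts_ok = all(
            len([v for v in vals if v is not None]) >= 2 for vals in by_setup.values()
        )
        if len(by_setup) >= 2 and counts_ok:
            payload["pairwise_tests"] = [
                asdict(c)
                for c in pairwise_group_test(
                    {
                        s: [v for v in vals if v is not None]
                        for s, vals in by_setup.items()
                    },
                    variable="satisfaction",
                )
            ]
        p.write_text(json.dumps(payload, indent=1))
        artifacts["satisfaction_summary"] = p
        fig, ax = plt.subplots(figsize=(5, 4))
        names = list(summary["per_setup_mean"])
        ax.bar(names, [summary["per_setup_mean"][s] for s in names])
        ax.axhline(summary["combined_mean"], ls="--", color="k")
        ax.set_ylabel("mean satisfaction (Likert 1-5)")
        ax.set_ylim(0, 5)
        fig.tight_layout()
        fp = out / "fig_satisfaction.png"
        fig.savefig(fp, dpi=120)
        plt.close(fig)
        artifacts["fig_satisfaction"] = fp
    else:
        warnings.warn("no satisfaction responses: satisfaction report omitted",
                      stacklevel=2)

    return artifacts
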