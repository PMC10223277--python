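"""Cohort-level aggregation of per-segmentation FAZ metrics.

Works on the tidy metrics table (one row per segmentation, columns
``cohort, plexus, criterion, observer, series, eye_id, area_mm2,
acircularity``) and produces the study's summary structures: mean/SD tables
per group × plexus × criterion, the initial-vs-final criterion contrast,
inter-/intra-observer variability, and the paired area–acircularity table.

Cross-record summary SDs use the sample (N−1) divisor.  By default all
segmentations are pooled within a cell; an eye-averaged mode (one value per
eye before summarising) is available.  No inferential statistics are
computed — the rank correlation in the paired table is descriptive.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInput, MissingCriterion
from .types import Criterion

__all__ = [
    "summarize",
    "criterion_contrast",
    "observer_variability",
    "area_acircularity_pairs",
    "plot_distributions",
    "plot_area_vs_acircularity",
    "IRREGULARITY_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: acircularity above this denotes a very irregular FAZ (poor segmentation
#: or a boundary genuinely far from circular)
IRREGULARITY_THRESHOLD = 0.5

_VALID_KEYS = ("cohort", "plexus", "criterion", "observer")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records)
    if records.empty:
        raise EmptyInput("no segmentation records to aggregate")
    missing = {"area_mm2", "acircularity"} - set(records.columns)
    if missing:
        raise EmptyInput(f"records table lacks required columns: {sorted(missing)}")
    return records


def summarize(
    records: pd.DataFrame,
    by: Sequence[str] = ("cohort", "plexus", "criterion"),
    eye_averaged: bool = False,
) -> pd.DataFrame:
    """Per-group n, mean and SD of area (mm²) and acircularity.

    ``by`` is any subset of {cohort, plexus, criterion, observer}.  With
    ``eye_averaged=True`` each eye contributes one value (its mean across
    tracings) per group instead of all pooled segmentations.
    """
    records = _check_records(records)
    bad = set(by) - set(_VALID_KEYS)
    if bad:
        raise ValueError(f"invalid grouping keys {sorted(bad)}; allowed: {_VALID_KEYS}")
    by = list(by)
    df = records
    if eye_averaged:
        df = (
            records.groupby(by + ["eye_id"], observed=True)[["area_mm2", "acircularity"]]
            .mean()
            .reset_index()
        )
    grouped = df.groupby(by, observed=True)
    out = grouped.agg(
        n=("area_mm2", "size"),
        mean_area_mm2=("area_mm2", "mean"),
        sd_area_mm2=("area_mm2", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        mean_acircularity=("acircularity", "mean"),
        sd_acircularity=("acircularity", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
    ).reset_index()
    empty = out["n"] == 0
    if empty.any():
        logger.info("dropping %d empty groups from summary", int(empty.sum()))
        out = out[~empty].reset_index(drop=True)
    return out


def criterion_contrast(summary: pd.DataFrame) -> pd.DataFrame:
    """Initial-vs-final contrast per cell of a criterion-grouped summary.

    For every remaining grouping cell: Δmean = mean(INITIAL) − mean(FINAL),
    ΔSD likewise, and ratio = mean(FINAL) / mean(INITIAL), for both area and
    acircularity.  Signs only; no hypothesis test.
    """
    if "criterion" not in summary.columns:
        raise MissingCriterion("summary lacks a 'criterion' column")
    keys = [c for c in ("cohort", "plexus", "observer") if c in summary.columns]
    rows = []
    grouped = summary.groupby(keys, observed=True) if keys else [((), summary)]
    for cell, sub in grouped:
        crit = {Criterion(c): r for c, r in zip(sub["criterion"], sub.itertuples())}
        if Criterion.INITIAL not in crit or Criterion.FINAL not in crit:
            have = sorted(str(c) for c in sub["criterion"])
            raise MissingCriterion(f"cell {cell} has criteria {have}; need both")
        ini, fin = crit[Criterion.INITIAL], crit[Criterion.FINAL]
        row = dict(zip(keys, cell if isinstance(cell, tuple) else (cell,)))
        row.update({
            "delta_mean_area_mm2": ini.mean_area_mm2 - fin.mean_area_mm2,
            "delta_sd_area_mm2": ini.sd_area_mm2 - fin.sd_area_mm2,
            "area_ratio_final_initial": (
                fin.mean_area_mm2 / ini.mean_area_mm2 if ini.mean_area_mm2 else np.nan
            ),
            "delta_mean_acircularity": ini.mean_acircularity - fin.mean_acircularity,
            "delta_sd_acircularity": ini.sd_acircularity - fin.sd_acircularity,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def observer_variability(records: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Inter- and intra-observer SD of FAZ area per (eye, plexus, criterion).

    Inter-observer: SD across observers of each observer's series-averaged
    area (requires ≥ 2 observers).  Intra-observer: SD across series within
    an observer (requires ≥ 2 series), averaged over such observers.  Cells
    without the needed replication report NaN rather than erroring.

    Returns the per-eye table and its cohort-level means (grouped by
    cohort × plexus × criterion).
    """
    records = _check_records(records)
    rows = []
    for (eye, plexus, crit), sub in records.groupby(
        ["eye_id", "plexus", "criterion"], observed=True
    ):
        per_obs_mean = sub.groupby("observer", observed=True)["area_mm2"].mean()
        inter = per_obs_mean.std(ddof=1) if len(per_obs_mean) > 1 else np.nan
        intra_sds = [
            g.std(ddof=1)
            for _, g in sub.groupby("observer", observed=True)["area_mm2"]
            if len(g) > 1
        ]
        intra = float(np.mean(intra_sds)) if intra_sds else np.nan
        rows.append({
            "eye_id": eye,
            "cohort": sub["cohort"].iloc[0] if "cohort" in sub else "",
            "plexus": plexus,
            "criterion": crit,
            "inter_observer_sd_mm2": inter,
            "intra_observer_sd_mm2": intra,
        })
    per_eye = pd.DataFrame(rows)
    cohort_level = (
        per_eye.groupby(["cohort", "plexus", "criterion"], observed=True)[
            ["inter_observer_sd_mm2", "intra_observer_sd_mm2"]
        ]
        .mean()
        .reset_index()
    )
    return per_eye, cohort_level


def area_acircularity_pairs(records: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Paired area–acircularity table plus rank correlations.

    One row per segmentation with an ``irregular_flag`` marking
    acircularity > 0.5; the second table gives Spearman's rank correlation
    between area and acircularity per (plexus, criterion) — descriptive
    only, no p-value reported.
    """
    records = _check_records(records)
    cols = [c for c in ("record_id", "eye_id", "cohort", "plexus", "criterion",
                        "observer", "series") if c in records.columns]
    pairs = records[cols + ["area_mm2", "acircularity"]].copy()
    pairs["irregular_flag"] = pairs["acircularity"] > IRREGULARITY_THRESHOLD

    corr_rows = []
    for (plexus, crit), sub in pairs.groupby(["plexus", "criterion"], observed=True):
        if len(sub) > 2 and sub["area_mm2"].nunique() > 1:
            rho = stats.spearmanr(sub["area_mm2"], sub["acircularity"]).statistic
        else:
            rho = np.nan
        corr_rows.append({
            "plexus": plexus,
            "criterion": crit,
            "n": len(sub),
            "spearman_rho": float(rho) if rho == rho else np.nan,
        })
    return pairs, pd.DataFrame(corr_rows)


# ---------------------------------------------------------------------------
# optional figures


def plot_distributions(records: pd.DataFrame, value: str = "area_mm2", path=None):
    """Violin-style distribution of a metric per cohort × plexus × criterion."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    records = _check_records(records)
    plexuses = sorted(records["plexus"].unique())
    fig, axes = plt.subplots(1, len(plexuses), figsize=(6 * len(plexuses), 4),
                             squeeze=False)
    for ax, plexus in zip(axes[0], plexuses):
        sub = records[records["plexus"] == plexus]
        groups, labels = [], []
        for cohort in sorted(sub["cohort"].unique()):
            for crit in (Criterion.INITIAL.value, Criterion.FINAL.value):
                vals = sub[(sub["cohort"] == cohort) & (sub["criterion"] == crit)][value]
                if len(vals):
                    groups.append(vals.to_numpy())
                    labels.append(f"{cohort}\n{crit.lower()}")
        if groups:
            ax.violinplot(groups, showmeans=True)
            ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=7)
        ax.set_title(plexus)
        ax.set_ylabel(value)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_area_vs_acircularity(pairs: pd.DataFrame, path=None):
    """Scatter of acircularity against area, split by criterion and plexus."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plexuses = sorted(pairs["plexus"].unique())
    fig, axes = plt.subplots(1, len(plexuses), figsize=(6 * len(plexuses), 4),
                             squeeze=False)
    colours = {Criterion.INITIAL.value: "tab:blue", Criterion.FINAL.value: "tab:orange"}
    for ax, plexus in zip(axes[0], plexuses):
        sub = pairs[pairs["plexus"] == plexus]
        for crit, col in colours.items():
            s = sub[sub["criterion"] == crit]
            ax.scatter(s["area_mm2"], s["acircularity"], s=6, alpha=0.5,
                       color=col, label=crit.lower())
        ax.axhline(IRREGULARITY_THRESHOLD, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("area (mm²)")
        ax.set_ylabel("acircularity")
        ax.set_title(plexus)
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
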