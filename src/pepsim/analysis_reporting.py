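"""Condition means, congruency/CSPC effects, and summary figures.

Aggregation follows the field's convention: cell means are computed within
each simulated participant first (correct, non-timeout trials only for RT;
errors as a percentage of non-timeout trials), then averaged across
participants unweighted.  The CSPC effect is

    (incongruent - congruent | MC context) - (incongruent - congruent | MI context)

so a positive value is a proportion-congruency effect in the standard
direction (larger congruency effect where trials are mostly congruent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .experiment_designs import CONGRUENT, INCONGRUENT, MC, MI

_CELLS = [(MC, CONGRUENT), (MC, INCONGRUENT), (MI, CONGRUENT), (MI, INCONGRUENT)]


@dataclass(frozen=True)
class EffectSummary:
    """Congruency effects per context and their difference (the CSPC effect),
    with the per-participant effect distribution and a one-sample t-test of
    the CSPC effect against zero."""

    congruency_effect_mc: float
    congruency_effect_mi: float
    cspc_effect: float
    per_participant: pd.Series
    t_statistic: float
    p_value: float
    n_participants: int


def _filter(results: pd.DataFrame, item_type: Optional[str]) -> pd.DataFrame:
    if item_type is not None:
        results = results[results["item_type"] == item_type]
    if results.empty:
        raise ValueError("no trials left after item_type filtering")
    return results


def summarize(results: pd.DataFrame, item_type: Optional[str] = None) -> pd.DataFrame:
    """Grand condition summary: mean correct RT, error %, and trial counts
    per context x congruency cell (participant means averaged unweighted).

    Cells with no usable trials are reported as NaN, never silently zero.
    """
    results = _filter(results, item_type)
    valid = results[~results["timeout"]]
    rows = []
    for ctx, cong in _CELLS:
        cell = valid[(valid["context"] == ctx) & (valid["congruency"] == cong)]
        if cell.empty:
            rows.append({"context": ctx, "congruency": cong,
                         "item_type": item_type or "all",
                         "mean_rt": np.nan, "error_pct": np.nan, "n": 0})
            continue
        per_rt = cell[cell["accuracy"]].groupby("participant")["rt_cycles"].mean()
        per_err = cell.groupby("participant")["accuracy"] \
                      .apply(lambda a: 100.0 * (1.0 - a.mean()))
        rows.append({"context": ctx, "congruency": cong,
                     "item_type": item_type or "all",
                     "mean_rt": float(per_rt.mean()) if len(per_rt) else np.nan,
                     "error_pct": float(per_err.mean()),
                     "n": int(len(cell))})
    return pd.DataFrame(rows)


def per_participant_cells(results: pd.DataFrame, item_type: Optional[str] = None,
                          measure: str = "rt") -> pd.DataFrame:
    """Participant x (context, congruency) cell means.

    ``measure`` is ``"rt"`` (mean correct, non-timeout RT) or ``"error"``
    (error % of non-timeout trials).
    """
    results = _filter(results, item_type)
    valid = results[~results["timeout"]]
    if measure == "rt":
        data = valid[valid["accuracy"]]
        cells = data.groupby(["participant", "context", "congruency"])["rt_cycles"].mean()
    elif measure == "error":
        cells = valid.groupby(["participant", "context", "congruency"])["accuracy"] \
                     .apply(lambda a: 100.0 * (1.0 - a.mean()))
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return cells.unstack(["context", "congruency"])


def cspc_effect(results: pd.DataFrame, item_type: Optional[str] = None,
                measure: str = "rt") -> EffectSummary:
    """Context-specific proportion-congruency effect across participants."""
    cells = per_participant_cells(results, item_type, measure)
    for key in _CELLS:
        if key not in cells.columns:
            raise ValueError(f"missing condition cell {key}")
    cells = cells.dropna()
    if cells.empty:
        raise ValueError("no participant has all four condition cells")
    eff_mc = cells[(MC, INCONGRUENT)] - cells[(MC, CONGRUENT)]
    eff_mi = cells[(MI, INCONGRUENT)] - cells[(MI, CONGRUENT)]
    per = eff_mc - eff_mi
    if len(per) > 1 and per.std(ddof=1) > 0:
        t, p = stats.ttest_1samp(per, 0.0)
    else:
        t, p = np.nan, np.nan
    return EffectSummary(
        congruency_effect_mc=float(eff_mc.mean()),
        congruency_effect_mi=float(eff_mi.mean()),
        cspc_effect=float(per.mean()),
        per_participant=per,
        t_statistic=float(t), p_value=float(p),
        n_participants=int(len(per)),
    )


def congruency_effect(results: pd.DataFrame, item_type: Optional[str] = None,
                      measure: str = "rt") -> pd.Series:
    """Per-participant overall congruency effect (both contexts pooled)."""
    results = _filter(results, item_type)
    valid = results[~results["timeout"]]
    data = valid[valid["accuracy"]] if measure == "rt" else valid
    if measure == "rt":
        cells = data.groupby(["participant", "congruency"])["rt_cycles"].mean().unstack()
    else:
        cells = valid.groupby(["participant", "congruency"])["accuracy"] \
                     .apply(lambda a: 100.0 * (1.0 - a.mean())).unstack()
    return (cells[INCONGRUENT] - cells[CONGRUENT]).dropna()


def contingency_effect(results: pd.DataFrame) -> pd.Series:
    """Per-participant low-minus-high contingency RT cost, incongruent
    trials only (so the contrast is congruency-free); requires a results
    table from the contingency-learning design."""
    if "contingency" not in results.columns:
        raise ValueError("results carry no contingency labels")
    valid = results[(~results["timeout"]) & results["accuracy"]
                    & (results["congruency"] == INCONGRUENT)]
    cells = valid.groupby(["participant", "contingency"])["rt_cycles"].mean().unstack()
    return (cells["low"] - cells["high"]).dropna()


def effects_table(effect: EffectSummary) -> pd.DataFrame:
    return pd.DataFrame([{
        "congruency_effect_MC": effect.congruency_effect_mc,
        "congruency_effect_MI": effect.congruency_effect_mi,
        "cspc_effect": effect.cspc_effect,
        "t": effect.t_statistic, "p": effect.p_value,
        "n_participants": effect.n_participants,
    }])


def plot_condition_means(summaries, path, titles=None):
    """Bar panels of the four context x congruency cell means.

    ``summaries`` is one summary frame (from :func:`summarize`) or a list of
    them, one panel each; the figure is written to ``path``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(summaries, pd.DataFrame):
        summaries = [summaries]
    titles = titles or [f"panel {i + 1}" for i in range(len(summaries))]
    fig, axes = plt.subplots(1, len(summaries),
                             figsize=(4.0 * len(summaries), 3.2), squeeze=False)
    for ax, summary, title in zip(axes[0], summaries, titles):
        x = np.arange(2)
        width = 0.35
        for k, cong in enumerate((CONGRUENT, INCONGRUENT)):
            vals = [float(summary[(summary["context"] == ctx)
                                  & (summary["congruency"] == cong)]["mean_rt"].iloc[0])
                    for ctx in (MC, MI)]
            ax.bar(x + (k - 0.5) * width, vals, width, label=cong)
        ax.set_xticks(x)
        ax.set_xticklabels(["mostly congruent", "mostly incongruent"])
        ax.set_ylabel("mean correct RT (cycles)")
        ax.set_title(title)
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
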