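"""Behavioral summary statistics: learning curves and switch identification.

Learning curves report, per game type and trial index, the mean across
sessions of a per-trial statistic (each session first averaged over its
games of that type).  The performance curve uses the *expected* reward
probability of the realized stimulus under the true rule — the number of
rewarding features mapped through the task's interpolation table — rather
than the noisy 0/1 outcome.  The uncertainty band is +/-1 s.e.m. across
sessions (agents).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import task
from .task import Session, Trial


def _curve_table(cohort: Sequence[Session], stat) -> pd.DataFrame:
    """Tidy (game_type, trial) table of the across-session mean and s.e.m."""
    rows = []
    for session in cohort:
        for spec, trials in session.games:
            choices, stims, _ = task.game_arrays(trials)
            vals = stat(spec, choices, stims)
            for t, v in enumerate(vals, start=1):
                rows.append(
                    (session.session_id, spec.game_type, t, float(v))
                )
    df = pd.DataFrame(rows, columns=["session", "game_type", "trial", "value"])
    per_session = (
        df.groupby(["game_type", "trial", "session"])["value"].mean().reset_index()
    )
    g = per_session.groupby(["game_type", "trial"])["value"]
    out = g.agg(["mean", "count"]).reset_index()
    sem = g.std(ddof=1) / np.sqrt(g.count())
    out["sem"] = sem.values
    out = out.rename(columns={"count": "n_sessions"})
    return out[["game_type", "trial", "mean", "sem", "n_sessions"]]


def reward_prob_curve(cohort: Sequence[Session]) -> pd.DataFrame:
    """Expected reward probability of the realized stimulus, by type and trial."""

    def stat(spec, choices, stims):
        return task.P_REWARD[spec.true_rule.index, stims]

    return _curve_table(cohort, stat)


def features_selected_curve(cohort: Sequence[Session]) -> pd.DataFrame:
    """Number of dimensions the agent selected (0-3), by type and trial."""

    def stat(spec, choices, stims):
        return task.CONFIG_NDIMS[choices].astype(float)

    return _curve_table(cohort, stat)


def identify_switch_trials(trials: Sequence[Trial]) -> np.ndarray:
    """Flag trials whose configuration differs from the previous trial's.

    Behavioral switch identification: any change in choice counts, and the
    first trial is never a switch.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    choices = np.array([t.choice.index for t in trials])
    flags = np.zeros(len(trials), dtype=bool)
    flags[1:] = choices[1:] != choices[:-1]
    return flags


def plot_curves(curve: pd.DataFrame, path=None, ylabel: str = "value"):
    """Small-multiples plot of a curve table: one panel per complexity,
    known/unknown as separate lines; written to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=True)
    for ax, d in zip(axes, (1, 2, 3)):
        for knowledge, color in (("known", "tab:red"), ("unknown", "tab:blue")):
            sub = curve[curve["game_type"] == f"{d}D-{knowledge}"]
            if sub.empty:
                continue
            ax.plot(sub["trial"], sub["mean"], color=color, label=knowledge)
            ax.fill_between(
                sub["trial"],
                sub["mean"] - sub["sem"],
                sub["mean"] + sub["sem"],
                color=color,
                alpha=0.25,
                linewidth=0,
            )
        ax.set_title(f"{d}D-relevant")
        ax.set_xlabel("trial")
    axes[0].set_ylabel(ylabel)
    axes[0].legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
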