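"""Figure and Markdown rendering of simulation results.

Per scenario, a panel figure mirrors how capacity-planning results are read:
weekly capacity profiles with the vacation windows shaded, the ready-to-start
queue, and delivered fraction-units against available capacity with overtime
and idle called out.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .engine import SimulationResult
from .scenarios import SuiteResult, VacationScenario

__all__ = ["render_scenario_figure", "render_report"]

log = logging.getLogger("rtflow")

_PANELS = {
    "capacity": ("prep_capacity", "treat_capacity"),
    "ready queue": ("ready_to_start",),
    "delivered vs capacity": ("fractions_delivered", "treat_capacity", "overtime_units", "idle_units"),
}


def _shade_windows(ax, scenario: VacationScenario | None) -> None:
    if scenario is None:
        return
    ax.axvspan(scenario.prep_weeks.start, scenario.prep_weeks.stop,
               color="tab:blue", alpha=0.10, lw=0)
    ax.axvspan(scenario.treat_weeks.start, scenario.treat_weeks.stop,
               color="tab:orange", alpha=0.12, lw=0)


def render_scenario_figure(
    weekly: pd.DataFrame,
    scenario: VacationScenario | None,
    path: str | Path,
    title: str = "",
) -> Path | None:
    """Three-panel weekly figure for one run; skips panels whose columns are absent."""
    panels = {
        name: cols for name, cols in _PANELS.items()
        if all(c in weekly.columns for c in cols[:2])
    }
    for name in _PANELS.keys() - panels.keys():
        log.warning("panel %r skipped: metric columns missing", name)
    if not panels:
        return None
    fig, axes = plt.subplots(len(panels), 1, figsize=(8, 2.6 * len(panels)), sharex=True)
    if len(panels) == 1:
        axes = [axes]
    weeks = weekly.index
    for ax, (name, cols) in zip(axes, panels.items()):
        if name == "capacity":
            ax.step(weeks, weekly["prep_capacity"], where="mid", label="prep [patients/wk]")
            ax.step(weeks, weekly["treat_capacity"], where="mid", label="treat [units/wk]")
        elif name == "ready queue":
            ax.plot(weeks, weekly["ready_to_start"], label="ready to start [patients]")
        else:
            ax.plot(weeks, weekly["fractions_delivered"], label="delivered [units/wk]")
            ax.plot(weeks, weekly["treat_capacity"], ls="--", label="capacity [units/wk]")
            if "overtime_units" in weekly:
                ax.bar(weeks, weekly["overtime_units"], color="tab:red", alpha=0.6, label="overtime")
            if "idle_units" in weekly:
                ax.bar(weeks, -weekly["idle_units"], color="tab:gray", alpha=0.5, label="idle (below axis)")
        _shade_windows(ax, scenario)
        ax.set_ylabel(name)
        ax.legend(loc="upper left", fontsize=7)
    axes[-1].set_xlabel("week")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def render_report(
    suite: SuiteResult,
    out_dir: str | Path,
    plots: bool = True,
) -> Path:
    """Write a Markdown comparison report (+ per-scenario figures) to ``out_dir``.

    Returns the path of the Markdown file.  Figures require the suite to have
    been run with ``keep_results=True``; otherwise only the table/rankings
    are written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [suite.to_markdown()]
    if plots and suite.results:
        lines.append("\n## Figures\n")
        for sid, res in sorted(suite.results.items()):
            fname = f"scenario_{sid.lstrip('#')}.png"
            made = render_scenario_figure(
                res.weekly(), res.scenario, out_dir / fname, title=f"scenario {sid}"
            )
            if made is not None:
                lines.append(f"- {sid}: ![{sid}]({fname})")
    md = out_dir / "comparison.md"
    md.write_text("\n".join(lines) + "\n")
    return md
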