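"""Figure helpers: trajectory plane plots and the error-vs-BMI scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .anthropometrics import BmiAnova, weight_group
from .trajectory import GlobalTrajectory, LinearAgeModel, evaluate_trajectory

__all__ = ["plot_trajectories", "plot_bmi_scatter"]


def plot_trajectories(traj: GlobalTrajectory,
                      subject_models_young: list[LinearAgeModel],
                      subject_models_old: list[LinearAgeModel],
                      path: str | Path, *, components: tuple[int, int] = (0, 1)) -> None:
    """PC-plane plot: thin per-subject arrows, thick cohort arrows, global curve.

    Arrows run from each model evaluated at the start of its age range to
    its end; the global trajectory is drawn over a dense age grid. Only a
    2-D projection of the K-dimensional trajectory is shown.
    """
    i, j = components
    fig, ax = plt.subplots(figsize=(7, 6))

    def _arrow(model: LinearAgeModel, **kw):
        p0 = model(model.age_range[0])
        p1 = model(model.age_range[1])
        ax.annotate("", xy=(p1[i], p1[j]), xytext=(p0[i], p0[j]),
                    arrowprops=dict(arrowstyle="->", **kw))

    for m in subject_models_young:
        _arrow(m, color="tab:blue", alpha=0.35, lw=0.8)
    for m in subject_models_old:
        _arrow(m, color="tab:orange", alpha=0.35, lw=0.8)
    _arrow(traj.young, color="tab:blue", lw=2.5)
    _arrow(traj.old, color="tab:orange", lw=2.5)

    ages = np.linspace(traj.young.age_range[0], traj.old.age_range[1], 200)
    curve = evaluate_trajectory(traj, ages, allow_extrapolation=True)
    ax.plot(curve[:, i], curve[:, j], color="green", lw=2.0, label="global trajectory")
    ax.set_xlabel(f"PC{i + 1}")
    ax.set_ylabel(f"PC{j + 1}")
    ax.set_title(f"Ageing trajectories ({traj.sex or 'unspecified sex'})")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bmi_scatter(delta_percentile: np.ndarray, mean_error: np.ndarray,
                     start_percentile: np.ndarray, anova: BmiAnova,
                     path: str | Path, *, title: str = "") -> None:
    """Scatter of per-subject mean error vs ΔBMI percentile, three weight
    groups by starting percentile, with the fitted regression line."""
    groups = np.array([weight_group(p) for p in start_percentile])
    fig, ax = plt.subplots(figsize=(6, 5))
    for g, c in (("<25", "tab:blue"), ("25-75", "tab:green"), (">75", "tab:red")):
        sel = groups == g
        if sel.any():
            ax.scatter(delta_percentile[sel], mean_error[sel], s=25, color=c, label=g)
    xs = np.linspace(min(delta_percentile), max(delta_percentile), 50)
    ax.plot(xs, anova.intercept + anova.slope * xs, "k-",
            label=f"fit (p={anova.p_value:.3g})")
    ax.set_xlabel("change of BMI percentile")
    ax.set_ylabel("mean prediction error (mm)")
    if title:
        ax.set_title(title)
    ax.legend(title="start percentile")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
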