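"""Optional diagnostic figures for a finished analysis run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cusp.geometry import bifurcation_set
from .pipeline import AnalysisReport


def plot_cusp_projection(report: AnalysisReport, path: str | Path) -> None:
    """Control-plane projection: per-year (alpha, beta) over the shaded
    bistable cusp area; bistable years red, stable years black."""
    pts = report.cusp_fit.per_year
    betas = np.array([p.beta for p in pts])
    bmax = max(0.5, float(betas.max()))
    poly = bifurcation_set(np.linspace(0.0, bmax * 1.1, 200))
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.fill_betweenx(poly["beta"], poly["alpha_low"], poly["alpha_high"],
                     color="0.8", label="bistable (cusp) area")
    for p in pts:
        ax.plot(p.alpha, p.beta, "o", ms=4,
                color="crimson" if p.state_class == "bistable" else "black")
        ax.annotate(str(p.year % 100), (p.alpha, p.beta), fontsize=5,
                    textcoords="offset points", xytext=(3, 2))
    ax.set_xlabel("asymmetry  alpha")
    ax.set_ylabel("bifurcation  beta")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_state_series(report: AnalysisReport, path: str | Path) -> None:
    """Observed vs cusp-predicted state over time, regime boundaries dashed."""
    t = report.table
    years = t.years
    state = t.column(report.cusp_fit.state_var)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(years, state, "--", color="0.5", label="observed")
    colors = ["crimson" if p.state_class == "bistable" else "black"
              for p in report.cusp_fit.per_year]
    ax.plot(years, report.predicted_state, "-", color="black", lw=1)
    ax.scatter(years, report.predicted_state, c=colors, s=16, zorder=3,
               label="predicted (red = bistable year)")
    for seg in report.segmentations:
        if seg.series_name == report.cusp_fit.state_var:
            for y in seg.changepoint_years:
                ax.axvline(y + 0.5, ls=":", color="0.7")
    ax.set_xlabel("year")
    ax.set_ylabel(report.cusp_fit.state_var)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
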