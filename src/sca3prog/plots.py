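"""Publication-style figures for a fitted progression model."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .design import build_design, registry_spec
from .diagnostics import DiagnosticsBundle
from .errors import Sca3ProgError
from .lmm import FitResult, blup_random_effects, fit_lmm

__all__ = ["render_figures"]


def _spaghetti(ax, cohort: pd.DataFrame, ycol: str):
    for _, sub in cohort.groupby("subject_id"):
        ax.plot(sub["duration"], sub[ycol], "-o", ms=2, lw=0.6, alpha=0.5)


def render_figures(cohort: pd.DataFrame, fit: FitResult,
                   bundle: DiagnosticsBundle, out_dir, fmt: str = "png"
                   ) -> dict:
    """Write the diagnostic figure set; returns paths and the fig-2A slope.

    Figures: (1a) observed trajectories with the single-slope and two-segment
    population mean lines; (1b) BLUP-predicted individual trajectories;
    (2a) predicted vs actual scores with OLS and identity lines; (2b)
    residuals vs duration; (3a) residual histogram with density; (3b) normal
    Q-Q plot of standardized residuals.  Deterministic given its inputs.
    """
    if len(cohort) == 0:
        raise Sca3ProgError("cannot render figures for an empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    knot = fit.spec.knot if (fit.spec and fit.spec.knot) else 13.0
    lm1 = fit_lmm(build_design(cohort, registry_spec("LM1")))
    pm1 = fit_lmm(build_design(cohort, registry_spec("PM1", knot)))
    dt_grid = np.linspace(cohort["duration"].min(), cohort["duration"].max(), 100)

    # 1a: observed spaghetti + population mean lines
    fig, ax = plt.subplots(figsize=(6, 4))
    _spaghetti(ax, cohort, "icars")
    ax.plot(dt_grid, lm1.coef("intercept") + lm1.coef("dt") * dt_grid,
            color="purple", lw=2, label="single slope")
    d1 = np.where(dt_grid <= knot, dt_grid - knot, 0.0)
    d2 = np.where(dt_grid > knot, dt_grid - knot, 0.0)
    ax.plot(dt_grid, pm1.coef("intercept") + pm1.coef("d1") * d1
            + pm1.coef("d2") * d2, color="black", lw=2, label="two segments")
    ax.axvline(knot, color="gray", ls=":", lw=1)
    ax.set_xlabel("disease duration (years)")
    ax.set_ylabel("ICARS")
    ax.legend()
    fig.tight_layout()
    paths["fig1a_trajectories"] = out_dir / f"fig1a_trajectories.{fmt}"
    fig.savefig(paths["fig1a_trajectories"])
    plt.close(fig)

    # 1b: BLUP-predicted individual trajectories
    design = fit.design
    b = blup_random_effects(fit, design)
    codes = pd.factorize(design.groups)[0]
    pred = design.X @ fit.beta + np.einsum(
        "nq,nq->n", design.Z, b.to_numpy()[codes])
    pred_df = pd.DataFrame({"subject_id": design.groups,
                            "duration": cohort["duration"].to_numpy(),
                            "pred": pred})
    fig, ax = plt.subplots(figsize=(6, 4))
    _spaghetti(ax, pred_df, "pred")
    ax.set_xlabel("disease duration (years)")
    ax.set_ylabel(f"predicted ICARS ({fit.spec.name})")
    fig.tight_layout()
    paths["fig1b_predicted"] = out_dir / f"fig1b_predicted.{fmt}"
    fig.savefig(paths["fig1b_predicted"])
    plt.close(fig)

    # 2a: predicted vs actual with OLS + identity lines
    actual = design.y
    predicted = bundle.predicted
    slope, intercept = np.polyfit(actual, predicted, 1)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(actual, predicted, s=8, alpha=0.5)
    lims = np.asarray([min(actual.min(), predicted.min()),
                       max(actual.max(), predicted.max())])
    ax.plot(lims, lims, "k--", lw=1, label="identity")
    ax.plot(lims, intercept + slope * lims, color="red", lw=1.5,
            label=f"OLS slope = {slope:.3f}")
    ax.set_xlabel("actual ICARS")
    ax.set_ylabel("predicted ICARS")
    ax.set_title(f"predicted vs actual (slope {slope:.3f})")
    ax.legend()
    fig.tight_layout()
    paths["fig2a_pred_vs_actual"] = out_dir / f"fig2a_pred_vs_actual.{fmt}"
    fig.savefig(paths["fig2a_pred_vs_actual"])
    plt.close(fig)

    # 2b: residual (predicted - actual) vs duration
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(bundle.durations, bundle.residuals, s=8, alpha=0.5)
    ax.axhline(0.0, color="black", ls="--", lw=1)
    ax.set_xlabel("disease duration (years)")
    ax.set_ylabel("residual (predicted - actual)")
    fig.tight_layout()
    paths["fig2b_residuals"] = out_dir / f"fig2b_residuals.{fmt}"
    fig.savefig(paths["fig2b_residuals"])
    plt.close(fig)

    # 3a: residual histogram + density curve
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(bundle.residuals, bins=bundle.hist_edges, density=True,
            alpha=0.6, edgecolor="white")
    ax.plot(bundle.density_x, bundle.density_y, color="blue", lw=1.5)
    ax.set_xlabel("residual (ICARS points)")
    ax.set_ylabel("density")
    fig.tight_layout()
    paths["fig3a_histogram"] = out_dir / f"fig3a_histogram.{fmt}"
    fig.savefig(paths["fig3a_histogram"])
    plt.close(fig)

    # 3b: normal Q-Q plot of standardized residuals
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(bundle.qq_theoretical, bundle.qq_observed, "-o", ms=3,
            color="blue", lw=0.8)
    lims = np.asarray([bundle.qq_theoretical.min(), bundle.qq_theoretical.max()])
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("theoretical quantiles")
    ax.set_ylabel("standardized residuals")
    fig.tight_layout()
    paths["fig3b_qq"] = out_dir / f"fig3b_qq.{fmt}"
    fig.savefig(paths["fig3b_qq"])
    plt.close(fig)

    return {"paths": {k: str(v) for k, v in paths.items()},
            "fig2a_slope": float(slope)}
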