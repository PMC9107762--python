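"""Residual diagnostics for a fitted growth model.

Residuals follow the predicted-minus-actual sign convention.  Two modes:

* ``"fixed"`` -- population-level residuals, prediction = X beta;
* ``"subject"`` -- subject-level residuals, prediction adds the BLUP
  random-effect contribution Z b_i (the individualized trajectory).

The numeric stand-in for the visual normality checks (histogram/Q-Q) is a
Shapiro-Wilk test on the standardized residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrices
from .errors import Sca3ProgError
from .lmm import FitResult, blup_random_effects

__all__ = ["DiagnosticsBundle", "residual_diagnostics"]


@dataclass
class DiagnosticsBundle:
    """Residuals and normality-check material for one fit."""

    mode: str
    predicted: np.ndarray
    residuals: np.ndarray           # predicted - actual, ICARS points
    standardized: np.ndarray
    durations: np.ndarray
    qq_theoretical: np.ndarray      # sorted normal quantiles
    qq_observed: np.ndarray         # sorted standardized residuals
    hist_edges: np.ndarray
    hist_density: np.ndarray
    density_x: np.ndarray
    density_y: np.ndarray
    shapiro_stat: float
    shapiro_p: float


def residual_diagnostics(fit: FitResult, design: DesignMatrices | None = None,
                         mode: str = "subject") -> DiagnosticsBundle:
    """Compute the residual bundle for a converged fit."""
    design = design or fit.design
    if design is None:
        raise Sca3ProgError("diagnostics need the design the model was fitted to")
    if mode not in ("fixed", "subject"):
        raise Sca3ProgError("mode must be 'fixed' or 'subject'")

    predicted = design.X @ fit.beta
    if mode == "subject":
        b = blup_random_effects(fit, design)
        codes = pd.factorize(design.groups)[0]
        order = {s: i for i, s in enumerate(b.index)}
        # align BLUP rows to factorize codes
        b_mat = b.to_numpy()[[order[s] for s in pd.unique(design.groups)]]
        predicted = predicted + np.einsum("nq,nq->n", design.Z, b_mat[codes])

    residuals = predicted - design.y
    sd = residuals.std(ddof=1) if len(residuals) > 1 else 1.0
    standardized = (residuals - residuals.mean()) / (sd if sd > 0 else 1.0)

    osm, osr = stats.probplot(standardized, dist="norm", fit=False)
    edges = np.histogram_bin_edges(residuals, bins="auto")
    density, _ = np.histogram(residuals, bins=edges, density=True)
    if len(residuals) > 1 and residuals.std() > 0:
        kde = stats.gaussian_kde(residuals)
        xs = np.linspace(residuals.min(), residuals.max(), 200)
        ys = kde(xs)
    else:
        xs = np.asarray([0.0])
        ys = np.asarray([1.0])
    if len(standardized) >= 3:
        sw_stat, sw_p = stats.shapiro(standardized)
    else:
        sw_stat, sw_p = np.nan, np.nan

    durations = design.Z[:, 0] * 0.0  # placeholder if no dt column
    # recover raw duration from the design: linear models carry dt in Z,
    # piece-wise models carry d1/d2 with dt = d1 + d2 + knot
    if "dt" in design.random_names:
        durations = design.Z[:, design.random_names.index("dt")]
    elif {"d1", "d2"} <= set(design.random_names) and design.spec is not None:
        i1 = design.random_names.index("d1")
        i2 = design.random_names.index("d2")
        durations = design.Z[:, i1] + design.Z[:, i2] + design.spec.knot

    return DiagnosticsBundle(
        mode=mode, predicted=predicted, residuals=residuals,
        standardized=standardized, durations=durations,
        qq_theoretical=osm, qq_observed=osr,
        hist_edges=edges, hist_density=density,
        density_x=xs, density_y=ys,
        shapiro_stat=float(sw_stat), shapiro_p=float(sw_p),
    )
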