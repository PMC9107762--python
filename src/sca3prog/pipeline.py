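"""End-to-end progression analysis: knot search, model ladder, comparisons.

The analysis proceeds in three steps on a cleaned cohort:

1. grid-search the knot (inflection point) of the base two-segment model over
   a candidate grid of durations, selecting by minimum AIC;
2. fit the full ladder of growth models at the selected knot and assemble a
   published-style coefficient/fit-statistics table;
3. compare models by likelihood-ratio (ANOVA) tests under three schemes:
   (a) every extension of the single-slope linear model vs LM1,
   (b) every extension of the base piece-wise model vs PM1, and
   (c) each piece-wise model vs its linear counterpart.

A collinearity check (variance inflation factor of onset age against CAG
repeat length) guards the models that carry both covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import add_rao, compute_rao
from .design import build_design, registry_spec
from .errors import NonNestedError, Sca3ProgError
from .lmm import FitResult, LRTResult, fit_lmm, lrt
from .published import LADDER_MODELS

__all__ = [
    "DEFAULT_KNOT_GRID",
    "KnotSearchResult",
    "LadderResult",
    "knot_search",
    "fit_ladder",
    "compare_models",
    "vif_from_r2",
    "collinearity_check",
    "CollinearityResult",
]

#: the 18-candidate knot grid (years of disease duration)
DEFAULT_KNOT_GRID = (3.0, 5.0, 7.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0,
                     16.0, 17.0, 18.0, 19.0, 20.0, 25.0, 30.0, 35.0)

#: subjects contributing visits on each side of a knot below which the
#: candidate is flagged as thin
_MIN_SIDE_SUBJECTS = 5


@dataclass
class KnotSearchResult:
    """Per-candidate fit criteria and the AIC-selected knot."""

    table: pd.DataFrame  # knot, loglik, aic, bic, n_pre, n_post, thin
    best_knot: float
    selection_rule: str
    base_model: str

    def fit_at(self, cohort: pd.DataFrame, knot: float | None = None) -> FitResult:
        knot = self.best_knot if knot is None else knot
        spec = registry_spec(self.base_model, knot)
        return fit_lmm(build_design(cohort, spec))


def knot_search(cohort: pd.DataFrame, candidates=DEFAULT_KNOT_GRID,
                base: str = "PM1") -> KnotSearchResult:
    """Fit the base piece-wise model at each candidate knot; select by AIC.

    Candidates outside the observed duration range are not admissible; a
    candidate with fewer than five subjects contributing visits on either
    side is fitted but flagged thin.  Ties on AIC break by BIC, then by the
    smaller knot; the result is invariant to candidate order.
    """
    dt = cohort["duration"].to_numpy(dtype=float)
    lo, hi = dt.min(), dt.max()
    admissible = sorted({float(c) for c in candidates if lo < c < hi})
    if not admissible:
        raise Sca3ProgError(
            f"no candidate knot lies strictly inside the observed duration "
            f"range ({lo:.3g}, {hi:.3g})"
        )
    rows = []
    for knot in admissible:
        spec = registry_spec(base, knot)
        fit = fit_lmm(build_design(cohort, spec))
        pre = cohort.loc[cohort["duration"] <= knot, "subject_id"].nunique()
        post = cohort.loc[cohort["duration"] > knot, "subject_id"].nunique()
        rows.append({
            "knot": knot, "loglik": fit.loglik, "aic": fit.aic, "bic": fit.bic,
            "n_subjects_pre": pre, "n_subjects_post": post,
            "thin": min(pre, post) < _MIN_SIDE_SUBJECTS,
        })
    table = pd.DataFrame(rows)
    best = min(rows, key=lambda r: (r["aic"], r["bic"], r["knot"]))
    return KnotSearchResult(table=table, best_knot=best["knot"],
                            selection_rule="min_aic", base_model=base)


@dataclass
class LadderResult:
    """Fits of the requested ladder models on one cohort at one knot."""

    fits: dict[str, FitResult]
    errors: dict[str, str]
    knot: float

    def coefficient_table(self) -> pd.DataFrame:
        """Published-style table: one column per model, coefficient rows
        formatted as ``estimate (SE), p`` at 3 decimals, then fit statistics."""
        terms: list[str] = []
        for fit in self.fits.values():
            for t in fit.fixed_names:
                if t not in terms:
                    terms.append(t)
        data = {}
        for name, fit in self.fits.items():
            col = {}
            bd = fit.beta_dict()
            sd = dict(zip(fit.fixed_names, fit.se))
            pdn = dict(zip(fit.fixed_names, fit.wald_p))
            for t in terms:
                if t in bd:
                    p = pdn[t]
                    p_str = "<0.001" if p < 0.001 else f"{p:.3f}"
                    col[t] = f"{bd[t]:.3f} ({sd[t]:.3f}) P={p_str}"
                else:
                    col[t] = "-"
            col["AIC"] = f"{fit.aic:.3f}"
            col["BIC"] = f"{fit.bic:.3f}"
            col["logLik"] = f"{fit.loglik:.3f}"
            col["Conditional R2"] = f"{fit.r2_conditional:.3f}"
            col["Marginal R2"] = f"{fit.r2_marginal:.3f}"
            data[name] = col
        stat_rows = ["AIC", "BIC", "logLik", "Conditional R2", "Marginal R2"]
        return pd.DataFrame(data).reindex(terms + stat_rows)

    def tidy(self) -> pd.DataFrame:
        """Long-format numeric table of all coefficients across models."""
        rows = []
        for name, fit in self.fits.items():
            for t, b, s, p in zip(fit.fixed_names, fit.beta, fit.se, fit.wald_p):
                rows.append({"model": name, "term": t, "estimate": float(b),
                             "se": float(s), "p": float(p)})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "knot": self.knot,
            "fits": {name: fit.to_dict() for name, fit in self.fits.items()},
            "errors": dict(self.errors),
        }


def fit_ladder(cohort: pd.DataFrame, names=LADDER_MODELS,
               knot: float = 13.0) -> LadderResult:
    """Fit every named ladder model on the same cohort at a fixed knot.

    A model whose covariate is unavailable records a per-model error; the
    remaining models are still fitted.
    """
    needs_rao = any("6" in str(n) for n in names)
    data = add_rao(cohort) if needs_rao else cohort
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    for name in names:
        try:
            spec = registry_spec(name, knot)
            fits[spec.name] = fit_lmm(build_design(data, spec))
        except Sca3ProgError as exc:
            errors[str(name)] = str(exc)
    return LadderResult(fits=fits, errors=errors, knot=float(knot))


# the published comparison schemes: (scheme, null model, full model)
_SCHEME_A = [("a", "LM1", m) for m in ("LM2", "LM3", "LM4", "QM1", "PM1")]
_SCHEME_B = [("b", "PM1", m) for m in
             ("QM1", "PM2", "PM2c", "PM3", "PM3c", "PM4", "PM4c")]
_SCHEME_C = [("c", lin, pm) for lin, pm in
             (("LM1", "PM1"), ("LM2", "PM2"), ("LM2", "PM2c"),
              ("LM3", "PM3"), ("LM3", "PM3c"), ("LM4", "PM4"),
              ("LM4", "PM4c"))]


def compare_models(ladder: LadderResult) -> pd.DataFrame:
    """ANOVA (likelihood-ratio) table over the three comparison schemes.

    Non-nested pairs (the quadratic vs the piece-wise base model) are
    reported with their AIC difference only, the LRT marked not applicable.
    Pairs whose members were not fitted are omitted with a note.
    """
    rows = []
    for scheme, null_name, full_name in _SCHEME_A + _SCHEME_B + _SCHEME_C:
        row = {"scheme": scheme, "null": null_name, "full": full_name,
               "stat": np.nan, "df": np.nan, "p": np.nan,
               "aic_diff": np.nan, "note": ""}
        if null_name not in ladder.fits or full_name not in ladder.fits:
            row["note"] = "model(s) not fitted"
            rows.append(row)
            continue
        null_fit, full_fit = ladder.fits[null_name], ladder.fits[full_name]
        row["aic_diff"] = full_fit.aic - null_fit.aic
        try:
            res: LRTResult = lrt(null_fit, full_fit)
            row.update(stat=res.stat, df=res.df, p=res.p)
        except NonNestedError:
            row["note"] = "not nested: LRT not applicable, AIC difference only"
        rows.append(row)
    return pd.DataFrame(rows)


def vif_from_r2(r2: float) -> float:
    """Variance inflation factor 1 / (1 - R^2)."""
    if not (0.0 <= r2 < 1.0):
        raise Sca3ProgError(f"R^2 must be in [0, 1), got {r2}")
    return 1.0 / (1.0 - r2)


@dataclass
class CollinearityResult:
    r_squared: float
    vif: float
    threshold: float
    verdict: str


def collinearity_check(cohort: pd.DataFrame, threshold: float = 5.0
                       ) -> CollinearityResult:
    """VIF of onset age against CAG repeat length (subject-level regression).

    The verdict is "acceptable" below the threshold (5 by convention,
    configurable to 10), else "problematic".
    """
    r2 = compute_rao(cohort).r_squared
    vif = vif_from_r2(r2)
    verdict = "acceptable" if vif < threshold else "problematic"
    return CollinearityResult(r_squared=r2, vif=vif, threshold=threshold,
                              verdict=verdict)
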