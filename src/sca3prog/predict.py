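"""Fixed-effect ICARS prediction from a coefficient set.

A :class:`CoefficientSet` is a model name, a knot, and a map of fixed-effect
terms to values -- taken from a fresh fit or transcribed from the published
columns (:mod:`sca3prog.published`).  Predictions follow the design
conventions of :mod:`sca3prog.design`: segment basis d1/d2 from the knot,
interactions on raw duration in the "c" models, covariates uncentered.
Predictions are not clamped to the 0-100 score range by default (the
published prediction spreadsheets are unclamped linear arithmetic).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import published
from .design import ModelSpec, piecewise_basis, registry_spec
from .errors import DesignError

__all__ = ["CoefficientSet", "predict_fixed", "prediction_grid"]


@dataclass(frozen=True)
class CoefficientSet:
    """Fixed-effect coefficients of one ladder model."""

    model_name: str
    knot: float | None
    beta: dict[str, float]

    def spec(self) -> ModelSpec:
        return registry_spec(self.model_name, self.knot)

    def __post_init__(self):
        spec = self.spec()
        if set(self.beta) != set(spec.fixed_terms):
            raise DesignError(
                f"coefficient terms {sorted(self.beta)} do not match "
                f"{spec.name}'s fixed terms {sorted(spec.fixed_terms)}"
            )

    @classmethod
    def from_published(cls, model_name: str,
                       knot: float = published.PUBLISHED_KNOT) -> "CoefficientSet":
        """The transcribed published column of one ladder model."""
        return cls(model_name=model_name, knot=knot,
                   beta=published.published_beta(model_name))

    @classmethod
    def from_fit(cls, fit) -> "CoefficientSet":
        return cls(model_name=fit.spec.name, knot=fit.spec.knot,
                   beta=fit.beta_dict())

    def to_json(self, path=None) -> str:
        doc = json.dumps({"model_name": self.model_name, "knot": self.knot,
                          "beta": dict(self.beta)}, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(model_name=d["model_name"], knot=d.get("knot"),
                   beta={k: float(v) for k, v in d["beta"].items()})


def _design_row(spec: ModelSpec, duration: float, values: dict[str, float]
                ) -> dict[str, float]:
    dt = float(duration)
    if dt < 0:
        raise DesignError("duration must be non-negative")
    time_vals = {"intercept": 1.0, "dt": dt, "dt2": dt * dt}
    if spec.is_piecewise:
        d1, d2 = piecewise_basis(dt, spec.knot)
        time_vals["d1"], time_vals["d2"] = d1, d2
    row = {}
    for term in spec.fixed_terms:
        if term in time_vals:
            row[term] = time_vals[term]
        elif "*" in term:
            tpart, cov = term.split("*")
            row[term] = time_vals[tpart] * values[cov]
        else:
            row[term] = values[term]
    return row


def predict_fixed(coeffs: CoefficientSet, duration: float,
                  cag_exp: float | None = None, aoga: float | None = None,
                  gender: str | float | None = None, rao: float | None = None,
                  clamp: bool = False) -> float:
    """Population-average ICARS score at one disease duration.

    Only the covariates the model carries are required (e.g. PM2c needs
    ``cag_exp`` only; PM4c needs ``cag_exp`` and ``aoga``); a missing one
    raises an error naming the model's requirements.
    """
    spec = coeffs.spec()
    supplied = {"CAGexp": cag_exp, "AOga": aoga, "RAO": rao}
    if gender is not None:
        if isinstance(gender, str):
            g = gender.strip().lower()
            if g not in ("female", "male", "f", "m"):
                raise DesignError(f"unrecognized gender {gender!r}")
            supplied["gender"] = 1.0 if g.startswith("f") else 0.0
        else:
            supplied["gender"] = float(gender)
    else:
        supplied["gender"] = None
    values = {}
    for cov in spec.covariates:
        if supplied.get(cov) is None:
            raise DesignError(
                f"model {spec.name} requires covariates "
                f"{list(spec.covariates)}; {cov} is missing"
            )
        values[cov] = float(supplied[cov])
    row = _design_row(spec, duration, values)
    pred = float(sum(coeffs.beta[t] * v for t, v in row.items()))
    if clamp:
        pred = float(np.clip(pred, 0.0, 100.0))
    return pred


def prediction_grid(coeffs: CoefficientSet, durations,
                    cag_range=None, aoga_range=None, clamp: bool = False
                    ) -> pd.DataFrame:
    """Cartesian-product table of fixed-effect predictions.

    One row per combination of covariate values and duration, mirroring the
    published prediction spreadsheets; written to CSV by the caller.
    """
    spec = coeffs.spec()
    axes: list[tuple[str, list]] = []
    if "CAGexp" in spec.covariates:
        if cag_range is None:
            raise DesignError(f"model {spec.name} needs cag_range")
        axes.append(("cag_exp", list(cag_range)))
    if "AOga" in spec.covariates:
        if aoga_range is None:
            raise DesignError(f"model {spec.name} needs aoga_range")
        axes.append(("aoga", list(aoga_range)))
    axes.append(("duration", list(durations)))
    if any(len(v) == 0 for _, v in axes):
        raise DesignError("prediction grids must be non-empty")

    rows = []
    for combo in itertools.product(*(v for _, v in axes)):
        rec = dict(zip((n for n, _ in axes), combo))
        rows.append({
            **rec,
            "icars_pred": predict_fixed(
                coeffs, duration=rec["duration"],
                cag_exp=rec.get("cag_exp"), aoga=rec.get("aoga"), clamp=clamp,
            ),
        })
    return pd.DataFrame(rows)
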