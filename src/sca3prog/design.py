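"""Growth-model registry and design-matrix construction.

The analysis compares a family of linear mixed-effects growth models for a
0-100 ataxia severity score (ICARS) against disease duration ``dt`` (years
since onset of gait ataxia):

* ``LM*`` - single-slope linear models (time basis ``1, dt``),
* ``QM1`` - quadratic model (``1, dt, dt^2``),
* ``PM*`` - two-segment piece-wise linear models with a knot ``I``:
  ``d1 = dt - I`` before the knot (else 0) and ``d2 = dt - I`` after the knot
  (else 0), so the intercept is the expected score AT the knot and the two
  slopes are the early- and late-stage progression rates.

Candidate modifiers (CAG repeat length ``CAGexp``, age at onset ``AOga``, its
CAG-independent residual ``RAO``, and ``gender``) enter uncentered with a main
effect plus a time interaction.  In piece-wise models the interaction is
either segment-wise (``d1*cov``, ``d2*cov``) or, in the "c" variants, on raw
duration (``dt*cov``).

Random effects: intercept + dt slope (unstructured 2x2 covariance) for linear
and quadratic models; intercept + d1 + d2 slopes (unstructured 3x3) for all
piece-wise models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "piecewise_basis",
    "registry_spec",
    "build_design",
    "MODEL_NAMES",
]

# interaction styles
BY_DT = "by_dt"            # cov, dt*cov  (the "c" convention for PM models)
BY_SEGMENT = "by_segment"  # cov, d1*cov, d2*cov

# time bases
LINEAR = "linear"
QUADRATIC = "quadratic"
PIECEWISE = "piecewise"

# name -> (time_basis, covariates, interaction_style)
_REGISTRY: dict[str, tuple[str, tuple[str, ...], str]] = {
    "LM1": (LINEAR, (), BY_DT),
    "LM2": (LINEAR, ("CAGexp",), BY_DT),
    "LM3": (LINEAR, ("AOga",), BY_DT),
    "LM4": (LINEAR, ("CAGexp", "AOga"), BY_DT),
    "LM5": (LINEAR, ("gender",), BY_DT),
    "LM6": (LINEAR, ("CAGexp", "RAO"), BY_DT),
    "QM1": (QUADRATIC, (), BY_DT),
    "PM1": (PIECEWISE, (), BY_SEGMENT),
    "PM2": (PIECEWISE, ("CAGexp",), BY_SEGMENT),
    "PM2c": (PIECEWISE, ("CAGexp",), BY_DT),
    "PM3": (PIECEWISE, ("AOga",), BY_SEGMENT),
    "PM3c": (PIECEWISE, ("AOga",), BY_DT),
    "PM4": (PIECEWISE, ("CAGexp", "AOga"), BY_SEGMENT),
    "PM4c": (PIECEWISE, ("CAGexp", "AOga"), BY_DT),
    "PM5": (PIECEWISE, ("gender",), BY_SEGMENT),
    "PM5c": (PIECEWISE, ("gender",), BY_DT),
    "PM6": (PIECEWISE, ("CAGexp", "RAO"), BY_SEGMENT),
    "PM6c": (PIECEWISE, ("CAGexp", "RAO"), BY_DT),
}

_CANONICAL = {name.upper(): name for name in _REGISTRY}

#: all registered model names, in registry order
MODEL_NAMES = tuple(_REGISTRY.keys())

# cohort DataFrame column backing each covariate name
_COVARIATE_COLUMNS = {
    "CAGexp": "cag_exp",
    "AOga": "aoga",
    "RAO": "rao",
    "gender": "gender",
}


def piecewise_basis(dt, knot: float):
    """Split duration into the two-segment basis (d1, d2).

    ``d1 = dt - knot`` for ``dt <= knot`` (else 0); ``d2 = dt - knot`` for
    ``dt > knot`` (else 0).  Hence d1 <= 0 <= d2, at most one is nonzero, and
    ``d1 + d2 + knot = dt``.

    Accepts scalars or arrays; negative durations or a non-positive knot raise
    :class:`~sca3prog.errors.DesignError`.
    """
    dt = np.asarray(dt, dtype=float)
    if knot <= 0:
        raise DesignError(f"knot must be positive, got {knot}")
    if np.any(dt < 0):
        raise DesignError("durations must be non-negative")
    d1 = np.where(dt <= knot, dt - knot, 0.0)
    d2 = np.where(dt > knot, dt - knot, 0.0)
    if d1.ndim == 0:
        return float(d1), float(d2)
    return d1, d2


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one ladder model."""

    name: str
    time_basis: str
    covariates: tuple[str, ...]
    interaction_style: str
    knot: float | None = None

    @property
    def is_piecewise(self) -> bool:
        return self.time_basis == PIECEWISE

    @property
    def time_terms(self) -> tuple[str, ...]:
        if self.time_basis == LINEAR:
            return ("intercept", "dt")
        if self.time_basis == QUADRATIC:
            return ("intercept", "dt", "dt2")
        return ("intercept", "d1", "d2")

    @property
    def random_basis(self) -> tuple[str, ...]:
        """Random-effect columns: intercept + slope(s) on the model's timescale."""
        if self.is_piecewise:
            return ("intercept", "d1", "d2")
        return ("intercept", "dt")

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        """Ordered fixed-effect term names (published column order)."""
        terms = list(self.time_terms)
        for cov in self.covariates:
            terms.append(cov)
            if self.interaction_style == BY_SEGMENT:
                terms += [f"d1*{cov}", f"d2*{cov}"]
            elif self.interaction_style == BY_DT:
                terms.append(f"dt*{cov}")
        return tuple(terms)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_terms)

    @property
    def n_random(self) -> int:
        return len(self.random_basis)

    @property
    def param_count(self) -> int:
        """Total ML parameter count: fixed effects + unique entries of the
        unstructured random covariance + residual variance."""
        q = self.n_random
        return self.n_fixed + q * (q + 1) // 2 + 1

    def required_columns(self) -> tuple[str, ...]:
        return tuple(_COVARIATE_COLUMNS[c] for c in self.covariates)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "time_basis": self.time_basis,
            "covariates": list(self.covariates),
            "interaction_style": self.interaction_style,
            "random_basis": list(self.random_basis),
            "fixed_terms": list(self.fixed_terms),
            "knot": self.knot,
        }


def registry_spec(name: str, knot: float | None = None) -> ModelSpec:
    """Look up a ladder model by name (case-insensitive).

    Piece-wise models require a positive ``knot`` (years of duration); linear
    and quadratic models ignore it.
    """
    try:
        canonical = _CANONICAL[str(name).upper()]
    except KeyError:
        raise DesignError(
            f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
        ) from None
    basis, covs, style = _REGISTRY[canonical]
    if basis == PIECEWISE:
        if knot is None or knot <= 0:
            raise DesignError(
                f"model {canonical} is piece-wise and needs a positive knot"
            )
        return ModelSpec(canonical, basis, covs, style, float(knot))
    return ModelSpec(canonical, basis, covs, style, None)


@dataclass
class DesignMatrices:
    """Response, fixed and random design matrices plus subject grouping."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    groups: np.ndarray
    fixed_names: tuple[str, ...]
    random_names: tuple[str, ...]
    spec: ModelSpec = field(repr=False, default=None)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_subjects(self) -> int:
        return len(pd.unique(self.groups))


def _gender_indicator(col: pd.Series) -> np.ndarray:
    """Map gender labels to the 0/1 indicator (female = 1, male = 0)."""
    s = col.astype(str).str.strip().str.lower()
    mapping = {"female": 1.0, "f": 1.0, "1": 1.0, "1.0": 1.0,
               "male": 0.0, "m": 0.0, "0": 0.0, "0.0": 0.0}
    out = s.map(mapping)
    if out.isna().any():
        bad = sorted(s[out.isna()].unique())
        raise DesignError(f"unrecognized gender labels: {bad}")
    return out.to_numpy(dtype=float)


def _time_columns(dt: np.ndarray, spec: ModelSpec) -> dict[str, np.ndarray]:
    cols = {"intercept": np.ones_like(dt), "dt": dt}
    if spec.time_basis == QUADRATIC:
        cols["dt2"] = dt ** 2
    if spec.is_piecewise:
        d1, d2 = piecewise_basis(dt, spec.knot)
        cols["d1"], cols["d2"] = d1, d2
    return cols


def build_design(cohort: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Assemble y, X, Z and the grouping vector for one model.

    Requires ``duration`` and ``icars`` columns plus the covariate columns the
    model names (``rao`` must be precomputed, see
    :func:`sca3prog.cohort.add_rao`).  In "c"-style piece-wise models the
    covariate-time interaction uses raw duration, not the segment basis;
    covariates enter uncentered in their original units.
    """
    for col in ("duration", "icars", "subject_id"):
        if col not in cohort.columns:
            raise DesignError(f"cohort is missing required column {col!r}")
    dt = cohort["duration"].to_numpy(dtype=float)
    if np.any(dt < 0):
        raise DesignError("durations must be non-negative")
    time_cols = _time_columns(dt, spec)

    cov_values: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        col = _COVARIATE_COLUMNS[cov]
        if col not in cohort.columns:
            raise DesignError(
                f"model {spec.name} needs covariate column {col!r}"
            )
        if cov == "gender":
            cov_values[cov] = _gender_indicator(cohort[col])
        else:
            cov_values[cov] = cohort[col].to_numpy(dtype=float)

    columns = []
    for term in spec.fixed_terms:
        if term in time_cols:
            columns.append(time_cols[term])
        elif "*" in term:
            tpart, cov = term.split("*")
            columns.append(time_cols[tpart] * cov_values[cov])
        else:
            columns.append(cov_values[term])
    X = np.column_stack(columns)

    Z = np.column_stack([time_cols[t] for t in spec.random_basis])
    y = cohort["icars"].to_numpy(dtype=float)
    groups = cohort["subject_id"].to_numpy()
    return DesignMatrices(
        y=y, X=X, Z=Z, groups=groups,
        fixed_names=spec.fixed_terms, random_names=spec.random_basis,
        spec=spec,
    )
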