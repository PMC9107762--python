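"""Synthetic SCA3 cohort generator.

Emulates the statistical structure of the longitudinal cohort behind the
progression analysis: a genotype (CAG repeat length) distribution coupled to
age at onset so that a configurable share of onset variance is explained by
the repeat length, an irregular visit process (subjects enter follow-up at
various disease durations and return at roughly yearly intervals), and ICARS
trajectories drawn from a linear mixed-effects growth model with
subject-level random intercepts and slopes.

Distribution families (the published cohort reports only moments and ranges):

* CAGexp: rounded truncated normal within [cag_min, cag_max];
* AOga: linear in CAGexp with negative slope (longer repeats -> earlier
  onset) plus normal noise, the slope/noise solved from the moment equations
  so the marginal mean/SD and the explained-variance share hit their targets;
* visit count: 1 + Poisson, clamped to [n_visits_min, n_visits_max];
* first-visit duration: truncated normal with positive support;
* inter-visit gaps: gamma, moment-matched to the target interval mean/SD.

The trajectory truth (fixed effects, random-effect covariance, residual SD)
is a :class:`ModelTruth`; by default the fixed effects are the published
column of the chosen ladder model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from . import published
from .cohort import add_rao
from .design import build_design, registry_spec
from .errors import ConfigurationError

__all__ = [
    "ModelTruth",
    "CohortConfig",
    "default_truth",
    "sample_genetics",
    "sample_visit_schedule",
    "simulate_icars",
    "generate_cohort",
]

#: AOga is floored at this value (years); onset in infancy is not modelled
_AOGA_FLOOR = 5.0

#: default random-effect SDs: intercept (ICARS points) and per-segment slope
#: (points/year); correlations zero.  Chosen so that the conditional R^2 far
#: exceeds the marginal R^2, as in the published fits.
_DEFAULT_INTERCEPT_SD = 12.0
_DEFAULT_SLOPE_SD = 1.0
_DEFAULT_RESID_SD = 3.0


@dataclass(frozen=True)
class ModelTruth:
    """Generating parameters of the trajectory model.

    ``beta`` keys must exactly match the fixed terms of ``model_name``'s
    registry spec; ``re_cov`` is the random-effects covariance over the
    model's random basis (intercept[, slope(s)]), in ICARS^2 units.
    """

    model_name: str
    knot: float | None
    beta: dict[str, float]
    re_cov: np.ndarray
    resid_sd: float

    def spec(self):
        return registry_spec(self.model_name, self.knot)

    def validate(self) -> None:
        spec = self.spec()
        if tuple(self.beta.keys()) != spec.fixed_terms:
            raise ConfigurationError(
                f"beta terms {tuple(self.beta)} do not match "
                f"{self.model_name}'s fixed terms {spec.fixed_terms}"
            )
        q = spec.n_random
        re_cov = np.asarray(self.re_cov, dtype=float)
        if re_cov.shape != (q, q):
            raise ConfigurationError(
                f"re_cov must be {q}x{q} for {self.model_name}, got {re_cov.shape}"
            )
        if not np.allclose(re_cov, re_cov.T):
            raise ConfigurationError("re_cov must be symmetric")
        if np.linalg.eigvalsh(re_cov).min() < -1e-8:
            raise ConfigurationError("re_cov must be positive semi-definite")
        if not self.resid_sd > 0:
            raise ConfigurationError("resid_sd must be positive")

    def beta_vector(self) -> np.ndarray:
        return np.asarray(list(self.beta.values()), dtype=float)


def default_truth(model_name: str = "PM1", knot: float = published.PUBLISHED_KNOT,
                  intercept_sd: float = _DEFAULT_INTERCEPT_SD,
                  slope_sd: float = _DEFAULT_SLOPE_SD,
                  resid_sd: float = _DEFAULT_RESID_SD) -> ModelTruth:
    """Truth with the published fixed effects of one ladder model and a
    diagonal random covariance (intercept SD 12 points, slope SD 1 point/year
    per time term, residual SD 3 points)."""
    spec = registry_spec(model_name, knot)
    beta = published.published_beta(spec.name)
    beta = {term: beta[term] for term in spec.fixed_terms}  # enforce order
    sds = [intercept_sd] + [slope_sd] * (spec.n_random - 1)
    re_cov = np.diag(np.asarray(sds, dtype=float) ** 2)
    return ModelTruth(model_name=spec.name, knot=spec.knot, beta=beta,
                      re_cov=re_cov, resid_sd=resid_sd)


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults reproduce the published cohort's
    descriptive statistics (81 subjects, CAG 67.7 +/- 3.65 in [60, 75], onset
    42.1 +/- 9.88 years with 49% of its variance explained by CAG, ~7.8
    visits at ~1.21-year intervals, first visit ~7.1 years after onset)."""

    n_subjects: int = 81
    cag_mean: float = 67.7
    cag_sd: float = 3.65
    cag_min: float = 60.0
    cag_max: float = 75.0
    aoga_mean: float = 42.1
    aoga_sd: float = 9.88
    cag_aoga_r2: float = 0.49
    first_duration_mean: float = 7.11
    first_duration_sd: float = 5.03
    first_duration_min: float = 0.5
    n_visits_mean: float = 7.83
    n_visits_min: int = 1
    n_visits_max: int = 16
    interval_mean: float = 1.21
    interval_sd: float = 0.783
    female_fraction: float = 43.0 / 81.0
    truth: ModelTruth = field(default_factory=default_truth)
    clip_icars: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not (self.cag_min <= self.cag_mean <= self.cag_max):
            raise ConfigurationError("need cag_min <= cag_mean <= cag_max")
        if not (0.0 <= self.cag_aoga_r2 < 1.0):
            raise ConfigurationError("cag_aoga_r2 must be in [0, 1)")
        if self.cag_sd == 0 and self.cag_aoga_r2 > 0:
            raise ConfigurationError(
                "cag_sd = 0 cannot explain any AOga variance (cag_aoga_r2 > 0)"
            )
        for name in ("cag_sd", "aoga_sd", "first_duration_sd", "interval_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_visits_min < 1 or self.n_visits_max < self.n_visits_min:
            raise ConfigurationError("need 1 <= n_visits_min <= n_visits_max")
        if self.interval_mean <= 0:
            raise ConfigurationError("interval_mean must be positive")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ConfigurationError("female_fraction must be in [0, 1]")
        if self.first_duration_min <= 0:
            raise ConfigurationError("first_duration_min must be positive")
        self.truth.validate()

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "truth"}
        d["truth"] = {
            "model_name": self.truth.model_name,
            "knot": self.truth.knot,
            "beta": dict(self.truth.beta),
            "re_cov": np.asarray(self.truth.re_cov).tolist(),
            "resid_sd": self.truth.resid_sd,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        t = d.pop("truth", None)
        if t is not None:
            truth = ModelTruth(
                model_name=t["model_name"], knot=t.get("knot"),
                beta=dict(t["beta"]),
                re_cov=np.asarray(t["re_cov"], dtype=float),
                resid_sd=float(t["resid_sd"]),
            )
        else:
            truth = default_truth()
        return cls(truth=truth, **d)


def _matched_truncnorm(mean, sd, lower, upper, size, rng):
    """Truncated normal whose TRUNCATED mean/SD equal the targets.

    Truncation shifts the mean toward the interval's interior and shrinks the
    spread, so the location and scale are solved from the truncated-moment
    equations rather than set to the targets directly; if the solve fails
    (targets incompatible with the bounds) the plain clipped normal is used.
    """
    if sd == 0:
        return np.full(size, float(np.clip(mean, lower, upper)))
    loc, scale = _solve_truncnorm_params(float(mean), float(sd), float(lower),
                                         float(upper))
    a, b = (lower - loc) / scale, (upper - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                               random_state=rng)


@lru_cache(maxsize=64)
def _solve_truncnorm_params(mean: float, sd: float, lower: float, upper: float
                            ) -> tuple[float, float]:
    def eqs(p):
        loc, log_scale = p
        scale = np.exp(log_scale)
        a, b = (lower - loc) / scale, (upper - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    from scipy.optimize import fsolve
    with np.errstate(all="ignore"):
        sol, _, ier, _ = fsolve(eqs, [mean, np.log(sd)], full_output=True)
    if ier == 1 and np.isfinite(sol).all():
        return float(sol[0]), float(np.exp(sol[1]))
    return mean, sd  # fall back: clipped normal at the target moments


def sample_genetics(config: CohortConfig, rng: np.random.Generator
                    ) -> pd.DataFrame:
    """Per-subject CAG repeat length, onset age, and gender.

    CAGexp is a rounded truncated normal.  AOga = a + b*CAGexp + eps with
    b < 0 (longer repeats -> earlier onset); (a, b, sd(eps)) are solved from
    the moment equations against the realized spread of the drawn CAG values,
    so that the marginal mean/SD of AOga match their targets and the share of
    AOga variance explained by CAGexp equals ``cag_aoga_r2``.
    """
    config.validate()
    n = config.n_subjects
    cag = _matched_truncnorm(config.cag_mean, config.cag_sd, config.cag_min,
                             config.cag_max, n, rng)
    cag = np.clip(np.rint(cag), config.cag_min, config.cag_max).astype(int)

    r2 = config.cag_aoga_r2
    if r2 > 0:
        s = float(np.std(cag, ddof=1)) if n > 1 else 0.0
        if s == 0:
            raise ConfigurationError(
                "drawn CAGexp values are constant; cannot target cag_aoga_r2 > 0"
            )
        b = -np.sqrt(r2) * config.aoga_sd / s
    else:
        b = 0.0
    eps_sd = config.aoga_sd * np.sqrt(1.0 - r2)
    a = config.aoga_mean - b * float(np.mean(cag))
    aoga = a + b * cag + rng.normal(0.0, eps_sd, size=n)
    aoga = np.maximum(aoga, _AOGA_FLOOR)

    gender = np.where(rng.random(n) < config.female_fraction, "female", "male")
    subject_id = [f"S{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame({
        "subject_id": subject_id, "cag_exp": cag, "aoga": aoga, "gender": gender,
    })


def sample_visit_schedule(config: CohortConfig, rng: np.random.Generator
                          ) -> list[np.ndarray]:
    """Strictly increasing disease durations (years) for each subject."""
    config.validate()
    n = config.n_subjects
    lam = max(config.n_visits_mean - 1.0, 0.0)
    counts = 1 + (rng.poisson(lam, size=n) if lam > 0 else np.zeros(n, dtype=int))
    counts = np.clip(counts, config.n_visits_min, config.n_visits_max)

    first = _matched_truncnorm(config.first_duration_mean,
                               config.first_duration_sd,
                               config.first_duration_min, np.inf, n, rng)
    schedules = []
    for i in range(n):
        c = int(counts[i])
        if c == 1:
            schedules.append(np.asarray([first[i]]))
            continue
        if config.interval_sd == 0:
            gaps = np.full(c - 1, config.interval_mean)
        else:
            shape = (config.interval_mean / config.interval_sd) ** 2
            scale = config.interval_sd ** 2 / config.interval_mean
            gaps = rng.gamma(shape, scale, size=c - 1)
            gaps = np.maximum(gaps, 1e-6)
        schedules.append(first[i] + np.concatenate([[0.0], np.cumsum(gaps)]))
    return schedules


def simulate_icars(truth: ModelTruth, covariates: pd.DataFrame,
                   schedule: list[np.ndarray], rng: np.random.Generator,
                   clip_icars: bool = False) -> pd.DataFrame:
    """Draw ICARS trajectories from the mixed-model truth.

    For each subject a random-effect vector is drawn with covariance
    ``truth.re_cov``; the score at each visit is the fixed part (model design
    row dotted with the true beta) plus the random part plus residual noise.
    Scores are clamped to [0, 100] only if ``clip_icars`` (clipping biases
    linear-model recovery, so it is off by default).
    """
    truth.validate()
    spec = truth.spec()
    n = len(covariates)
    if len(schedule) != n:
        raise ConfigurationError("schedule and covariates disagree on n_subjects")

    rows = []
    for i, durations in enumerate(schedule):
        for dt in durations:
            rows.append((covariates["subject_id"].iat[i], float(dt)))
    long = pd.DataFrame(rows, columns=["subject_id", "duration"])
    long = long.merge(covariates, on="subject_id", how="left")
    long["age_at_exam"] = long["aoga"] + long["duration"]
    long["icars"] = 0.0
    if "RAO" in spec.covariates:
        long = add_rao(long)

    design = build_design(long, spec)
    fixed = design.X @ truth.beta_vector()

    # PSD-safe square root of the random covariance
    re_cov = np.asarray(truth.re_cov, dtype=float)
    w, V = np.linalg.eigh(re_cov)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    b = rng.standard_normal((n, re_cov.shape[0])) @ root.T

    codes = pd.factorize(long["subject_id"])[0]
    random_part = np.einsum("nq,nq->n", design.Z, b[codes])
    noise = rng.normal(0.0, truth.resid_sd, size=len(long))
    icars = fixed + random_part + noise
    if clip_icars:
        icars = np.clip(icars, 0.0, 100.0)
    long["icars"] = icars
    return long


def generate_cohort(config: CohortConfig, seed: int | None = None
                    ) -> pd.DataFrame:
    """Compose the three samplers into a long-format cohort.

    Deterministic for a fixed (config, seed); ``seed`` overrides
    ``config.seed`` when given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    covariates = sample_genetics(config, rng)
    schedule = sample_visit_schedule(config, rng)
    return simulate_icars(config.truth, covariates, schedule, rng,
                          clip_icars=config.clip_icars)


def with_truth(config: CohortConfig, truth: ModelTruth) -> CohortConfig:
    """Convenience copy of a config with a different generating truth."""
    return replace(config, truth=truth)
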