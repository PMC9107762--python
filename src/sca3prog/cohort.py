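"""Long-format cohort handling: reading, cleaning, RAO, descriptive summaries.

A cohort is a pandas DataFrame with one ICARS examination per row and columns

    subject_id, cag_exp, aoga, gender, age_at_exam, duration, icars

where ``cag_exp`` is the expanded ATXN3 CAG repeat length, ``aoga`` the age at
onset of gait ataxia (years), and ``duration`` the disease duration at the
examination (years since onset) -- the analysis timescale.  Subject-level
covariates must be constant within a subject.  ``duration`` may be supplied
directly (simulated cohorts) or derived as ``age_at_exam - aoga``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CohortLoadError, Sca3ProgError

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "compute_duration",
    "remove_duration_outliers",
    "compute_rao",
    "add_rao",
    "summarize_cohort",
    "CohortSummary",
    "RaoResult",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = (
    "subject_id", "cag_exp", "aoga", "gender", "age_at_exam", "duration", "icars",
)

_SUBJECT_LEVEL = ("cag_exp", "aoga", "gender")

#: tolerance (years) for an explicitly supplied duration disagreeing with
#: age_at_exam - aoga
_DURATION_TOL = 1e-6


def compute_duration(age_at_exam, aoga):
    """Disease duration = age at examination minus age at onset of gait ataxia.

    Raises for pre-onset visits (examination before onset).  Vectorized.
    """
    age = np.asarray(age_at_exam, dtype=float)
    onset = np.asarray(aoga, dtype=float)
    if np.any(age < onset):
        raise Sca3ProgError(
            "age_at_exam earlier than AOga: pre-onset visits are not allowed"
        )
    out = age - onset
    return float(out) if out.ndim == 0 else out


def _normalize_gender(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    mapping = {"female": "female", "f": "female", "1": "female", "1.0": "female",
               "male": "male", "m": "male", "0": "male", "0.0": "male"}
    out = s.map(mapping)
    if out.isna().any():
        bad = sorted(s[out.isna()].unique())
        raise CohortLoadError(f"unrecognized gender labels: {bad}")
    return out


def validate_cohort(df: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Check cohort invariants, derive duration, and sort visits.

    Rows with missing ICARS, missing both time fields, or non-positive derived
    duration are dropped with a logged per-row report.  Subject-level
    covariates that vary within a subject raise
    :class:`~sca3prog.errors.CohortLoadError` naming the subject.  With
    ``strict=True``, ICARS values outside [0, 100] are an error instead of a
    logged warning (simulated cohorts are unclipped by default, so lenient is
    the default).
    """
    df = df.copy()
    missing = [c for c in ("subject_id", "icars") if c not in df.columns]
    if missing:
        raise CohortLoadError(f"cohort is missing required columns: {missing}")
    if "duration" not in df.columns and "age_at_exam" not in df.columns:
        raise CohortLoadError("cohort needs a 'duration' or 'age_at_exam' column")
    for col in ("duration", "age_at_exam"):
        if col not in df.columns:
            df[col] = np.nan

    for col in ("cag_exp", "aoga", "age_at_exam", "duration", "icars"):
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise CohortLoadError(f"non-numeric values in column {col!r}: {exc}")
    if "gender" in df.columns:
        df["gender"] = _normalize_gender(df["gender"])

    dropped: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    no_icars = df["icars"].isna()
    no_time = df["duration"].isna() & df["age_at_exam"].isna()
    for idx in df.index[no_icars]:
        dropped.append((idx, "missing icars"))
    for idx in df.index[no_time & ~no_icars]:
        dropped.append((idx, "missing both age_at_exam and duration"))
    keep &= ~(no_icars | no_time).to_numpy()

    # derive / cross-check duration
    has_age = df["age_at_exam"].notna() & df["aoga"].notna() \
        if "aoga" in df.columns else pd.Series(False, index=df.index)
    derived = df["age_at_exam"] - df["aoga"] if "aoga" in df.columns else None
    if derived is not None:
        both = has_age & df["duration"].notna()
        incons = both & ((df["duration"] - derived).abs() > _DURATION_TOL)
        if incons.any():
            rows = df.index[incons].tolist()
            raise CohortLoadError(
                f"duration inconsistent with age_at_exam - aoga in rows {rows}"
            )
        pre_onset = has_age & df["duration"].isna() & (derived < 0)
        if pre_onset.any():
            rows = df.index[pre_onset].tolist()
            raise CohortLoadError(f"pre-onset visits (age < AOga) in rows {rows}")
        df.loc[has_age & df["duration"].isna(), "duration"] = derived

    nonpos = df["duration"].notna() & (df["duration"] <= 0)
    for idx in df.index[nonpos & keep]:
        dropped.append((idx, "non-positive duration"))
    keep &= ~nonpos.to_numpy()

    out_of_range = df["icars"].notna() & ((df["icars"] < 0) | (df["icars"] > 100))
    if out_of_range.any():
        msg = (f"{int(out_of_range.sum())} ICARS values outside [0, 100] "
               f"(unclipped simulation?)")
        if strict:
            raise CohortLoadError(msg)
        logger.warning(msg)

    if dropped:
        for idx, reason in dropped:
            logger.warning("dropping row %s: %s", idx, reason)
        logger.info("dropped %d of %d rows", len(dropped), len(df))
    df = df[keep]

    for col in _SUBJECT_LEVEL:
        if col in df.columns:
            nun = df.groupby("subject_id")[col].nunique(dropna=False)
            bad = nun[nun > 1].index.tolist()
            if bad:
                raise CohortLoadError(
                    f"subject-level covariate {col!r} varies within subjects: {bad}"
                )

    df = df.sort_values(["subject_id", "duration"], kind="stable")
    return df.reset_index(drop=True)


def read_cohort(path, strict: bool = False) -> pd.DataFrame:
    """Read a long-format cohort CSV (comma-delimited, UTF-8, '.' decimal)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CohortLoadError(f"could not parse {path}: {exc}") from exc
    return validate_cohort(df, strict=strict)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV (full float precision; round-trip lossless)."""
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, index=False)


def remove_duration_outliers(cohort: pd.DataFrame, max_duration: float = 40.0
                             ) -> tuple[pd.DataFrame, dict]:
    """Drop every visit of subjects whose maximum duration exceeds the cutoff.

    Filtering is subject-level (the whole participant is removed, mirroring
    the 82 -> 81 subjects / 642 -> 634 examinations cleaning step) and
    idempotent.  Returns the filtered cohort and a report dict.
    """
    max_dt = cohort.groupby("subject_id")["duration"].max()
    removed = max_dt[max_dt > max_duration].index.tolist()
    mask = cohort["subject_id"].isin(removed)
    report = {
        "max_duration": float(max_duration),
        "removed_subjects": {
            str(s): int((cohort["subject_id"] == s).sum()) for s in removed
        },
        "n_subjects_removed": len(removed),
        "n_rows_removed": int(mask.sum()),
    }
    if removed:
        logger.info(
            "removed %d subject(s), %d visit rows with duration > %g years",
            len(removed), int(mask.sum()), max_duration,
        )
    return cohort[~mask].reset_index(drop=True), report


@dataclass
class RaoResult:
    """Subject-level regression of AOga on CAGexp and its residuals (RAO)."""

    per_subject: pd.DataFrame  # columns: subject_id, rao
    intercept: float
    slope: float
    r_squared: float


def compute_rao(cohort: pd.DataFrame) -> RaoResult:
    """Residual age at onset: AOga minus its OLS fit on CAGexp.

    The regression uses one row per subject.  RAO is the CAG-independent
    component of onset age; its mean is zero by construction.
    """
    subj = cohort.drop_duplicates("subject_id")[["subject_id", "cag_exp", "aoga"]]
    if len(subj) < 3:
        raise Sca3ProgError("RAO needs at least 3 distinct subjects")
    x = subj["cag_exp"].to_numpy(dtype=float)
    y = subj["aoga"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise Sca3ProgError("all CAGexp identical: AOga~CAGexp regression degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    per_subject = pd.DataFrame({"subject_id": subj["subject_id"].to_numpy(),
                                "rao": resid})
    return RaoResult(per_subject=per_subject, intercept=float(intercept),
                     slope=float(slope), r_squared=r2)


def add_rao(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return the cohort with a per-subject ``rao`` column merged in."""
    res = compute_rao(cohort)
    out = cohort.drop(columns=["rao"], errors="ignore")
    return out.merge(res.per_subject, on="subject_id", how="left")


@dataclass
class _Stat:
    mean: float
    sd: float
    min: float
    max: float

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in ("mean", "sd", "min", "max")}

    def __str__(self) -> str:
        return f"{self.mean:.3f} ± {self.sd:.3f} [{self.min:.3f}-{self.max:.3f}]"


def _agg(values: np.ndarray) -> _Stat:
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return _Stat(float(np.mean(values)), sd, float(np.min(values)),
                 float(np.max(values)))


@dataclass
class CohortSummary:
    """Descriptive statistics of a cohort, one aggregate per characteristic.

    Per-subject quantities (visit count, follow-up span, mean inter-visit
    interval, first-examination values) are computed within subject and then
    aggregated as mean +/- SD [min-max] across subjects; subjects with a
    single visit contribute a zero follow-up span and no interval.
    """

    n_subjects: int
    n_female: int
    n_exams: int
    visits_per_subject: _Stat
    followup_years: _Stat
    interval_years: _Stat | None
    cag_exp: _Stat
    aoga: _Stat
    duration_first: _Stat
    age_first: _Stat | None
    icars_first: _Stat

    def to_dict(self) -> dict:
        out = {}
        for name, val in self.__dict__.items():
            if isinstance(val, _Stat):
                out[name] = val.to_dict()
            elif val is None:
                out[name] = None
            else:
                out[name] = int(val)
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def __str__(self) -> str:
        lines = [
            f"Subjects: {self.n_subjects} ({self.n_female} female)",
            f"Examinations: {self.n_exams}",
            f"Visits/subject: {self.visits_per_subject}",
            f"Follow-up (years): {self.followup_years}",
        ]
        if self.interval_years is not None:
            lines.append(f"Visit interval (years): {self.interval_years}")
        lines += [
            f"CAGexp: {self.cag_exp}",
            f"AOga (years): {self.aoga}",
            f"Duration at first exam (years): {self.duration_first}",
        ]
        if self.age_first is not None:
            lines.append(f"Age at first exam (years): {self.age_first}")
        lines.append(f"ICARS at first exam: {self.icars_first}")
        return "\n".join(lines)


def summarize_cohort(cohort: pd.DataFrame) -> CohortSummary:
    """Table-1-style descriptive summary of a long-format cohort."""
    if len(cohort) == 0:
        raise Sca3ProgError("cannot summarize an empty cohort")
    g = cohort.groupby("subject_id", sort=True)
    counts = g.size().to_numpy()
    followup = (g["duration"].max() - g["duration"].min()).to_numpy()
    mean_intervals = [
        float(np.mean(np.diff(np.sort(sub["duration"].to_numpy()))))
        for _, sub in g if len(sub) > 1
    ]
    # first examination = minimum duration per subject (ties: file order)
    first = cohort.sort_values(["subject_id", "duration"], kind="stable") \
                  .groupby("subject_id", sort=True).head(1)
    subj = g.head(1).sort_values("subject_id")
    n_female = int((subj["gender"] == "female").sum()) if "gender" in cohort else 0
    has_age = "age_at_exam" in first.columns and first["age_at_exam"].notna().all()
    return CohortSummary(
        n_subjects=len(counts),
        n_female=n_female,
        n_exams=int(len(cohort)),
        visits_per_subject=_agg(counts),
        followup_years=_agg(followup),
        interval_years=_agg(mean_intervals) if mean_intervals else None,
        cag_exp=_agg(subj["cag_exp"]),
        aoga=_agg(subj["aoga"]),
        duration_first=_agg(first["duration"]),
        age_first=_agg(first["age_at_exam"]) if has_age else None,
        icars_first=_agg(first["icars"]),
    )
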