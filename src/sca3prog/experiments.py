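"""Monte-Carlo recovery experiments on synthetic cohorts.

These are the package's calibration studies: generate many cohorts from a
known trajectory truth, run the estimation machinery on each, and summarize
how well the generating parameters (fixed slopes, knot location) are
recovered.  Replicate r uses seed ``base_seed + r`` so a single integer seed
reproduces the whole experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections import Counter

import numpy as np
import pandas as pd

from .design import build_design, registry_spec
from .lmm import fit_lmm
from .pipeline import DEFAULT_KNOT_GRID, knot_search
from .simulate import CohortConfig, default_truth, generate_cohort

__all__ = ["SlopeRecoveryResult", "KnotRecoveryResult",
           "slope_recovery", "knot_recovery"]


@dataclass
class SlopeRecoveryResult:
    """Per-replicate fixed-effect estimates and their MC summary."""

    model_name: str
    truth: dict[str, float]
    estimates: pd.DataFrame  # one row per replicate, one column per term
    n_reps: int
    n_subjects: int

    def mean(self, term: str) -> float:
        return float(self.estimates[term].mean())

    def mc_se(self, term: str) -> float:
        """Monte-Carlo standard error of the mean estimate."""
        return float(self.estimates[term].std(ddof=1) / np.sqrt(self.n_reps))

    def bias(self, term: str) -> float:
        return self.mean(term) - self.truth[term]


def slope_recovery(model_name: str = "PM1", n_reps: int = 200,
                   n_subjects: int = 81, base_seed: int = 1,
                   knot: float = 13.0,
                   config: CohortConfig | None = None) -> SlopeRecoveryResult:
    """Fit the generating model to many synthetic cohorts drawn from its own
    published-column truth; collect the fixed-effect estimates."""
    truth = default_truth(model_name, knot)
    cfg = config if config is not None else CohortConfig(n_subjects=n_subjects)
    cfg = replace(cfg, truth=truth, n_subjects=n_subjects)
    spec = registry_spec(model_name, knot if truth.knot else None)

    rows = []
    for r in range(n_reps):
        cohort = generate_cohort(cfg, seed=base_seed + r)
        fit = fit_lmm(build_design(cohort, spec))
        rows.append(fit.beta_dict())
    return SlopeRecoveryResult(
        model_name=spec.name, truth=dict(truth.beta),
        estimates=pd.DataFrame(rows), n_reps=n_reps, n_subjects=n_subjects,
    )


@dataclass
class KnotRecoveryResult:
    """AIC-selected knots across replicates and their mode."""

    selected: list[float]
    modal_knot: float
    truth_knot: float
    n_reps: int

    def counts(self) -> dict[float, int]:
        return dict(Counter(self.selected))


def knot_recovery(n_reps: int = 50, n_subjects: int = 81, base_seed: int = 1,
                  truth_knot: float = 13.0, grid=DEFAULT_KNOT_GRID
                  ) -> KnotRecoveryResult:
    """Run the knot grid-search on cohorts generated from a knot-13-style
    piece-wise truth; report the modal AIC-selected knot (ties toward the
    smaller knot)."""
    truth = default_truth("PM1", truth_knot)
    cfg = CohortConfig(n_subjects=n_subjects, truth=truth)
    selected = []
    for r in range(n_reps):
        cohort = generate_cohort(cfg, seed=base_seed + r)
        res = knot_search(cohort, candidates=grid, base="PM1")
        selected.append(res.best_knot)
    counts = Counter(selected)
    top = max(counts.values())
    modal = min(k for k, c in counts.items() if c == top)
    return KnotRecoveryResult(selected=selected, modal_knot=float(modal),
                              truth_knot=float(truth_knot), n_reps=n_reps)
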