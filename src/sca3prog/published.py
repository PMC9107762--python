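"""Published coefficient columns of the SCA3 ICARS growth-model ladder.

These are the fixed-effect estimates (with standard errors and printed
p-values) and fit statistics of the twelve growth models fitted to the Dutch
SCA3 cohort (81 participants, 634 ICARS examinations, knot at 13 years of
disease duration).  They serve two purposes in this package:

* as ready-made :class:`~sca3prog.predict.CoefficientSet` inputs for
  fixed-effect ICARS prediction (the published prediction spreadsheets are
  regenerated from the PM2c and PM4c columns), and
* as default "truth" parameters for the synthetic cohort generator, so that
  parameter-recovery experiments run at realistic effect sizes.

p-values are kept as the printed strings (some are reported only as bounds,
e.g. ``"<0.001"``); they are display metadata, never used in computation.
"""

from __future__ import annotations

#: knot (years of disease duration) used by the published piece-wise models
PUBLISHED_KNOT = 13.0

#: number of subjects / observations behind the published fits
PUBLISHED_N_SUBJECTS = 81
PUBLISHED_N_OBS = 634

# Per model: ordered fixed-effect estimates, their SEs, printed p-values, and
# the fit statistics (ML).  Term names follow the registry in
# :mod:`sca3prog.design` (e.g. "dt*CAGexp" is the interaction of raw duration
# with CAG repeat length).
PUBLISHED_COLUMNS: dict[str, dict] = {
    "LM1": {
        "beta": {"intercept": 2.067, "dt": 2.744},
        "se": {"intercept": 1.309, "dt": 0.154},
        "p": {"intercept": "0.115", "dt": "<0.001"},
        "stats": {"aic": 4019.470, "bic": 4046.163, "loglik": -2003.735,
                  "r2_conditional": 0.970, "r2_marginal": 0.479},
    },
    "LM2": {
        "beta": {"intercept": 44.448, "dt": -7.940, "CAGexp": -0.623,
                 "dt*CAGexp": 0.157},
        "se": {"intercept": 24.183, "dt": 2.670, "CAGexp": 0.356,
               "dt*CAGexp": 0.039},
        "p": {"intercept": "0.067", "dt": "0.003", "CAGexp": "0.084",
              "dt*CAGexp": "<0.001"},
        "stats": {"aic": 4013.763, "bic": 4049.328, "loglik": -1998.881,
                  "r2_conditional": 0.971, "r2_marginal": 0.540},
    },
    "LM3": {
        "beta": {"intercept": -16.464, "dt": 4.050, "AOga": 0.446,
                 "dt*AOga": -0.032},
        "se": {"intercept": 5.448, "dt": 0.702, "AOga": 0.128,
               "dt*AOga": 0.016},
        "p": {"intercept": "0.003", "dt": "<0.001", "AOga": "<0.001",
              "dt*AOga": "0.055"},
        "stats": {"aic": 4021.004, "bic": 4056.57, "loglik": -2002.502,
                  "r2_conditional": 0.971, "r2_marginal": 0.480},
    },
    "LM4": {
        "beta": {"intercept": -60.517, "dt": -12.590, "CAGexp": 0.562,
                 "dt*CAGexp": 0.205, "AOga": 0.590, "dt*AOga": 0.025},
        "se": {"intercept": 38.837, "dt": 4.346, "CAGexp": 0.485,
               "dt*CAGexp": 0.054, "AOga": 0.184, "dt*AOga": 0.021},
        "p": {"intercept": "0.120", "dt": "0.005", "CAGexp": "0.250",
              "dt*CAGexp": "<0.001", "AOga": "0.002", "dt*AOga": "0.232"},
        "stats": {"aic": 4005.769, "bic": 4050.194, "loglik": -1992.884,
                  "r2_conditional": 0.972, "r2_marginal": 0.623},
    },
    "QM1": {
        "beta": {"intercept": 10.726, "dt": 1.199, "dt2": 0.069},
        "se": {"intercept": 1.915, "dt": 0.280, "dt2": 0.009},
        "p": {"intercept": "<0.001", "dt": "<0.001", "dt2": "<0.001"},
        "stats": {"aic": 3984.778, "bic": 4015.909, "loglik": -1985.389,
                  "r2_conditional": 0.978, "r2_marginal": 0.488},
    },
    "PM1": {
        "beta": {"intercept": 36.746, "d1": 2.445, "d2": 3.547},
        "se": {"intercept": 1.955, "d1": 0.185, "d2": 0.312},
        "p": {"intercept": "<0.001", "d1": "<0.001", "d2": "<0.001"},
        "stats": {"aic": 3945.904, "bic": 3990.377, "loglik": -1962.952,
                  "r2_conditional": 0.979, "r2_marginal": 0.517},
    },
    "PM2": {
        "beta": {"intercept": -59.997, "d1": -7.264, "d2": -7.516,
                 "CAGexp": 1.429, "d1*CAGexp": 0.144, "d2*CAGexp": 0.162},
        "se": {"intercept": 35.214, "d1": 3.305, "d2": 5.989,
               "CAGexp": 0.519, "d1*CAGexp": 0.049, "d2*CAGexp": 0.088},
        "p": {"intercept": "0.089", "d1": "0.028", "d2": "0.210",
              "CAGexp": "0.007", "d1*CAGexp": "0.003", "d2*CAGexp": "0.067"},
        "stats": {"aic": 3947.395, "bic": 4005.148, "loglik": -1960.697,
                  "r2_conditional": 0.979, "r2_marginal": 0.575},
    },
    "PM2c": {
        "beta": {"intercept": -62.620, "d1": -7.582, "d2": -6.604,
                 "CAGexp": -0.460, "dt*CAGexp": 0.148},
        "se": {"intercept": 31.899, "d1": 2.771, "d2": 2.785,
               "CAGexp": 0.328, "dt*CAGexp": 0.041},
        "p": {"intercept": "0.050", "d1": "0.006", "d2": "0.018",
              "CAGexp": "0.164", "dt*CAGexp": "<0.001"},
        "stats": {"aic": 3942.736, "bic": 3996.066, "loglik": -1959.368,
                  "r2_conditional": 0.979, "r2_marginal": 0.575},
    },
    "PM3": {
        "beta": {"intercept": 35.501, "d1": 3.671, "d2": 5.323,
                 "AOga": 0.026, "d1*AOga": -0.030, "d2*AOga": -0.043},
        "se": {"intercept": 8.876, "d1": 0.817, "d2": 1.582,
               "AOga": 0.206, "d1*AOga": 0.019, "d2*AOga": 0.037},
        "p": {"intercept": "<0.001", "d1": "<0.001", "d2": "<0.001",
              "AOga": "0.898", "d1*AOga": "0.123", "d2*AOga": "0.251"},
        "stats": {"aic": 3952.541, "bic": 4010.294, "loglik": -1963.270,
                  "r2_conditional": 0.979, "r2_marginal": 0.516},
    },
    "PM3c": {
        "beta": {"intercept": 36.472, "d1": 3.787, "d2": 4.878,
                 "AOga": 0.424, "dt*AOga": -0.032},
        "se": {"intercept": 8.274, "d1": 0.723, "d2": 0.765,
               "AOga": 0.112, "dt*AOga": 0.017},
        "p": {"intercept": "<0.001", "d1": "<0.001", "d2": "<0.001",
              "AOga": "<0.001", "dt*AOga": "0.055"},
        "stats": {"aic": 3946.137, "bic": 3999.467, "loglik": -1961.069,
                  "r2_conditional": 0.979, "r2_marginal": 0.517},
    },
    "PM4": {
        "beta": {"intercept": -217.508, "d1": -9.944, "d2": -8.414,
                 "CAGexp": 3.195, "d1*CAGexp": 0.171, "d2*CAGexp": 0.172,
                 "AOga": 0.895, "d1*AOga": 0.018, "d2*AOga": 0.005},
        "se": {"intercept": 57.354, "d1": 5.672, "d2": 9.030,
               "CAGexp": 0.716, "d1*CAGexp": 0.070, "d2*CAGexp": 0.113,
               "AOga": 0.271, "d1*AOga": 0.027, "d2*AOga": 0.047},
        "p": {"intercept": "<0.001", "d1": "0.080", "d2": "0.352",
              "CAGexp": "<0.001", "d1*CAGexp": "0.016", "d2*CAGexp": "0.128",
              "AOga": "0.002", "d1*AOga": "0.517", "d2*AOga": "0.917"},
        "stats": {"aic": 3939.014, "bic": 4010.018, "loglik": -1953.507,
                  "r2_conditional": 0.980, "r2_marginal": 0.641},
    },
    "PM4c": {
        "beta": {"intercept": -216.416, "d1": -9.814, "d2": -8.745,
                 "CAGexp": 0.970, "dt*CAGexp": 0.171,
                 "AOga": 0.680, "dt*AOga": 0.015},
        "se": {"intercept": 49.701, "d1": 4.606, "d2": 4.618,
               "CAGexp": 0.449, "dt*CAGexp": 0.058,
               "AOga": 0.168, "dt*AOga": 0.022},
        "p": {"intercept": "<0.001", "d1": "0.034", "d2": "0.059",
              "CAGexp": "0.034", "dt*CAGexp": "0.003",
              "AOga": "<0.001", "dt*AOga": "0.513"},
        "stats": {"aic": 3928.450, "bic": 3990.623, "loglik": -1950.225,
                  "r2_conditional": 0.980, "r2_marginal": 0.643},
    },
}

#: the twelve models of the published comparison ladder, in column order
LADDER_MODELS = tuple(PUBLISHED_COLUMNS.keys())


def published_beta(name: str) -> dict[str, float]:
    """Fixed-effect estimates of one published model column.

    Raises ``KeyError`` listing valid names for unknown models.
    """
    try:
        return dict(PUBLISHED_COLUMNS[name]["beta"])
    except KeyError:
        raise KeyError(
            f"no published column for {name!r}; available: {sorted(PUBLISHED_COLUMNS)}"
        ) from None


def published_stats(name: str) -> dict[str, float]:
    """Published ML fit statistics (AIC, BIC, logLik, Nakagawa R^2)."""
    try:
        return dict(PUBLISHED_COLUMNS[name]["stats"])
    except KeyError:
        raise KeyError(
            f"no published column for {name!r}; available: {sorted(PUBLISHED_COLUMNS)}"
        ) from None
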