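"""Fit the full 12-model comparison ladder and the ANOVA table.

The ladder spans single-slope linear models (LM1-LM4), a quadratic model
(QM1) and two-segment piece-wise models (PM1-PM4c) with CAG repeat length
and onset age as candidate modifiers.  Models are compared by AIC/BIC/logLik
and likelihood-ratio tests under three schemes: (a) vs LM1, (b) vs PM1, and
(c) each piece-wise model vs its linear counterpart.
"""

from sca3prog import CohortConfig, compare_models, fit_ladder, generate_cohort
from sca3prog.published import LADDER_MODELS

cohort = generate_cohort(CohortConfig(n_subjects=81, seed=1))
ladder = fit_ladder(cohort, names=LADDER_MODELS, knot=13.0)

print(ladder.coefficient_table().to_string())
print("\nANOVA comparisons (stat ~ chi-square on df; NaN = not nested):")
print(compare_models(ladder).to_string(index=False,
                                       float_format=lambda v: f"{v:.3f}"))
print("\nLower AIC/BIC and higher logLik indicate better fit; with this "
      "generating truth the piece-wise models dominate the linear ones.")
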