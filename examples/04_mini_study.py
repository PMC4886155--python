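"""A desk-scale Monte-Carlo comparison of the two estimators.

Runs a small grid (two and five covariates, 10% MAR missingness, 25
replicates of 280 MZ + 720 DZ pairs) and prints the aggregate table: mean
estimates, bias and replicate SD per estimator.  The full run of the
design grid (4 covariate counts x 3 proportions x 3 mechanisms, 200+
replicates) uses the same `run_study` call; see also the `twinfiml study`
command-line entry point.
"""

import pandas as pd

import twinfiml as tf
from twinfiml.study import StudyCondition

conditions = [
    StudyCondition(2, 0.10, "MAR", n_replicates=25),
    StudyCondition(5, 0.10, "MAR", n_replicates=25),
]
result = tf.run_study(conditions, master_seed=11, progress=True)
agg = result.aggregate()

pd.set_option("display.width", 160)
cols = ["condition", "approach", "parameter", "truth", "mean", "bias", "empirical_sd"]
view = agg[agg.parameter.isin(["sigma2_A", "sigma2_C"])][cols]
print(view.round(4).to_string(index=False))
print()
print("Even at 25 replicates the pattern is visible: the usual approach's")
print("replicate SD grows with the number of covariates (more individuals")
print("deleted) while the full-information SD stays put, and the usual")
print("shared-environment estimate is pulled below its generating value.")
print("Expected usual-approach individual loss:",
      f"K=2: {tf.expected_deleted_fraction(0.10, 2):.0%},",
      f"K=5: {tf.expected_deleted_fraction(0.10, 5):.0%}")
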