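"""Simulate one twin study with missing covariates and fit both estimators.

Draws the design dataset (280 MZ + 720 DZ pairs, five covariates), deletes
10% of the covariate entries MAR (lower-scoring twins lose more answers),
then fits the full-information estimator (uses every observed value) and
the usual twin-wise-deletion estimator.  The deletion estimator loses about
40% of the individuals and visibly underestimates the shared-environment
variance.
"""

import numpy as np

import twinfiml as tf

config = tf.SimulationConfig()  # the study design defaults
rng = np.random.default_rng(2025)
complete = tf.simulate_dataset(config, rng)
observed = tf.impose_missingness(complete, tf.MissingnessSpec("MAR", 0.10), rng)
print(observed)
print("masked covariate entries:", int(np.isnan(observed.X).sum()), "of", 2 * len(observed) * observed.K)
print()

full = tf.fit_full_information(observed)
usual = tf.fit_usual(observed)

print(f"{'':>12}  {'truth':>6}  {'full-info (SE)':>16}  {'usual (SE)':>16}")
truth = {"sigma2_A": 0.5, "sigma2_C": 0.3, "sigma2_E": 0.2}
for name in truth:
    f_est = getattr(full.ace, name)
    u_est = getattr(usual.ace, name)
    print(
        f"{name:>12}  {truth[name]:>6.2f}  "
        f"{f_est:>8.3f} ({full.se[name]:.3f})  {u_est:>8.3f} ({usual.se[name]:.3f})"
    )
print(f"{'h2':>12}  {0.50:>6.2f}  {full.h2:>8.3f} ({full.h2_se:.3f})  {usual.h2:>8.3f} ({usual.h2_se:.3f})")
print()
print("full-information used all", full.n_pairs_used, "pairs;")
print(
    "usual approach kept", usual.n_pairs_used, "intact pairs +",
    usual.n_singletons_used, "singletons",
    f"(~{2*usual.n_pairs_used + usual.n_singletons_used} of {2*len(observed)} individuals).",
)
print("Note the smaller full-information SEs and the usual approach's")
print("downward-biased shared-environment estimate under MAR deletion.")
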