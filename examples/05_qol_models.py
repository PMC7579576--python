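"""Relate complexity indicators to quality-of-life dimensions.

QoL scores for the clinical group are generated with a planted negative
dependence of self-determination on global clustering (slope -2, noise
sized for R^2 of about 0.5).  The flagged Pearson correlations and the
AIC-stepwise linear model should both recover the negative relation.
"""

import numpy as np

from dmnqol import (
    CohortConfig,
    PipelineConfig,
    QoLGenSpec,
    gen_cohort,
    gen_qol_table,
    profile_cohort,
    run_relate,
)

config = PipelineConfig(
    cohort=CohortConfig(n_group_a=1, n_group_b=40), n_null=20, seed=21
)
profiled = profile_cohort(gen_cohort(config.cohort), config)
profiles = [p for p, lab in profiled if lab == "ds"]

clustering = np.array([p.global_clustering for p in profiles])
spec = QoLGenSpec(
    slopes={("self_determination", "global_clustering"): -2.0},
    noise_sd=2.0 * clustering.std(ddof=1),
    seed=22,
)
qol = gen_qol_table(profiles, spec)
corr, models_table, models = run_relate(profiles, qol)

r = corr.r.loc["self_determination", "global_clustering"]
flag = corr.flags.loc["self_determination", "global_clustering"]
print(f"corr(self-determination, clustering) = {r:.3f} {flag}")
model = [m for m in models if m.response == "self_determination"][0]
print(f"stepwise model for self-determination "
      f"(R^2 = {model.r_squared:.3f}, AIC = {model.aic:.2f}):")
for name, beta in model.coefficients.items():
    print(f"  {name:20s} {beta:+.3f}")
print(
    "\nA negative clustering coefficient close to the planted -2 confirms "
    "the pipeline recovers the inverse complexity-QoL relation; flags: "
    "* p < 0.05, ** p < 0.001."
)
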