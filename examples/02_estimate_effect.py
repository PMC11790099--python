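"""Estimate the treatment effect with all four causal estimators.

On a null-effect simulation with severity-driven confounding, the naive
mortality contrast is strongly biased (sicker patients get albumin);
the adjusted estimators should sit near zero.  AIPW gets a 50-replicate
patient-level bootstrap interval.
"""

import ehrtrial as et

tables, truth = et.simulate(et.SimConfig(n_patients=8_000, seed=7, true_ate_rd=0.0))
spec = et.CohortSpec()
ridge = et.NuisanceSpec("ridge_logistic", search_budget=1)

print(f"true risk difference: {truth.ate:+.3f}\n")
for estimator in ("naive", "IPW", "Gformula_T", "AIPW", "DML"):
    config = et.AnalysisConfig(
        aggregation="first_and_last",
        estimator=estimator,
        nuisance=ridge,
        n_bootstrap=50 if estimator == "AIPW" else 0,
        seed=1,
    )
    est, cohort = et.estimate_effect(tables, spec, config)
    ci = f"  95% CI [{est.ci[0]:+.3f}, {est.ci[1]:+.3f}]" if est.ci else ""
    print(f"{estimator:11s} RD = {est.point:+.4f}{ci}")

print("\nThe naive contrast shows the confounding; adjusted estimates "
      "recover the (null) effect. The AIPW interval should cover zero.")
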