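"""Estimate frailty-outcome associations in one trial.

Fits the Poisson model for serious adverse events (first event, log
observation-time offset) and the logistic model for trial attrition, both
adjusted for age and sex, and reports effects per 0.1-unit FI.
"""

import frailtykit as fk

config = fk.preset("dementia", n=2000, seed=11)
baseline, outcomes, truth = fk.generate_trial(config)

fi_table = fk.build_fi_table(baseline, config.catalog, "physical")
prepared = fk.prepare_outcomes(outcomes, follow_up=config.follow_up_days)
data = (
    fi_table.loc[~fi_table["excluded"]]
    .merge(prepared, on="participant_id")
    .merge(baseline[["participant_id", "age_years", "sex"]], on="participant_id")
)

sae = fk.fit_poisson_sae(data)
attr = fk.fit_logistic_attrition(data)
inter = fk.fit_interaction("poisson_sae", data)

print(f"SAE incidence rate ratio per 0.1 FI: {sae.effect:.2f} "
      f"[{sae.effect_ci95[0]:.2f}, {sae.effect_ci95[1]:.2f}]  "
      f"(generating value {truth['sae_irr_per_01fi']:.2f})")
print(f"attrition odds ratio per 0.1 FI:     {attr.effect:.2f} "
      f"[{attr.effect_ci95[0]:.2f}, {attr.effect_ci95[1]:.2f}]  "
      f"(generating value {truth['attr_or_per_01fi']:.2f})")
print(f"sex x FI interaction Wald p = {inter.interaction.p:.3f} "
      "(no interaction was simulated)")

# An IRR of e.g. 1.6 means each 0.1-unit FI increase multiplies the SAE
# hazard by 1.6; the CIs should bracket the generating values.
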