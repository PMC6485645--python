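"""Fit the logistic mixed-effects growth model to a synthetic cohort.

Generates 30 untreated primary-lesion volume series (logistic growth,
10% multiplicative measurement noise), fits the hierarchical Bayesian
model by MCMC, and compares the three candidate growth laws by AIC.
"""

import warnings

warnings.filterwarnings("ignore")

from pdacsim import (
    LesionClass,
    McmcOptions,
    MixedEffectsSpec,
    ModelKind,
    fit_mixed_model,
    generate_cohort,
    model_selection_cohort_config,
    select_model,
)

cfg = model_selection_cohort_config(n=30, seed=0, noise_sd=0.1)
truth, cohort = generate_cohort(cfg)
print(f"cohort: {len(cohort)} lesions, {cohort[0].n_scans} scans each")

fits = {}
for kind in (ModelKind.LOGISTIC, ModelKind.EXPONENTIAL, ModelKind.LINEAR):
    spec = MixedEffectsSpec.for_cohort(kind, LesionClass.PRIMARY)
    fits[kind.value] = fit_mixed_model(
        cohort, spec, McmcOptions(chains=2, iterations=2000, seed=1)
    )

post = fits["logistic"]
print("\nlogistic fixed effects (posterior median and quartiles):")
print(post.fixed[["param", "median", "q1", "q3", "rhat"]].to_string(index=False))
print(f"\ntrue fixed-effect rate 0.28/month, capacity median {truth.capacity_cm3.median():.1f} cm^3")

print("\ngrowth-law comparison (AIC, lower is better):")
print(select_model(fits).to_string(index=False))
print(
    "\nThe logistic law should rank first: the data were generated from it, "
    "and the late, saturating scans separate it from the alternatives."
)
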