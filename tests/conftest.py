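import warnings

import pytest

warnings.filterwarnings("ignore", message=".*ArviZ is undergoing a major refactor.*")


@pytest.fixture(scope="session")
def recovery_fit():
    """One shared logistic mixed-effects fit of the recovery benchmark cohort.

    n = 50 lesions, 5 scans, 10% log-normal noise; reused by the
    parameter-recovery acceptance check and the pipeline-closure test.
    """
    from pdacsim import (
        LesionClass,
        McmcOptions,
        MixedEffectsSpec,
        ModelKind,
        fit_mixed_model,
        generate_cohort,
        recovery_cohort_config,
    )

    cfg = recovery_cohort_config(n=50, seed=42, noise_sd=0.1)
    truth, cohort = generate_cohort(cfg)
    spec = MixedEffectsSpec.for_cohort(ModelKind.LOGISTIC, LesionClass.PRIMARY)
    post = fit_mixed_model(cohort, spec, McmcOptions(chains=4, iterations=4000, seed=1))
    return cfg, truth, cohort, post
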