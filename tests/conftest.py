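import numpy as np
import pytest

import atnreserve as a


@pytest.fixture(scope="session")
def default_truth():
    return a.TrueParams()


@pytest.fixture(scope="session")
def small_cohort(default_truth):
    """Moderate cohort with missingness, preprocessed (analysis scale)."""
    cc = a.CohortConfig(n_subjects=500, seed=42, complete_biomarker_fraction=0.6)
    raw = a.apply_missingness(a.generate_cohort(cc, default_truth), cc)
    return a.preprocess(raw)


@pytest.fixture(scope="session")
def mediation_dataset(default_truth):
    """Complete-biomarker analysis sample (n=332), true latent moderator,
    EF on the generator's raw scale so the estimand equals the truth."""
    cc = a.CohortConfig(n_subjects=332, seed=7, complete_biomarker_fraction=1.0)
    raw = a.apply_missingness(a.generate_cohort(cc, default_truth), cc)
    pre = a.preprocess(raw, standardize_ef=False)
    spec = a.MediationSpec(w_col="true_memr")
    return a.build_design(pre, spec)


@pytest.fixture(scope="session")
def mediation_fit(mediation_dataset):
    return a.fit_growth_mediation(mediation_dataset)
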