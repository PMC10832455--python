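import numpy as np
import pandas as pd
import pytest

from pufa_phewas.prep import prepare_cohort
from pufa_phewas.synthetic import (CohortSpec, DiseaseSpec, MetaboliteSpec,
                                   SummaryStatsSpec, generate_cohort,
                                   generate_summary_stats)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Prepared 6k cohort: one metabolite with a protective effect, one null disease."""
    spec = CohortSpec(
        n_individuals=6000, seed=42,
        metabolites=[MetaboliteSpec("omega3")],
        diseases=[
            DiseaseSpec("d_eff", group="endocrine", baseline_prevalence=0.15,
                        beta_metabolite=-0.4, beta_prs=0.3, metabolite="omega3"),
            DiseaseSpec("d_null", group="circulatory", baseline_prevalence=0.10,
                        metabolite="omega3"),
            DiseaseSpec("d_rare", group="digestive", baseline_prevalence=0.004,
                        metabolite="omega3"),
        ])
    return prepare_cohort(generate_cohort(spec), ["omega3"])


@pytest.fixture(scope="session")
def mr_pair():
    """Harmonizable exposure/outcome tables with a causal effect of -0.3."""
    return generate_summary_stats(SummaryStatsSpec(seed=11, causal_effect=-0.3, n_snps=50))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
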