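import numpy as np
import pytest

import methylmr as mm
from methylmr.lmm import build_covariate_design


@pytest.fixture(scope="session")
def small_study():
    """A modest null-coupling study with active instruments (n ~ 600)."""
    return mm.simulate_study(mm.null_scenario(seed=42))


@pytest.fixture(scope="session")
def forward_study():
    """Strong forward causal effect (log-TG -> M-value, gamma = -0.12)."""
    return mm.simulate_study(mm.lipid_to_meth_scenario(seed=7))


def study_frames(study):
    """Covariate design, family vector and log-TG for a simulated study."""
    p = study.phenotypes
    cov = build_covariate_design(p.df)
    fam = p.df["family_id"].to_numpy()
    logtg = np.log(p.df["tg"].to_numpy())
    return cov, fam, logtg
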