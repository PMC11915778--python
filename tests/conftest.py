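import numpy as np
import pytest

from cesofa import GeneratorConfig, generate_cohort
from cesofa.cohort import PatientRecord


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort with the default effect structure, n = 200."""
    return generate_cohort(GeneratorConfig(n=200, seed=11), label="small")


@pytest.fixture(scope="session")
def train_cohort():
    """Training-sized synthetic cohort (n = 250)."""
    return generate_cohort(GeneratorConfig(n=250, seed=23), label="train")


@pytest.fixture()
def null_config():
    """Generator config with all outcome effects switched off."""
    cfg = GeneratorConfig(n=200, seed=5)
    cfg.effect_log_odds = {k: 0.0 for k in cfg.effect_log_odds}
    return cfg


def make_record(**overrides) -> PatientRecord:
    """A valid baseline patient; override any field."""
    base = dict(
        id="P1", age=70.0, sex="male", sbp=120.0, dbp=70.0, hr=90.0,
        hs_ctnt=10.0, nt_probnp=500.0, af_status="none",
        norepinephrine_dose=0.0, dopamine_dose=0.0, other_vasoactive=False,
        sofa_neuro=0, sofa_resp=0, sofa_renal=0, sofa_hepatic=0, sofa_coag=0,
        died_30d=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture()
def record_factory():
    return make_record
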