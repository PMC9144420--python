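import numpy as np
import pytest

from hupkpd import ErythroParams, HbFParams, LeukoParams, PKParameters


@pytest.fixture(scope="session")
def pk_population_mean() -> PKParameters:
    """Population-mean PK constants of the pediatric cohort."""
    return PKParameters(F=0.12, ktr=5.02, Nt=1.14, ke=0.54)


@pytest.fixture(scope="session")
def erythro_median() -> ErythroParams:
    """Population-median erythropoiesis/MCV constants."""
    return ErythroParams(
        kpe_max=2.10e12, psi_e=2.20e11, gamma_e=1.6,
        kdse_max=0.17, Kdse50=0.43, kte=0.2,
        kde_max=0.03, Kde50=310.0, alpha=0.37, Vm0=85.34,
    )


@pytest.fixture(scope="session")
def leuko_median() -> LeukoParams:
    """Population-median leukopoiesis constants."""
    return LeukoParams(
        kpl_max=1.10e12, psi_l=4.70e8, gamma_l=3.5,
        kdsl_max=0.16, Kdsl50=0.3, ktl=0.09, kdl=0.13,
    )


@pytest.fixture(scope="session")
def hbf_median() -> HbFParams:
    """Population-median fetal-hemoglobin activation constants."""
    return HbFParams(
        kmet=1.2, Kmet=27.0, kdi=0.03, kbf=0.16,
        kaf=1.5, Kaf=13.0, n=3.2, kdf=0.07,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
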