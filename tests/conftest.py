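import numpy as np
import pytest

import replimix as rm


@pytest.fixture
def null_mixture() -> rm.ZMixture:
    """Pure-noise model: every z is standard normal, SNR is identically 0."""
    return rm.ZMixture(np.array([1.0]), np.array([1.0]))


@pytest.fixture
def two_comp_mixture() -> rm.ZMixture:
    return rm.ZMixture(np.array([0.5, 0.5]), np.array([1.0, 2.0]))


@pytest.fixture
def truth_mixture() -> rm.ZMixture:
    """The z-scale truth used across recovery checks: w=(0.6,0.4), sigma=(1.5,4)."""
    return rm.ZMixture(np.array([0.6, 0.4]), np.array([1.5, 4.0]))


@pytest.fixture
def toy_csv(tmp_path):
    """Five-row effect table exercising derivation and filtering rules."""
    p = tmp_path / "toy.csv"
    p.write_text(
        "meta,study,est,v,kind,title\n"
        "M1,S1,0.5,0.0625,SMD,Alpha study\n"
        "M1,S1,-0.3,0.09,SMD,Alpha study\n"
        "M1,S2,0.2,0,lnRR,Beta study\n"
        "M2,S3,1.1,,Zr,Gamma study\n"
        "M2,S4,0.8,0.16,SMD,Delta study\n"
    )
    return p


@pytest.fixture
def toy_schema():
    return {"es": "est", "var": "v", "study": "study", "meta": "meta",
            "effect_type": "kind", "label": "title"}
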