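"""Shared fixtures: phantoms, trained toy models, synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from itmt.growth_charts import CentileModel, SplineCurve, make_basis
from itmt.imaging_io import preprocess
from itmt.phantom import PhantomSpec, generate_cohort, generate_phantom, linear_lms
from itmt.training import train_toy_models


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless reference phantom: thickness 8 mm left / 12 mm right."""
    spec = PhantomSpec(thickness_left_mm=8.0, thickness_right_mm=12.0, noise_sigma=0.0, seed=0)
    vol, left, right, z0 = generate_phantom(spec)
    return {"spec": spec, "vol": vol, "left": left, "right": right, "z0": z0}


@pytest.fixture(scope="session")
def preprocessed_phantom(clean_phantom):
    return {**clean_phantom, "vol_p": preprocess(clean_phantom["vol"])}


@pytest.fixture(scope="session")
def toy_models():
    """Slice regressor + segmenter trained on a small phantom family."""
    return train_toy_models(n_phantoms=4, seed=0)


@pytest.fixture(scope="session")
def lms_cohort():
    """n=2000 single-sex cohort from known curves L=1, M=6+0.3t, S=0.12."""
    curves = {"M": linear_lms(1.0, 6.0, 0.3, 0.12), "F": linear_lms(1.0, 6.0, 0.3, 0.12)}
    return generate_cohort(2000, sex_ratio=1.0, true_lms=curves, seed=7)


@pytest.fixture(scope="session")
def lms_fit(lms_cohort):
    from itmt.growth_charts import fit_lms

    return fit_lms(lms_cohort, "M", df_candidates=(2, 3, 4, 5), seed=0)


def constant_lms_model(L: float, M: float, S: float, domain=(4.0, 30.0)) -> CentileModel:
    """A CentileModel with constant curves, for closed-form checks."""
    ages = np.linspace(*domain, 20)

    def const(value, link):
        knots, degree = make_basis(ages, 1, domain)
        coef = np.array([np.log(value) if link == "log" else value], dtype=float)
        return SplineCurve(knots, degree, coef, link=link)

    return CentileModel(
        sex="M",
        L=const(L, "identity"),
        M=const(M, "log"),
        S=const(S, "log"),
        age_domain=domain,
        n=0,
        loglik=0.0,
        bic=0.0,
        df={"L": 1, "M": 1, "S": 1},
    )


@pytest.fixture()
def normal_model():
    """L=1, M=10 mm, S=0.1: the analytic reference chart."""
    return constant_lms_model(1.0, 10.0, 0.1)
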