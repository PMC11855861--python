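import numpy as np
import pytest

from demandtx import (
    DEFAULT_PRICE_LADDER,
    ConsumptionCurve,
    DemandParams,
    predict_consumption,
)


@pytest.fixture(scope="session")
def ladder():
    return np.asarray(DEFAULT_PRICE_LADDER, dtype=float)


def make_noiseless_curve(params: DemandParams, ladder, subject="s", group="METH"):
    return ConsumptionCurve(subject, group, ladder, predict_consumption(params, ladder))


def make_noisy_curve(params, ladder, noise_sd, rng, subject="s", group="METH"):
    import demandtx as dx

    log10_q = np.asarray(dx.predict_log10_consumption(params, ladder))
    q = 10.0 ** (log10_q + rng.normal(0.0, noise_sd, size=ladder.size))
    return ConsumptionCurve(subject, group, ladder, q)


@pytest.fixture
def noiseless_curve(ladder):
    return make_noiseless_curve(DemandParams(10.0, 0.003, 2.5), ladder)
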