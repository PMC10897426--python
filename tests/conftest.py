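import numpy as np
import pytest

from mmpsim import (
    DEFAULT_BIMODAL,
    DivisionModelParams,
    FlowSample,
    Stratum,
    default_division_params,
    generate_flow_sample,
)


@pytest.fixture(scope="session")
def bimodal_sample() -> FlowSample:
    """10,000 events from the default bimodal TMRM-like fixture."""
    return generate_flow_sample(DEFAULT_BIMODAL, 10_000, seed=7)


@pytest.fixture(scope="session")
def normal_parental() -> FlowSample:
    """A parental bulk population modelled as Normal(10, 1) on the activity
    scale (clamped at the floor of 1), 10,000 events."""
    rng = np.random.default_rng(321)
    return FlowSample("bulk", np.maximum(rng.normal(10.0, 1.0, 10_000), 1.0))


@pytest.fixture(scope="session")
def default_params(normal_parental) -> DivisionModelParams:
    """Division-model defaults matched to the normal parental population:
    t = 1.25, m = 0.8, low stratum (below the parental mean) with increase
    probability 0.8, symmetric outcomes elsewhere."""
    return default_division_params(normal_parental)


def single_stratum_params(probs, *, m=0.8, t=1.25, cap=10_000_000, **kw) -> DivisionModelParams:
    """One stratum covering (0, inf) with the given (p_I, p_J, p_K)."""
    return DivisionModelParams(
        m=m, n_coef=t, strata=(Stratum(0.0, np.inf, probs),),
        population_cap=cap, **kw,
    )
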