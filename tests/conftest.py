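import numpy as np
import pytest

from wolbsim import ModelParams


@pytest.fixture(scope="session")
def baseline() -> ModelParams:
    """Baseline wAlbB / Anopheles parameter set."""
    return ModelParams()


def random_params(rng: np.random.Generator, *, v_w: float | None = None,
                  c_i: float | None = None,
                  equal_male_rates: bool = False) -> ModelParams:
    """A random valid parameter draw: rates jittered around baseline on a
    log scale, fractions drawn uniformly unless pinned."""
    base = ModelParams()
    updates = {}
    for name in ModelParams.RATE_FIELDS:
        updates[name] = getattr(base, name) * float(10 ** rng.uniform(-0.3, 0.3))
    if equal_male_rates:
        updates["mu_mw"] = updates["mu_mu"]
    updates["v_w"] = float(rng.uniform(0.5, 1.0)) if v_w is None else v_w
    updates["c_i"] = float(rng.uniform(0.0, 1.0)) if c_i is None else c_i
    updates["b_f"] = float(rng.uniform(0.3, 0.7))
    updates["K_l"] = float(base.K_l * 10 ** rng.uniform(-1, 1))
    return ModelParams(**updates)
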