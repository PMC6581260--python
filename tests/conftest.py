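import math

import numpy as np
import pytest

from hbinfer.models import ModelSpec, SubjectData


@pytest.fixture(scope="session")
def rl_subject():
    """A deterministic RL-generated bandit subject (T=100)."""
    import hbinfer as hb
    spec = hb.get_model("rl")
    task = hb.generate_task("bandit2", 100, seed=12345)
    return spec, hb.simulate_agent(spec, [-0.8, 1.1], task, seed=99)


def gaussian_toy_model(prec_lik: float = 4.0, name: str = "gauss_toy") -> ModelSpec:
    """One-parameter model with a known Gaussian likelihood of precision
    ``prec_lik`` around the (single) observed outcome; the Laplace
    approximation is exact for it, making conjugate closed forms available
    as oracles."""

    def ll(th, d):
        x = d.outcomes[0]
        return float(-0.5 * math.log(2 * math.pi / prec_lik)
                     - 0.5 * prec_lik * (x - th[0]) ** 2)

    return ModelSpec(name, "bandit2", ("m",), ("identity",), ll, None)


def toy_subject(x: float) -> SubjectData:
    return SubjectData(choices=[0], outcomes=[float(x)])
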