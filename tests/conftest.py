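import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neurosep as ns

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def grid22() -> ns.StimulusGrid:
    return ns.StimulusGrid(levels_a=2, levels_b=2)


@pytest.fixture
def separable_model(grid22) -> ns.EncodingModel:
    """Four Gaussian channels tuned to dimension A only, unit channel noise."""
    bank = ns.make_gaussian_tuning_bank(
        grid22,
        centers=[0.5, 1.1667, 1.8333, 2.5],
        widths=1.0,
        gains=1.0,
        dim_values=[1.0, 2.0],
    )
    return ns.build_encoding_model(grid22, bank, 1.0)


@pytest.fixture
def discriminant_decoder(separable_model) -> ns.LinearDecoder:
    f1 = separable_model.mean((1, 1))
    f2 = separable_model.mean((2, 1))
    b = (f2 - f1) / np.linalg.norm(f2 - f1)
    return ns.LinearDecoder(beta=-float(b @ (f1 + f2)) / 2, weights=b)
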