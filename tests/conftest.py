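import pytest

from phenovir import ModelParams


@pytest.fixture(scope="session")
def baseline() -> ModelParams:
    """Baseline parameter set: T=3, t_l=1, tau=1.5, beta=200, delta=2, mu=0.5."""
    return ModelParams()
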