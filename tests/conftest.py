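import pytest

from scrunchkit import GaitParams, RenderParams, generate_length_trace, render_worm_stack
from scrunchkit.classify import load_reference_table


def scrunch_params(**overrides) -> GaitParams:
    base = dict(gait_kind="scrunching", frequency_hz=0.5, max_elongation=0.5,
                asymmetry=0.6, gliding_length=100.0, duration_s=10.0, fps=10.0,
                noise_sd=0.0, seed=0)
    base.update(overrides)
    return GaitParams(**base)


@pytest.fixture(scope="session")
def refs():
    return load_reference_table()


@pytest.fixture(scope="session")
def rendered_gliding():
    """Short noise-free gliding recording with frames and masks."""
    params = GaitParams(gait_kind="gliding", gliding_length=100.0, duration_s=2.0)
    trace, truth = generate_length_trace(params)
    stack, truth = render_worm_stack(trace, truth, RenderParams(worm_width=10.0))
    return stack, truth
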