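import numpy as np
import pytest

from wmidetect import PhantomSpec, LesionSpec, StateSpace, StateImage, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_state_image(states, n_states=None, stretched=None):
    """Build a StateImage directly from an integer label array (tests only)."""
    states = np.asarray(states, dtype=np.int64)
    if n_states is None:
        n_states = int(states.max()) + 1
    space = StateSpace(n_states)
    if stretched is None:
        stretched = np.where(states >= 0, states / max(space.n, 1), 0.0)
    return StateImage(
        states=states,
        space=space,
        source_stats=(0.0, 1.0),
        stretched=np.asarray(stretched, dtype=float),
    )


@pytest.fixture
def lesioned_phantom():
    spec = PhantomSpec(
        seed=11,
        lesions=(
            LesionSpec(center=(58, 60), radius=4, contrast=6.0),
            LesionSpec(center=(72, 74), radius=3, contrast=6.0),
        ),
    )
    return generate(spec)


@pytest.fixture
def clean_phantom():
    return generate(PhantomSpec(seed=12))
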