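import numpy as np
import pytest

from elscape import io as eio
from elscape import synth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_model(rng):
    """A random, well-conditioned (h, J) pair at C=7."""
    c = 7
    h = rng.uniform(-0.5, 0.5, c)
    J = rng.uniform(-0.5, 0.5, (c, c))
    J = (J + J.T) / 2
    np.fill_diagonal(J, 0.0)
    return h, J


def make_recording(
    n_channels=3,
    fs=7.81,
    trial_s=2.0,
    rest_s=1.0,
    labels=("happy", "calm", "fear", "noise"),
    n_blocks=1,
    seed=0,
    subject_id="s01",
    group="HC",
):
    """Tiny paradigm-shaped recording with one trial per label per block."""
    rng = np.random.default_rng(seed)
    spt = int(round(trial_s * fs))
    rest_n = int(round(rest_s * fs))
    order = [lab for _ in range(n_blocks) for lab in labels]
    total = len(order) * (rest_n + spt)
    signal = rng.normal(size=(total, n_channels))
    annotations = []
    cursor = 0
    for lab in order:
        cursor += rest_n
        annotations.append(
            eio.Annotation(onset=cursor / fs, duration=spt / fs, label=lab)
        )
        cursor += spt
    return eio.Recording(
        subject_id=subject_id,
        group=group,
        channel_ids=[f"ch{i + 1}" for i in range(n_channels)],
        fs=fs,
        signal=signal,
        annotations=annotations,
    )


@pytest.fixture
def tiny_recording():
    return make_recording()


@pytest.fixture(scope="session")
def small_state_cohort():
    """A small cohort of planted state series shared across tests."""
    config = synth.CohortConfig(n_per_group=6, seed=123)
    series, truth = synth.generate_state_cohort(config)
    return config, series, truth
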