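import numpy as np
import pytest

from riderp.core import EpochSet, default_layout
from riderp.simulate import ComponentSpec, SimConfig, simulate_trials


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_epochs(rng):
    """Random 6-trial, 4-channel epoch set (includes a mastoid pair)."""
    times = np.arange(-100, 500) * 2.0
    data = rng.normal(0.0, 5.0, (6, 4, len(times)))
    return EpochSet(
        data=data,
        times=times,
        conditions=np.array(["CON", "SEM", "SEM+SYN"] * 2, dtype=object),
        subject_id="S01",
        montage=["Cz", "Pz", "M1", "M2"],
    )


LATENCY_CHANNELS = ["Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"]


def single_component_config(
    seed: int,
    n_trials: int = 200,
    amplitude: float = 5.0,
    width: float = 50.0,
    latency_sd: float = 50.0,
    noise_sd: float = 0.25,
    mu: float = 400.0,
) -> SimConfig:
    """One jittered N400-like bump on a 7-channel midline montage."""
    comp = ComponentSpec(
        name="C1",
        mu=mu,
        width=width,
        scalp_weights=np.ones(len(LATENCY_CHANNELS)),
        amplitude_by_condition={"SEM": amplitude},
        latency_sd=latency_sd,
    )
    return SimConfig(
        seed=seed,
        n_subjects=1,
        trials_per_condition=n_trials,
        conditions=("SEM",),
        components=[comp],
        noise_sd=noise_sd,
        channels=LATENCY_CHANNELS,
        subject_gain_sd=0.0,
    )


@pytest.fixture(scope="session")
def jittered_single_component(layout):
    """200 trials of a width-50 bump with 50 ms latency jitter, low noise."""
    cfg = single_component_config(seed=11)
    epochs, truth = simulate_trials(cfg, layout)
    return epochs[0], truth
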