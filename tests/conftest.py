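import numpy as np
import pytest

from motilimap.synth import GroundTruthEvent, SimulationSpec, generate_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240811)


@pytest.fixture
def small_recording():
    """A small tapered recording with one ripple and one standing contraction."""
    spec = SimulationSpec(
        length_mm=30.0, n_frames=120, noise_sd_mm=0.0, seed=5, profile="taper"
    )
    events = [
        GroundTruthEvent(
            type="ripple",
            onset_time_s=20.0,
            initiation_site_mm=8.0,
            velocity_mm_per_s=0.25,
            direction="anterograde",
            duration_s=20.0,
            amplitude_frac=0.3,
            halfwidth_mm=1.0,
            kernel="square",
            envelope="square",
        ),
        GroundTruthEvent(
            type="standing",
            onset_time_s=60.0,
            initiation_site_mm=22.0,
            velocity_mm_per_s=0.0,
            direction="none",
            duration_s=8.0,
            amplitude_frac=0.4,
            halfwidth_mm=0.25,
            kernel="square",
            envelope="square",
        ),
    ]
    dm, gts = generate_matrix(spec, events)
    return dm, gts, spec
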