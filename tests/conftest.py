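import pytest

import neorhythm as nr


@pytest.fixture(scope="session")
def montage():
    return nr.build_montage()


@pytest.fixture(scope="session")
def stimulus_sets():
    """Full audio stimulus set (30 rhythmic + 30 matched arrhythmic), seed 0."""
    return nr.render_stimulus_sets(seed=0)


@pytest.fixture(scope="session")
def light_sets():
    """Event-level stimulus set (no audio), seed 0."""
    return nr.render_stimulus_sets(seed=0, synthesize_audio=False)


@pytest.fixture(scope="session")
def protocol(light_sets):
    rhythmic, arrhythmic = light_sets
    return nr.build_protocol(rhythmic + arrhythmic, seed=0)


@pytest.fixture(scope="session")
def noisefree_session(montage, protocol):
    cfg = nr.SynthConfig()
    truth = nr.make_ground_truth(montage, cfg, effect="default")
    return nr.simulate_session(
        montage, truth, protocol, cfg, seed=0, noise=False, artifacts=False
    )


@pytest.fixture(scope="session")
def noisy_session(montage, protocol):
    cfg = nr.SynthConfig()
    truth = nr.make_ground_truth(montage, cfg, effect="default")
    return nr.simulate_session(montage, truth, protocol, cfg, seed=3)
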