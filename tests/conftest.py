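import numpy as np
import pytest

from mersuite.synth import UnitSpec, render_extracellular


@pytest.fixture(scope="session")
def two_template_noiseless():
    """Noiseless rendering of two well-separated units (ground truth known).

    The seed is chosen so the two trains never collide within a waveform
    window: resolving overlapping spikes is out of scope for the sorter, so
    the clean-recovery fixture must not contain superposition events.
    """
    units = [
        UnitSpec(rate=2.0, process="gamma", kappa_shape=4.0, template_id=0, peak_amp=1.0),
        UnitSpec(rate=4.0, process="gamma", kappa_shape=4.0, template_id=2, peak_amp=0.6),
    ]
    rec = render_extracellular(units, 45.0, 20_000.0, noise_sd=0.0, seed=11)
    allt = np.sort(np.concatenate([u["timestamps"] for u in rec.truth["units"]]))
    assert np.diff(allt).min() > 3e-3
    return rec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
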