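import numpy as np
import pytest

from sfica import inverse, simulate, tfr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_subject():
    """A small planted three-network subject run through STFT + inverse.

    64-Hz sampling with a 128-point FFT keeps the 0.5-Hz bin spacing of
    the full design at a fraction of the cost (Nt=128, Ns=100).
    """
    sc, L, feats = simulate.three_network_scenario(
        n_channels=32, n_sources=100, duration=128.0, fs=64.0,
        sensor_noise_sd=0.02, seed=11)
    rec, gt = simulate.simulate_subject(sc, leadfield=L, features=feats)
    inv = inverse.compute_inverse_operator(L, lambda2=0.1, depth_gamma=0.8)
    sensor = tfr.select_band(tfr.stft(rec, nfft=128))
    dm = tfr.build_design_matrix(tfr.project_tfr(sensor, inv))
    return {"scenario": sc, "leadfield": L, "features": feats, "rec": rec,
            "truth": gt, "inv": inv, "tfr": sensor, "dm": dm}
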