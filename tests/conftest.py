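import numpy as np
import pandas as pd
import pytest

import dentspike as ds


@pytest.fixture(scope="session")
def clean_pool():
    """Noise-free 1000 DS1 + 1000 DS2 pool: waveform matrix over ±100 ms on
    the hilus channel, ground-truth types, and the recording itself."""
    cfg = ds.SynthConfig(duration_s=2700, n_ds1=1000, n_ds2=1000,
                         noise_sd_mv=0.0, delta_amp_mv=0.0, theta_amp_mv=0.0,
                         seed=8)
    rec, truth = ds.synthesize_recording(cfg)
    wm = ds.extract_waveforms(rec, truth, window=(-100.0, 100.0), channel=12)
    types = truth.set_index("event_id").loc[wm.event_ids, "true_type"].to_numpy()
    return rec, truth, wm, types


@pytest.fixture(scope="session")
def noisy_recording():
    """10-min 16-channel recording, 200 planted 2-mV DSs, noise sd 0.1 mV."""
    p1 = ds.TemplateParams(**{**ds.DS1_DEFAULTS.__dict__, "peak_amplitude_mv": 2.0})
    p2 = ds.TemplateParams(**{**ds.DS2_DEFAULTS.__dict__, "peak_amplitude_mv": 2.0})
    cfg = ds.SynthConfig(duration_s=600, n_ds1=100, n_ds2=100,
                         ds1_params=p1, ds2_params=p2,
                         noise_sd_mv=0.1, seed=1)
    return ds.synthesize_recording(cfg)


@pytest.fixture()
def small_events():
    return ds.make_event_table([1000, 1200, 1500], channel=12,
                               peak_amplitudes=[2.0, 1.8, 2.2],
                               offsets_ms=[0.0, -1.0, 1.0])


def gaussian_waveform(sigma_ms, window=(-200, 200), fs=1000.0, amp=1.0):
    t = np.arange(window[0], window[1] + 1e-9, 1000.0 / fs)
    return amp * np.exp(-0.5 * (t / sigma_ms) ** 2)
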