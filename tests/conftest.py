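import numpy as np
import pytest

import beatvar as bv


@pytest.fixture(scope="session")
def default_run():
    """A 300-beat synthetic recording at default (realistic) conditions."""
    cfg = bv.SimConfig(n_beats=300, seed=3)
    gt = bv.gen_beat_train(cfg)
    trace, _ = bv.gen_gray_trace(gt)
    beats = bv.detect_beats(trace)
    return cfg, gt, trace, beats


@pytest.fixture(scope="session")
def snr10_run():
    """The same recording rendered at SNR 10 (noise = amplitude / 10)."""
    cfg = bv.SimConfig(n_beats=300, noise_sd=2.1, seed=3)
    gt = bv.gen_beat_train(cfg)
    trace, _ = bv.gen_gray_trace(gt)
    beats = bv.detect_beats(trace)
    return cfg, gt, trace, beats


@pytest.fixture(scope="session")
def small_study():
    """A compact paired study for pipeline-level tests."""
    from beatvar.synthetic_data import default_ach_config, default_con_config

    con = default_con_config(n_beats=150)
    ach = default_ach_config(n_beats=130)
    return bv.gen_study(con, ach, n_animals=9, master_seed=21)
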