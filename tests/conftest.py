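import numpy as np
import pandas as pd
import pytest

from rtp import PlayerModel, SessionLog, TrialConfig, simulate_ct, simulate_msg


@pytest.fixture
def ct_config():
    return TrialConfig(
        module_kind="CT", duration_s=30, target_frequency_hz=0.25, target_amplitude=0.3
    )


@pytest.fixture
def msg_config():
    return TrialConfig(module_kind="MSG", duration_s=60, event_duration_s=2, rng_seed=11)


@pytest.fixture
def perfect_ct_log(ct_config):
    return simulate_ct(ct_config, PlayerModel(seed=0))


@pytest.fixture
def perfect_msg_log(msg_config):
    return simulate_msg(msg_config, PlayerModel(seed=0, reaction_time_mean_ms=300))


def make_ct_log(config: TrialConfig, paddle: np.ndarray) -> SessionLog:
    """Hand-built CT log with an arbitrary paddle trace."""
    t = np.arange(config.n_samples, dtype=np.int64) * config.dt_ms
    from rtp import CTWaveform

    wf = CTWaveform.from_config(config)
    target = wf.position(t)
    tx = target if config.axis == "horizontal" else np.full_like(target, 0.5)
    ty = np.full_like(target, 0.5) if config.axis == "horizontal" else target
    samples = pd.DataFrame(
        {
            "t_ms": t,
            "paddle_pos": np.asarray(paddle, dtype=float),
            "target_x": tx,
            "target_y": ty,
            "event_id": pd.array([pd.NA] * len(t), dtype="Int64"),
        }
    )
    return SessionLog(config=config, samples=samples, events=[], participant_id="hand")
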