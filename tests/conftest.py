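import numpy as np
import pytest
from hypothesis import settings

import patrolfret as pf

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def kin():
    return pf.KineticParams()


@pytest.fixture
def noise():
    """Default Gaussian detection noise (SNR 5, 30-ms frames)."""
    return pf.NoiseModel()


@pytest.fixture
def no_noise():
    return pf.NoiseModel(noise_kind="none")


@pytest.fixture
def sawtooth_construct():
    """End-labeled 40-nt patrol track with full-amplitude sawtooth."""
    return pf.ConstructSpec(track_length_nt=40, fret_anchor_low=0.30, fret_anchor_high=0.80)


@pytest.fixture
def g4_construct():
    """Patrol track plus an intramolecular G4 flanked by the dye pair."""
    return pf.ConstructSpec(
        track_length_nt=40, payload="G4_TP", fret_anchor_low=0.30, fret_anchor_high=0.75
    )


def ideal_sawtooth_trace(period_s=2.0, n_cycles=10, frame_interval=0.030,
                         lo=0.30, hi=0.80, molecule_id="ideal"):
    """Deterministic rising-sawtooth FRET trace with exact period."""
    n_frames = int(round(period_s * n_cycles / frame_interval))
    t = np.arange(n_frames) * frame_interval
    phase = (t % period_s) / period_s
    E = lo + (hi - lo) * phase
    return pf.FretTrace(
        molecule_id=molecule_id, time_s=t, E=E,
        valid=np.ones(n_frames, dtype=bool), frame_interval=frame_interval,
    )
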