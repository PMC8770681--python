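import numpy as np
import pandas as pd
import pytest

from cdsvoice.audio_io import Waveform


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_sine(freq: float, duration: float = 1.0, rate: int = 44100, amp: float = 0.5) -> Waveform:
    t = np.arange(int(round(duration * rate))) / rate
    return Waveform(amp * np.sin(2 * np.pi * freq * t), rate)


def make_long_table(n_mothers: int, seed: int, slope: float = -2.0, noise_sd: float = 10.0,
                    within_sd: float = 0.0) -> pd.DataFrame:
    """Long per-utterance table with a linear pitch-age law and optional
    within-mother scatter; identical utterances when within_sd=0."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(7.72, 16.47, n_mothers)
    mother_age = age + 25.0 + rng.normal(0, 5.0, n_mothers)
    pitch = 188.11 + slope * (age - age.mean()) + rng.normal(0, noise_sd, n_mothers)
    words = ["teebudishawlt", "keebudishawlt", "peebudishawlt"]
    rows = []
    for i in range(n_mothers):
        for w in words:
            for take in (1, 2, 3):
                rows.append(
                    {
                        "mother_id": f"m{i:03d}",
                        "word": w,
                        "take": take,
                        "mother_age": mother_age[i],
                        "child_age": age[i],
                        "child_sex": "girl" if i % 3 == 0 else "boy",
                        "language": "English",
                        "pitch_height": pitch[i] + rng.normal(0, within_sd),
                        "pitch_range": 25 + rng.normal(0, 3),
                        "duration": 0.9 + rng.normal(0, 0.05),
                        "amplitude": 0.1 + rng.normal(0, 0.01),
                        "brightness": 3 * pitch[i] + rng.normal(0, 40),
                        "pitch_p90": pitch[i] + 10,
                        "pitch_first500": pitch[i] + 3,
                    }
                )
    return pd.DataFrame(rows)
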