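"""Reading and writing the audio and tabular formats the pipeline touches.

Audio is RIFF WAV: 16-bit integer and IEEE-float PCM are accepted on read
(via :mod:`scipy.io.wavfile`); 16-bit mono is written.  Decoded samples are
full-scale floats in [-1, 1] (signed 16-bit divided by 32768).  Cohort
metadata is a CSV with one row per utterance and fixed column names.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

ALLOWED_WORDS = ("teebudishawlt", "keebudishawlt", "peebudishawlt")
ALLOWED_SEXES = ("girl", "boy")
ALLOWED_LANGUAGES = ("English", "Spanish")

#: required columns of a cohort metadata table, in canonical order
COHORT_COLUMNS = (
    "mother_id",
    "wav_path",
    "word",
    "take",
    "mother_age",
    "child_age",
    "child_sex",
    "language",
)

_INT16_FULL_SCALE = 32768.0


class AudioFormatError(ValueError):
    """The file is not a WAV payload this pipeline can decode."""


class CohortTableError(ValueError):
    """The cohort metadata table violates the recording contract."""


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal: full-scale float samples plus a sampling rate.

    ``samples`` are dimensionless amplitudes in [-1, 1]; ``rate`` is in Hz.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 1:
            raise ValueError(f"Waveform samples must be 1-D, got shape {self.samples.shape}")
        if int(self.rate) <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "rate", int(self.rate))

    @property
    def duration(self) -> float:
        """Signal duration in seconds (sample count / rate)."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class UtteranceMeta:
    """Identity and cohort covariates for one recorded utterance."""

    mother_id: str
    word: str
    take_index: int
    mother_age: float
    child_age: float
    child_sex: str
    language: str

    def __post_init__(self) -> None:
        if self.word not in ALLOWED_WORDS:
            raise ValueError(
                f"unknown word label {self.word!r}; allowed: {', '.join(ALLOWED_WORDS)}"
            )
        if not 1 <= int(self.take_index) <= 3:
            raise ValueError(f"take_index must be 1-3, got {self.take_index}")
        if self.child_sex not in ALLOWED_SEXES:
            raise ValueError(f"child_sex must be one of {ALLOWED_SEXES}, got {self.child_sex!r}")
        if self.language not in ALLOWED_LANGUAGES:
            raise ValueError(f"language must be one of {ALLOWED_LANGUAGES}, got {self.language!r}")
        if not self.mother_age > self.child_age:
            raise ValueError(
                f"mother_age ({self.mother_age}) must exceed child_age ({self.child_age})"
            )


def read_wav(path: str | os.PathLike, *, channel: int | None = None) -> Waveform:
    """Read a WAV file as a mono full-scale :class:`Waveform`.

    Stereo files are averaged across channels unless ``channel`` selects one
    (0-based).  Integer PCM is rescaled by the format's full-scale value;
    float PCM is taken as-is.

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    AudioFormatError
        for non-WAV payloads or zero-length audio.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # chunk-padding warnings from odd encoders
            rate, data = wavfile.read(path)
    except ValueError as exc:
        raise AudioFormatError(f"{path} is not a readable WAV file: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"{path} contains zero-length audio")

    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:  # signed PCM: symmetric full scale
            scale = float(-info.min)
            samples = data.astype(np.float64) / scale
        else:  # unsigned 8-bit: offset binary
            samples = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        samples = data.astype(np.float64)

    if samples.ndim == 2:
        if channel is not None:
            if not 0 <= channel < samples.shape[1]:
                raise ValueError(f"channel {channel} out of range for {samples.shape[1]} channels")
            samples = samples[:, channel]
        else:
            samples = samples.mean(axis=1)
    return Waveform(samples=samples, rate=int(rate))


def write_wav(path: str | os.PathLike, w: Waveform) -> None:
    """Write ``w`` as a 16-bit PCM mono WAV at ``w.rate``.

    Samples with magnitude above 1 are a contract violation and raise
    instead of being clamped.
    """
    peak = float(np.max(np.abs(w.samples))) if len(w) else 0.0
    if peak > 1.0:
        raise ValueError(f"cannot write clipping audio: max |sample| = {peak:.4f} > 1")
    # symmetric full scale 32768; +1.0 clips by one LSB to stay in int16
    pcm = np.clip(np.round(w.samples * _INT16_FULL_SCALE), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), w.rate, pcm)


def _check_cohort_frame(df: pd.DataFrame, strict: bool) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortTableError(f"cohort table missing required column(s): {', '.join(missing)}")

    bad_words = sorted(set(df["word"]) - set(ALLOWED_WORDS))
    if bad_words:
        raise CohortTableError(
            f"unknown word label(s) {bad_words}; allowed labels: {list(ALLOWED_WORDS)}"
        )

    dup = df.duplicated(subset=["mother_id", "word", "take"], keep=False)
    if dup.any():
        key = df.loc[dup, ["mother_id", "word", "take"]].iloc[0]
        raise CohortTableError(
            "duplicate utterance key (mother_id={}, word={}, take={})".format(
                key["mother_id"], key["word"], key["take"]
            )
        )

    counts = df.groupby("mother_id").size()
    off = counts[counts != 9]
    if len(off):
        msg = "mothers with != 9 utterances: " + ", ".join(
            f"{m} ({n})" for m, n in off.items()
        )
        if strict:
            raise CohortTableError(msg)
        warnings.warn(msg, stacklevel=3)


def read_cohort_table(path: str | os.PathLike, *, strict: bool = False) -> pd.DataFrame:
    """Read and validate a cohort metadata CSV.

    One row per utterance with columns ``mother_id, wav_path, word, take,
    mother_age, child_age, child_sex, language``.  Duplicate
    (mother_id, word, take) keys and unknown word labels always raise; a
    mother with a number of utterances other than nine raises under
    ``strict=True`` and warns otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cohort table: {path}")
    df = pd.read_csv(path, dtype={"mother_id": str})
    _check_cohort_frame(df, strict=strict)
    df = df.copy()
    df["take"] = df["take"].astype(int)
    # resolve audio paths relative to the table's own directory
    df["wav_path"] = [str((path.parent / p)) for p in df["wav_path"]]
    return df


def meta_from_row(row: pd.Series) -> UtteranceMeta:
    """Build a validated :class:`UtteranceMeta` from a cohort-table row."""
    return UtteranceMeta(
        mother_id=str(row["mother_id"]),
        word=str(row["word"]),
        take_index=int(row["take"]),
        mother_age=float(row["mother_age"]),
        child_age=float(row["child_age"]),
        child_sex=str(row["child_sex"]),
        language=str(row["language"]),
    )
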