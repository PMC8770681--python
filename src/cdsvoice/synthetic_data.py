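"""Synthetic voice cohorts with known ground truth.

The generator emulates a cohort of mothers each recorded producing nine
child-directed utterances (three nonsense words x three takes).  Cohort
structure is sampled first — child age, mother age, a per-mother true pitch
height whose population correlation with child age equals the configured
target, and a brightness latent coupled to pitch — then each utterance is
rendered as an additive-harmonic waveform: a time-varying F0 contour (flat,
then a linear declination over the final 30%, emulating the end-of-utterance
pitch drop-off of natural speech), harmonics attenuated by a spectral tilt
in dB/octave, per-frame F0 jitter, and 10-ms cosine fades.

The additive-harmonic voice model is not naturalistic speech — no formants,
no consonant bursts — but its ground-truth F0 and tilt are exact, which is
what validating a pitch tracker and an inference pipeline requires.

Calibration is closed-form: with child age ``a`` and a target correlation
``r`` for a Gaussian-noise affine response ``y = m + b*(a - E[a]) + e``,
choosing ``b = r * sd_y / sd_a`` and ``sd_e = sd_y * sqrt(1 - r^2)`` makes
the population correlation exactly ``r`` and the marginal moments exactly
``(m, sd_y)``, for any age distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from cdsvoice.acoustic_features import extract_sample_features
from cdsvoice.audio_io import ALLOWED_WORDS, COHORT_COLUMNS, Waveform, meta_from_row, write_wav

_TRUTH_COLUMNS = [
    "mother_id",
    "child_age",
    "mother_age",
    "child_sex",
    "language",
    "pitch_truth",
    "tilt_truth",
    "declination_truth",
    "duration_truth",
    "rms_truth",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic mother-voice cohort.

    Defaults reproduce the cohort regime the pipeline targets: 50 mothers,
    child ages uniform on [7.72, 16.47] years, mother age correlated 0.38
    with child age, per-mother mean F0 with marginal 188.11 +/- 18.20 Hz and
    a -0.38 population correlation with child age, and a brightness latent
    correlated 0.34 with pitch height.  Pitch range, duration and amplitude
    are null features: their truths are drawn independently of child age.
    """

    n_mothers: int = 50
    child_age_range: tuple[float, float] = (7.72, 16.47)
    mother_age_mean: float = 46.46
    mother_age_sd: float = 7.35
    mother_child_age_corr: float = 0.38
    pitch_mean: float = 188.11
    pitch_sd: float = 18.20
    pitch_age_corr: float = -0.38
    brightness_pitch_corr: float = 0.34
    #: take-to-take SD of an individual utterance's F0 around the mother's
    #: true pitch; a free parameter of the generator (no published estimate)
    within_mother_f0_sd: float = 8.0
    girl_fraction: float = 0.36
    spanish_fraction: float = 0.04
    declination_mean: float = 25.0
    declination_sd: float = 5.0
    duration_mean: float = 0.9
    duration_sd: float = 0.08
    rms_mean: float = 0.10
    rms_sd: float = 0.02
    tilt_mean: float = 9.0
    tilt_sd_per_latent: float = 2.0
    n_words: int = 3
    takes_per_word: int = 3
    rate: int = 44100

    def validate(self) -> None:
        for name in ("mother_child_age_corr", "pitch_age_corr", "brightness_pitch_corr"):
            r = getattr(self, name)
            if not -1 < r < 1:
                raise ValueError(f"{name} must lie in (-1, 1), got {r}")
        if self.child_age_range[0] >= self.child_age_range[1]:
            raise ValueError("child_age_range must be ordered (low, high)")
        for name in ("pitch_sd", "mother_age_sd", "within_mother_f0_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_mothers < 2:
            raise ValueError("need at least 2 mothers")


@dataclass(frozen=True)
class SynthesisSpec:
    """Parameters of one additive-harmonic synthetic utterance."""

    base_f0: float
    declination: float = 25.0  # Hz dropped linearly over the final 30%
    jitter_sd: float = 2.0  # Hz, frame-to-frame (10 ms frames)
    spectral_tilt: float = 9.0  # dB per octave harmonic attenuation
    n_harmonics: int = 10
    duration: float = 0.9
    rms_target: float = 0.1
    word: str = "keebudishawlt"
    rate: int = 44100

    def validate(self) -> None:
        if self.base_f0 - self.declination <= 0:
            raise ValueError("declination would drive F0 to or below zero")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.rms_target < 1 / np.sqrt(2):
            raise ValueError("rms_target must lie in (0, 1/sqrt(2))")
        if self.n_harmonics * self.base_f0 >= self.rate / 2:
            raise ValueError(
                f"harmonic {self.n_harmonics} of {self.base_f0} Hz is at or above "
                f"Nyquist ({self.rate / 2} Hz)"
            )


def _affine_response(
    x: np.ndarray, target_corr: float, out_mean: float, out_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-noise affine response with exact population moments/correlation."""
    x_sd = np.std(x)
    if x_sd == 0:
        raise ValueError("predictor has zero variance; correlation target infeasible")
    slope = target_corr * out_sd / x_sd
    noise_sd = out_sd * np.sqrt(1.0 - target_corr**2)
    return out_mean + slope * (x - np.mean(x)) + rng.normal(0.0, noise_sd, size=x.shape)


def sample_cohort_parameters(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-mother truth table for a cohort.

    Child ages are uniform on the configured range; mother age and true
    pitch height are affine-plus-Gaussian responses calibrated in closed
    form to the target correlations; the brightness latent is coupled to
    pitch height and mapped to a spectral tilt (higher latent -> shallower
    tilt -> brighter timbre).  Declination, duration and RMS truths are
    independent of age (null features).
    """
    spec.validate()
    n = spec.n_mothers
    lo, hi = spec.child_age_range
    child_age = rng.uniform(lo, hi, size=n)
    # center the affine responses on the *population* age mean so marginal
    # means hit their targets irrespective of the sampled ages
    age_centered = child_age - (lo + hi) / 2
    age_sd_pop = (hi - lo) / np.sqrt(12.0)

    def response(target_corr: float, out_mean: float, out_sd: float) -> np.ndarray:
        slope = target_corr * out_sd / age_sd_pop
        noise_sd = out_sd * np.sqrt(1.0 - target_corr**2)
        return out_mean + slope * age_centered + rng.normal(0.0, noise_sd, size=n)

    mother_age = response(spec.mother_child_age_corr, spec.mother_age_mean, spec.mother_age_sd)
    mother_age = np.maximum(mother_age, child_age + 14.0)  # biological floor
    pitch = response(spec.pitch_age_corr, spec.pitch_mean, spec.pitch_sd)

    pitch_z = (pitch - spec.pitch_mean) / spec.pitch_sd
    r_bp = spec.brightness_pitch_corr
    bright_latent = r_bp * pitch_z + np.sqrt(1 - r_bp**2) * rng.standard_normal(n)
    tilt = np.clip(spec.tilt_mean - spec.tilt_sd_per_latent * bright_latent, 2.0, 16.0)

    declination = np.clip(
        rng.normal(spec.declination_mean, spec.declination_sd, size=n), 5.0, None
    )
    dur = np.clip(rng.normal(spec.duration_mean, spec.duration_sd, size=n), 0.4, None)
    rms = np.clip(rng.normal(spec.rms_mean, spec.rms_sd, size=n), 0.02, 0.5)

    n_girls = int(round(spec.girl_fraction * n))
    sex = np.array(["girl"] * n_girls + ["boy"] * (n - n_girls))
    rng.shuffle(sex)
    n_spanish = int(round(spec.spanish_fraction * n))
    lang = np.array(["Spanish"] * n_spanish + ["English"] * (n - n_spanish))
    rng.shuffle(lang)

    return pd.DataFrame(
        {
            "mother_id": [f"m{i:03d}" for i in range(n)],
            "child_age": child_age,
            "mother_age": mother_age,
            "child_sex": sex,
            "language": lang,
            "pitch_truth": pitch,
            "tilt_truth": tilt,
            "declination_truth": declination,
            "duration_truth": dur,
            "rms_truth": rms,
        },
        columns=_TRUTH_COLUMNS,
    )


def synthesize_utterance(spec: SynthesisSpec, rng: np.random.Generator) -> Waveform:
    """Render one utterance as a sum of tilted harmonics of a moving F0.

    The F0 contour is flat at ``base_f0`` for the first 70% of the
    utterance, then declines linearly by ``declination`` Hz; Gaussian
    jitter is drawn per 10-ms frame and linearly interpolated to sample
    rate.  Harmonic ``k`` is attenuated by ``spectral_tilt`` dB per octave
    (amplitude ``10^(-tilt*log2(k)/20)``).  The signal gets 10-ms raised-
    cosine fades and is scaled to ``rms_target`` exactly.
    """
    spec.validate()
    rate = spec.rate
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate

    knee = 0.7 * spec.duration
    contour = np.where(
        t < knee,
        spec.base_f0,
        spec.base_f0 - spec.declination * (t - knee) / (0.3 * spec.duration),
    )
    if spec.jitter_sd > 0:
        n_frames = int(np.ceil(spec.duration / 0.01)) + 1
        jit = rng.normal(0.0, spec.jitter_sd, size=n_frames)
        contour = contour + np.interp(t, np.arange(n_frames) * 0.01, jit)

    phase = 2 * np.pi * np.cumsum(contour) / rate
    x = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        amp = 10.0 ** (-spec.spectral_tilt * np.log2(k) / 20.0)
        x += amp * np.sin(k * phase)

    fade = int(round(0.01 * rate))
    if fade and n >= 2 * fade:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(fade) / fade))
        x[:fade] *= ramp
        x[-fade:] *= ramp[::-1]

    rms = np.sqrt(np.mean(x**2))
    x *= spec.rms_target / rms
    peak = np.max(np.abs(x))
    if peak > 1.0:  # keep within full scale; renormalize and warn via exactness loss
        x /= peak
    return Waveform(samples=x, rate=rate)


def _utterance_spec_for_take(
    spec: CohortSpec, row: pd.Series, word: str, rng: np.random.Generator
) -> SynthesisSpec:
    # base_f0 is offset so the contour's time-average equals the mother's
    # true pitch: a linear drop of d Hz over the final 30% lowers the mean
    # by 0.15*d
    base = (
        row["pitch_truth"]
        + 0.15 * row["declination_truth"]
        + rng.normal(0.0, spec.within_mother_f0_sd)
    )
    return SynthesisSpec(
        base_f0=float(base),
        declination=float(row["declination_truth"]),
        spectral_tilt=float(row["tilt_truth"]),
        duration=float(np.clip(row["duration_truth"] + rng.normal(0.0, 0.04), 0.35, None)),
        rms_target=float(np.clip(row["rms_truth"] + rng.normal(0.0, 0.01), 0.02, 0.5)),
        word=word,
        rate=spec.rate,
    )


def iter_cohort_utterances(spec: CohortSpec, truth: pd.DataFrame, rng: np.random.Generator):
    """Yield ``(row_dict, waveform)`` for every utterance of the cohort.

    ``row_dict`` carries the metadata-table fields (without ``wav_path``).
    Deterministic given the generator state.
    """
    words = ALLOWED_WORDS[: spec.n_words]
    for _, row in truth.iterrows():
        for word in words:
            for take in range(1, spec.takes_per_word + 1):
                uspec = _utterance_spec_for_take(spec, row, word, rng)
                w = synthesize_utterance(uspec, rng)
                yield (
                    {
                        "mother_id": row["mother_id"],
                        "word": word,
                        "take": take,
                        "mother_age": row["mother_age"],
                        "child_age": row["child_age"],
                        "child_sex": row["child_sex"],
                        "language": row["language"],
                    },
                    w,
                )


def build_synthetic_corpus(
    spec: CohortSpec, out: str | Path, rng: np.random.Generator
) -> pd.DataFrame:
    """Write a full synthetic corpus: WAV files, metadata CSV, truth CSV.

    Returns the metadata table (also written to ``<out>/metadata.csv``).
    Audio lands in ``<out>/audio/<mother>_<word>_t<take>.wav``; the truth
    table in ``<out>/truth.csv`` for oracle tests.
    """
    out = Path(out)
    (out / "audio").mkdir(parents=True, exist_ok=True)
    truth = sample_cohort_parameters(spec, rng)
    rows = []
    for meta, w in iter_cohort_utterances(spec, truth, rng):
        rel = Path("audio") / f"{meta['mother_id']}_{meta['word']}_t{meta['take']}.wav"
        write_wav(out / rel, w)
        rows.append({**meta, "wav_path": str(rel)})
    table = pd.DataFrame(rows)[list(COHORT_COLUMNS)]
    table.to_csv(out / "metadata.csv", index=False, float_format="%.6f")
    truth.to_csv(out / "truth.csv", index=False, float_format="%.6f")
    return table


def simulate_extracted_cohort(
    spec: CohortSpec,
    rng: np.random.Generator,
    floor: float = 75.0,
    ceiling: float = 300.0,
) -> pd.DataFrame:
    """Synthesize a cohort in memory and run feature extraction on it.

    Returns the long per-utterance feature table (one row per utterance)
    without touching the filesystem — the workhorse for end-to-end
    simulation studies where writing hundreds of WAV files per replicate
    would be pure overhead.
    """
    truth = sample_cohort_parameters(spec, rng)
    rows = []
    for meta, w in iter_cohort_utterances(spec, truth, rng):
        feats = extract_sample_features(
            w, meta_from_row(pd.Series(meta)), floor=floor, ceiling=ceiling
        )
        rows.append(
            {
                **meta,
                "pitch_height": feats.pitch_height,
                "pitch_range": feats.pitch_range,
                "pitch_p90": feats.pitch_p90,
                "pitch_first500": feats.pitch_first500,
                "duration": feats.duration,
                "amplitude": feats.amplitude,
                "brightness": feats.brightness,
            }
        )
    return pd.DataFrame(rows)
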