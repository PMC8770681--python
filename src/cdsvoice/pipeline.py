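"""Corpus -> features -> statistics orchestration with a JSON report.

The pipeline reads a corpus (metadata CSV plus WAV files), extracts the
per-utterance features, aggregates per mother, and runs the complete
inferential battery.  All randomness flows from a single master seed that
is expanded into named substreams (one per stochastic stage), so any stage
can be replayed independently and a rerun with the same seed yields an
identical report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cdsvoice import cohort_stats as cs
from cdsvoice.acoustic_features import FeatureExtractionError, extract_pitch_track, extract_sample_features, summarize_pitch
from cdsvoice.audio_io import meta_from_row, read_cohort_table, read_wav

logger = logging.getLogger("cdsvoice.pipeline")

_SUBSTREAMS = ("folds", "permutations", "synthesis")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters; defaults are the standard settings of the
    child-directed-speech analysis (75/300 Hz pitch band, 10 ms frames,
    alpha = 0.05, 4 folds x 100 repetitions, 1000 surrogates, five-feature
    family with Bonferroni correction, 550 Hz control ceiling)."""

    corpus: str = ""
    pitch_floor: float = 75.0
    pitch_ceiling: float = 300.0
    pitch_step: float = 0.01
    ceiling_control: float = 550.0
    centroid_power: float = 2.0
    alpha: float = 0.05
    cv_folds: int = 4
    cv_repetitions: int = 100
    n_surrogates: int = 1000
    fwe_family: tuple = cs.FEATURES
    reference_adult_pitch: float = 175.0
    seed: int = 0
    output_dir: str = "cdsvoice_out"

    def substream(self, name: str) -> np.random.Generator:
        """Named, independent random stream derived from the master seed."""
        return np.random.default_rng([self.seed, _SUBSTREAMS.index(name)])


def extract_corpus_features(config: PipelineConfig) -> pd.DataFrame:
    """Run feature extraction over every utterance of the corpus.

    Returns the long table (one row per utterance) including the control
    pitch summaries and a pitch height re-extracted at the control
    ceiling.  Any per-utterance failure aborts with the utterance named.
    """
    table = read_cohort_table(Path(config.corpus) / "metadata.csv")
    rows = []
    t0 = time.perf_counter()
    for _, row in table.iterrows():
        meta = meta_from_row(row)
        w = read_wav(row["wav_path"])
        feats = extract_sample_features(
            w,
            meta,
            floor=config.pitch_floor,
            ceiling=config.pitch_ceiling,
            step=config.pitch_step,
            power_exponent=config.centroid_power,
        )
        control_track = extract_pitch_track(
            w, floor=config.pitch_floor, ceiling=config.ceiling_control, step=config.pitch_step
        )
        rows.append(
            {
                "mother_id": meta.mother_id,
                "word": meta.word,
                "take": meta.take_index,
                "mother_age": meta.mother_age,
                "child_age": meta.child_age,
                "child_sex": meta.child_sex,
                "language": meta.language,
                "pitch_height": feats.pitch_height,
                "pitch_range": feats.pitch_range,
                "pitch_p90": feats.pitch_p90,
                "pitch_first500": feats.pitch_first500,
                "duration": feats.duration,
                "amplitude": feats.amplitude,
                "brightness": feats.brightness,
                "pitch_height_ceiling_control": summarize_pitch(control_track, "mean"),
            }
        )
    logger.info(
        "extracted features for %d utterances in %.1f s", len(rows), time.perf_counter() - t0
    )
    return pd.DataFrame(rows)


def analyze_cohort(long_table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Run the full inferential battery on an extracted long table."""
    records = cs.aggregate_mother_features(long_table)
    age = records["child_age"].to_numpy()
    report: dict = {
        "params": {k: v for k, v in asdict(config).items() if k != "fwe_family"},
        "n_mothers": int(len(records)),
        "features": {},
    }

    pearson = {f: cs.pearson_inference(records[f], age) for f in config.fwe_family}
    p_fwe = cs.fwe_adjust([pearson[f].p for f in config.fwe_family])
    for f, adj in zip(config.fwe_family, p_fwe):
        mixed = cs.fit_random_intercept_model(long_table, f)
        report["features"][f] = {
            "pearson": pearson[f].to_dict(),
            "p_fwe": float(adj),
            "mixed_model": mixed.to_dict(),
        }

    pitch = records["pitch_height"].to_numpy()
    fold_rng = config.substream("folds")
    perm_rng = config.substream("permutations")
    cv = cs.cv_prediction_r(
        pitch, age, k=config.cv_folds, reps=config.cv_repetitions, rng=fold_rng
    )
    cv_perm = cs.permutation_test_cv(
        pitch,
        age,
        k=config.cv_folds,
        reps=config.cv_repetitions,
        n_surrogates=config.n_surrogates,
        rng=perm_rng,
    )
    controls = {
        "p90": cs.pearson_inference(records["pitch_p90"], age).to_dict(),
        "first500": cs.pearson_inference(records["pitch_first500"], age).to_dict(),
    }
    if "pitch_height_ceiling_control" in records.columns:
        controls["ceiling_control"] = cs.pearson_inference(
            records["pitch_height_ceiling_control"], age
        ).to_dict()
    report["pitch_extras"] = {
        "partial_vs_mother_age": cs.partial_correlation(
            pitch, age, records["mother_age"].to_numpy()
        ).to_dict(),
        "mother_age_child_age": cs.pearson_inference(records["mother_age"], age).to_dict(),
        "cv": {**cv.to_dict(), "p_perm": cv_perm.p_perm, "n_surrogates": cv_perm.n_surrogates},
        "controls": controls,
    }

    report["brightness_word_model"] = cs.fit_brightness_word_model(long_table).to_dict()
    report["simultaneous_regression"] = cs.simultaneous_regression(records).to_dict()
    report["stepwise_comparison"] = cs.stepwise_model_comparison(records).to_dict()
    report["subgroups"] = {
        "child_sex": {
            str(k): (v.to_dict() if isinstance(v, cs.CorrelationResult) else v)
            for k, v in cs.subgroup_correlations(records, "pitch_height", "child_age").items()
        },
        "primary_english_only": _language_exclusion(records),
    }
    try:
        report["extrapolation_years"] = cs.extrapolate_adult_pitch_age(
            records, reference_pitch=config.reference_adult_pitch
        )
    except ValueError as exc:
        report["extrapolation_years"] = None
        report["extrapolation_error"] = str(exc)
    return report


def _language_exclusion(records: pd.DataFrame) -> dict:
    sub = records[records["language"] == "English"]
    if len(sub) < 4:
        return {"status": f"skipped (n={len(sub)} < 4)"}
    res = cs.pearson_inference(sub["pitch_height"], sub["child_age"])
    return {"n_excluded": int(len(records) - len(sub)), **res.to_dict()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Extract features from the configured corpus and analyze the cohort."""
    long_table = extract_corpus_features(config)
    report = analyze_cohort(long_table, config)
    report["n_utterances"] = int(len(long_table))
    return report


def _table1_frame(report: dict) -> pd.DataFrame:
    rows = []
    for name, entry in report["simultaneous_regression"]["predictors"].items():
        rows.append(
            {
                "predictor": name,
                "beta_std": entry["beta_std"],
                "ci_lower": entry["ci_low"],
                "ci_upper": entry["ci_high"],
                "t": entry["t"],
                "p": entry["p"],
            }
        )
    return pd.DataFrame(rows)


def _table2_frame(report: dict) -> pd.DataFrame:
    step = report["stepwise_comparison"]
    rows = [
        {
            "model": "pitch_height",
            "adj_r2": step["adj_r2"],
            "delta_adj_r2": np.nan,
            "F": step["f_stat"],
            "p": step["f_p"],
        }
    ]
    for row in step["comparisons"]:
        rows.append(
            {
                "model": f"pitch_height + {row['added_predictor']}",
                "adj_r2": row["adj_r2"],
                "delta_adj_r2": row["delta_adj_r2"],
                "F": row["F"],
                "p": row["p"],
            }
        )
    return pd.DataFrame(rows)


REQUIRED_REPORT_KEYS = (
    "params",
    "features",
    "pitch_extras",
    "simultaneous_regression",
    "stepwise_comparison",
    "subgroups",
)


def write_report(report: dict, out: str | Path) -> dict[str, Path]:
    """Write the JSON report plus CSV tables mirroring the two regression
    tables.  Returns the paths written.  Raises if the report is missing a
    required section (e.g. a pipeline stage was skipped)."""
    missing = [k for k in REQUIRED_REPORT_KEYS if k not in report]
    if missing:
        raise ValueError(f"report is missing required section(s): {', '.join(missing)}")
    if "cv" not in report.get("pitch_extras", {}):
        raise ValueError("report is missing the cross-validation result")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out / "report.json",
        "table1": out / "table1_simultaneous_regression.csv",
        "table2": out / "table2_model_comparisons.csv",
    }
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
    _table1_frame(report).to_csv(paths["table1"], index=False, float_format="%.4f")
    _table2_frame(report).to_csv(paths["table2"], index=False, float_format="%.4f")
    return paths


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
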