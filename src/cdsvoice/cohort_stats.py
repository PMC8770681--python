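"""Cohort-level inference on per-mother acoustic features.

Implements the full battery used to relate a mother's voice acoustics to
her child's age:

* Pearson correlation with Fisher-z 95% interval and t test;
* partial correlation by residualization (removing mother's age);
* Bonferroni family-wise error correction across the feature family;
* repeated balanced k-fold cross-validated prediction, summarized as the
  correlation between observed outcomes and pooled out-of-fold
  predictions, with a permutation (surrogate) null for significance;
* random-intercept linear mixed models on the long (per-utterance) table,
  reported as standardized betas;
* simultaneous and stepwise multiple regression across all five features.

Fold assignment follows the balance constraint that a one-way ANOVA of
both the predictor and the outcome across folds shows no evidence of mean
differences (p > 0.50), re-randomizing until satisfied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

FEATURES = ("pitch_height", "pitch_range", "duration", "amplitude", "brightness")


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson (or partial) correlation with its full inference."""

    r: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CVResult:
    """Repeated cross-validated prediction accuracy, optionally with a
    permutation p-value."""

    r_obs_pred: float
    per_repetition: tuple
    p_perm: float | None
    n_folds: int
    n_repetitions: int
    n_surrogates: int
    seed: int | None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_repetition"] = list(self.per_repetition)
        return d


@dataclass(frozen=True)
class MixedModelResult:
    """Standardized slope of a random-intercept model, plus variance
    components.  ``df_method`` records how the p-value was obtained."""

    beta_std: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    var_mother: float
    var_resid: float
    df_method: str
    converged: bool
    word_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RegressionTable:
    """Per-predictor inference of a multiple regression, with optional
    nested-model comparison rows."""

    predictors: dict  # name -> {beta_std, ci_low, ci_high, t, p}
    adj_r2: float
    f_stat: float | None
    f_p: float | None
    comparisons: tuple = ()  # rows: {added_predictor, adj_r2, delta_adj_r2, F, p}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["comparisons"] = list(self.comparisons)
        return d


# ---------------------------------------------------------------------------
# aggregation


def aggregate_mother_features(long_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the per-utterance table to one record per mother.

    Feature values are arithmetic means across that mother's utterances
    (nine in a complete corpus); covariates are carried through unchanged.
    """
    if len(long_table) == 0:
        raise ValueError("cannot aggregate an empty feature table")
    counts = long_table.groupby("mother_id").size()
    off = counts[counts != 9]
    if len(off):
        warnings.warn(
            f"{len(off)} mother(s) have != 9 utterances: "
            + ", ".join(f"{m} ({c})" for m, c in off.items()),
            stacklevel=2,
        )
    feature_cols = [
        c
        for c in (
            "pitch_height",
            "pitch_range",
            "duration",
            "amplitude",
            "brightness",
            "pitch_p90",
            "pitch_first500",
            "pitch_height_ceiling_control",
        )
        if c in long_table.columns
    ]
    meta_cols = [c for c in ("mother_age", "child_age", "child_sex", "language") if c in long_table.columns]
    agg = long_table.groupby("mother_id", sort=True).agg(
        {**{c: "mean" for c in feature_cols}, **{c: "first" for c in meta_cols}}
    )
    return agg.reset_index()


# ---------------------------------------------------------------------------
# correlation inference


def _fisher_ci(r: float, n_eff: int, conf: float) -> tuple[float, float]:
    """Fisher-z interval; ``n_eff`` is n minus the number of controlled
    covariates, so the z standard error is 1/sqrt(n_eff - 3)."""
    if n_eff - 3 <= 0:
        return (-1.0, 1.0)
    if abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    half = st.norm.ppf(0.5 + conf / 2) / np.sqrt(n_eff - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def pearson_inference(x, y, conf: float = 0.95) -> CorrelationResult:
    """Pearson r with t test (df = n-2) and Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError(f"need n >= 4 for correlation inference, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0 - 1e-15:  # numerically perfect correlation
        r = float(np.sign(r))
        t_stat, p = np.sign(r) * np.inf, 0.0
    else:
        t_stat = r * np.sqrt(df) / np.sqrt(1 - r**2)
        p = 2 * st.t.sf(abs(t_stat), df)
    ci_low, ci_high = _fisher_ci(r, n, conf)
    return CorrelationResult(r=r, ci_low=ci_low, ci_high=ci_high, t=float(t_stat), df=df, p=float(p), n=n)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation(x, y, z, conf: float = 0.95) -> CorrelationResult:
    """Correlation between x and y after regressing the covariate z out of
    both (ordinary least squares with intercept); t test on df = n - 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == len(z) == n):
        raise ValueError("x, y, z must have equal length")
    if n < 5:
        raise ValueError(f"need n >= 5 for partial correlation, got {n}")
    if np.std(z) == 0:
        raise ValueError("covariate z has zero variance")
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    if np.std(ry) < 1e-12 * max(1.0, np.std(y)) or np.std(rx) < 1e-12 * max(1.0, np.std(x)):
        raise ValueError("residual variance is zero: a variable is collinear with z")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t_stat = r * np.sqrt(df) / np.sqrt(1 - r**2)
    p = 2 * st.t.sf(abs(t_stat), df)
    # one controlled covariate -> z-scale SE uses n - 4
    ci_low, ci_high = _fisher_ci(r, n - 1, conf)
    return CorrelationResult(r=r, ci_low=ci_low, ci_high=ci_high, t=float(t_stat), df=df, p=float(p), n=n)


def fwe_adjust(p_values) -> np.ndarray:
    """Bonferroni family-wise error adjustment: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, p.size * p)


# ---------------------------------------------------------------------------
# balanced-fold cross-validation with permutation null


def _anova_f(values: np.ndarray, labels: np.ndarray, k: int) -> float:
    """One-way ANOVA F statistic of ``values`` across ``k`` groups."""
    n = values.size
    sums = np.bincount(labels, weights=values, minlength=k)
    counts = np.bincount(labels, minlength=k)
    means = sums / counts
    grand = values.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum(values**2) - np.sum(counts * means**2))
    if ssw <= 0:
        return np.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def assign_balanced_folds(
    x,
    y,
    k: int = 4,
    balance_p: float = 0.50,
    rng: np.random.Generator | None = None,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Randomly assign n points to k folds of near-equal size such that a
    one-way ANOVA of x across folds and of y across folds both give
    p > ``balance_p``; the randomization is repeated until the constraint
    holds.  Returns integer labels 1..k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2 * k:
        raise ValueError(f"need n >= 2k points for {k} folds, got n={n}")
    if rng is None:
        rng = np.random.default_rng()
    base = np.arange(n) % k  # sizes differ by at most one
    # p > balance_p  <=>  F below the (1 - balance_p) quantile of F(k-1, n-k)
    f_crit = st.f.isf(balance_p, k - 1, n - k)
    best_f = np.inf
    for _ in range(max_tries):
        labels = rng.permutation(base)
        fx = _anova_f(x, labels, k)
        if fx >= f_crit:
            best_f = min(best_f, fx)
            continue
        fy = _anova_f(y, labels, k)
        if fy < f_crit:
            return labels + 1
        best_f = min(best_f, fy)
    best_p = float(st.f.sf(best_f, k - 1, n - k)) if np.isfinite(best_f) else 0.0
    raise RuntimeError(
        f"could not balance folds in {max_tries} tries (best ANOVA p ~ {best_p:.3f}, "
        f"required > {balance_p})"
    )


def _one_cv_repetition(x: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator) -> float:
    labels = assign_balanced_folds(x, y, k=k, rng=rng)
    preds = np.empty_like(y)
    for fold in range(1, k + 1):
        test = labels == fold
        xt, yt = x[~test], y[~test]
        vx = xt - xt.mean()
        var = float(vx @ vx)
        if var == 0:
            raise ValueError("constant predictor within a training split")
        slope = float(vx @ (yt - yt.mean())) / var
        intercept = yt.mean() - slope * xt.mean()
        preds[test] = intercept + slope * x[test]
    vy = y - y.mean()
    vp = preds - preds.mean()
    denom = np.sqrt((vy @ vy) * (vp @ vp))
    if denom == 0:
        return 0.0
    return float(vy @ vp / denom)


def cv_prediction_r(
    x,
    y,
    k: int = 4,
    reps: int = 100,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CVResult:
    """Repeated balanced k-fold cross-validated prediction of y from x.

    Per repetition, a simple linear model is fit on k-1 folds and predicts
    the held-out fold; the n observed values are correlated with the n
    pooled out-of-fold predictions, giving one r per repetition.
    ``r_obs_pred`` is the mean over repetitions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    rs = [_one_cv_repetition(x, y, k, rng) for _ in range(reps)]
    return CVResult(
        r_obs_pred=float(np.mean(rs)),
        per_repetition=tuple(rs),
        p_perm=None,
        n_folds=k,
        n_repetitions=reps,
        n_surrogates=0,
        seed=seed,
    )


def permutation_test_cv(
    x,
    y,
    k: int = 4,
    reps: int = 100,
    n_surrogates: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CVResult:
    """Assess cv_prediction_r against a permutation null.

    Each surrogate permutes y, then reruns the complete repeated
    cross-validation (fresh balanced fold assignments included).  The
    p-value uses the add-one estimator (1 + #{r_surr >= r_obs}) /
    (1 + n_surrogates), which never returns zero.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate dataset")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = cv_prediction_r(x, y, k=k, reps=reps, rng=rng)
    exceed = 0
    for _ in range(n_surrogates):
        y_perm = rng.permutation(y)
        r_s = cv_prediction_r(x, y_perm, k=k, reps=reps, rng=rng).r_obs_pred
        if r_s >= observed.r_obs_pred:
            exceed += 1
    p = (1 + exceed) / (1 + n_surrogates)
    return CVResult(
        r_obs_pred=observed.r_obs_pred,
        per_repetition=observed.per_repetition,
        p_perm=float(p),
        n_folds=k,
        n_repetitions=reps,
        n_surrogates=n_surrogates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# mixed models on the long table


def _zscore(v: pd.Series | np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def _fit_mixedlm(formula: str, data: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.mixedlm(formula, data, groups=data["mother_id"])
        return model.fit(reml=True)


def fit_random_intercept_model(long_table: pd.DataFrame, feature: str) -> MixedModelResult:
    """Random-intercept model of one feature against child age.

    ``feature ~ child_age + (1 | mother)``, fit by REML on the long
    per-utterance table.  The slope is standardized by refitting on
    z-scored outcome and predictor (z across all rows).  Inference on the
    slope uses the large-sample normal (Wald) approximation; the method is
    recorded in ``df_method``.
    """
    if long_table["mother_id"].nunique() < 2:
        raise ValueError("need at least 2 mothers for a random-intercept model")
    data = pd.DataFrame(
        {
            "mother_id": long_table["mother_id"].values,
            "y": _zscore(long_table[feature]),
            "age": _zscore(long_table["child_age"]),
        }
    )
    res = _fit_mixedlm("y ~ age", data)
    beta = float(res.params["age"])
    ci = res.conf_int().loc["age"]
    return MixedModelResult(
        beta_std=beta,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        t=float(res.tvalues["age"]),
        df=np.inf,
        p=float(res.pvalues["age"]),
        var_mother=float(res.cov_re.iloc[0, 0]),
        var_resid=float(res.scale),
        df_method="wald-normal",
        converged=bool(res.converged),
    )


def fit_brightness_word_model(long_table: pd.DataFrame) -> MixedModelResult:
    """Brightness model with nonsense-word main effect and word x age
    interaction, plus a random intercept per mother.

    The initial stop consonant of each nonsense word carries distinct
    high-frequency energy, which moves the spectral centroid; the word
    terms absorb that, and the interaction tests whether the age relation
    is word-specific.  Brightness and age are z-scored; word is a
    treatment-coded categorical.
    """
    words = sorted(long_table["word"].unique())
    if len(words) < 2:
        raise ValueError(
            "only one word label present; use fit_random_intercept_model instead"
        )
    data = pd.DataFrame(
        {
            "mother_id": long_table["mother_id"].values,
            "y": _zscore(long_table["brightness"]),
            "age": _zscore(long_table["child_age"]),
            "word": pd.Categorical(long_table["word"].values, categories=words),
        }
    )
    res = _fit_mixedlm("y ~ age * word", data)
    ci = res.conf_int()
    word_effects = {}
    interaction_effects = {}
    for name in res.params.index:
        entry = {
            "beta_std": float(res.params[name]),
            "ci_low": float(ci.loc[name, 0]),
            "ci_high": float(ci.loc[name, 1]),
            "t": float(res.tvalues[name]),
            "p": float(res.pvalues[name]),
        }
        if name.startswith("age:word"):
            interaction_effects[name] = entry
        elif name.startswith("word"):
            word_effects[name] = entry
    aci = ci.loc["age"]
    return MixedModelResult(
        beta_std=float(res.params["age"]),
        ci_low=float(aci[0]),
        ci_high=float(aci[1]),
        t=float(res.tvalues["age"]),
        df=np.inf,
        p=float(res.pvalues["age"]),
        var_mother=float(res.cov_re.iloc[0, 0]),
        var_resid=float(res.scale),
        df_method="wald-normal",
        converged=bool(res.converged),
        word_effects=word_effects,
        interaction_effects=interaction_effects,
    )


# ---------------------------------------------------------------------------
# multiple regression on the per-mother table


def _check_collinearity(records: pd.DataFrame, predictors: list[str]) -> None:
    for i, a in enumerate(predictors):
        for b in predictors[i + 1 :]:
            r = np.corrcoef(records[a], records[b])[0, 1]
            if abs(r) > 1 - 1e-10:
                raise ValueError(f"predictors {a!r} and {b!r} are exactly collinear")


def _standardized_ols(records: pd.DataFrame, outcome: str, predictors: list[str]):
    Z = pd.DataFrame({p: _zscore(records[p]) for p in predictors})
    yz = _zscore(records[outcome])
    X = sm.add_constant(Z)
    return sm.OLS(yz, X).fit()


def simultaneous_regression(
    records: pd.DataFrame,
    outcome: str = "child_age",
    predictors: tuple = FEATURES,
) -> RegressionTable:
    """Multiple regression of child age on all features at once, with
    standardized betas (everything z-scored before fitting)."""
    predictors = list(predictors)
    n = len(records)
    if n <= len(predictors) + 1:
        raise ValueError(f"need n > {len(predictors) + 1} records, got {n}")
    _check_collinearity(records, predictors)
    res = _standardized_ols(records, outcome, predictors)
    ci = res.conf_int()
    table = {
        p: {
            "beta_std": float(res.params[p]),
            "ci_low": float(ci.loc[p, 0]),
            "ci_high": float(ci.loc[p, 1]),
            "t": float(res.tvalues[p]),
            "p": float(res.pvalues[p]),
        }
        for p in predictors
    }
    return RegressionTable(
        predictors=table,
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        f_p=float(res.f_pvalue),
    )


def stepwise_model_comparison(
    records: pd.DataFrame,
    outcome: str = "child_age",
    base_predictor: str = "pitch_height",
    other_predictors: tuple = ("pitch_range", "duration", "amplitude", "brightness"),
) -> RegressionTable:
    """Base model (outcome ~ pitch height) versus one-feature extensions.

    The base row carries adjusted R-squared and the F test against the
    intercept-only model; each comparison row adds a single feature and
    reports the nested-model F test and the change in adjusted R-squared.
    """
    _check_collinearity(records, [base_predictor, *other_predictors])
    base = _standardized_ols(records, outcome, [base_predictor])
    ci = base.conf_int()
    rows = []
    for feat in other_predictors:
        ext = _standardized_ols(records, outcome, [base_predictor, feat])
        f_res = ext.compare_f_test(base)
        rows.append(
            {
                "added_predictor": feat,
                "adj_r2": float(ext.rsquared_adj),
                "delta_adj_r2": float(ext.rsquared_adj - base.rsquared_adj),
                "F": float(f_res[0]),
                "p": float(f_res[1]),
            }
        )
    return RegressionTable(
        predictors={
            base_predictor: {
                "beta_std": float(base.params[base_predictor]),
                "ci_low": float(ci.loc[base_predictor, 0]),
                "ci_high": float(ci.loc[base_predictor, 1]),
                "t": float(base.tvalues[base_predictor]),
                "p": float(base.pvalues[base_predictor]),
            }
        },
        adj_r2=float(base.rsquared_adj),
        f_stat=float(base.fvalue),
        f_p=float(base.f_pvalue),
        comparisons=tuple(rows),
    )


# ---------------------------------------------------------------------------
# subgroups and extrapolation


def subgroup_correlations(
    records: pd.DataFrame,
    x: str,
    y: str,
    grouping: str = "child_sex",
    min_n: int = 4,
) -> dict:
    """Pearson inference within each level of a grouping column.

    Groups smaller than ``min_n`` are reported as skipped rather than
    analyzed.  Returns ``{level: CorrelationResult | "skipped (n=...)"}``.
    """
    out: dict = {}
    for level, sub in records.groupby(grouping):
        if len(sub) < min_n:
            out[level] = f"skipped (n={len(sub)} < {min_n})"
        else:
            out[level] = pearson_inference(sub[x], sub[y])
    return out


def extrapolate_adult_pitch_age(
    records: pd.DataFrame,
    reference_pitch: float = 175.0,
    min_abs_slope: float = 1e-6,
) -> float:
    """Age at which the fitted pitch-height line reaches a reference
    adult-directed pitch: (reference - intercept) / slope.

    Requires a negative, non-negligible slope of pitch height on child
    age; otherwise the extrapolation is undefined and raises.
    """
    age = np.asarray(records["child_age"], dtype=float)
    pitch = np.asarray(records["pitch_height"], dtype=float)
    slope, intercept = np.polyfit(age, pitch, 1)
    if slope >= 0 or abs(slope) < min_abs_slope:
        raise ValueError(
            f"extrapolation undefined: pitch-height slope is {slope:.4g} Hz/year"
        )
    return float((reference_pitch - intercept) / slope)
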