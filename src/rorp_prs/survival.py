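"""Validation of polygenic scores against survival and tumor features.

Cox proportional-hazards models (lifelines, Efron ties) with ancestry
adjustment and nested covariate sets, Kaplan–Meier tertile analyses with
log-rank tests, REML random-effects meta-analysis with Cochran's Q and I²,
Grønnesby–Borgan goodness-of-fit, optimism-corrected bootstrap calibration,
and logistic/multinomial tumor-feature associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.optimize import minimize_scalar

from ._cox import score_test
from .errors import InputError

ANCESTRY_COVARIATES = [f"PC{i}" for i in range(1, 11)]
TREATMENT_COVARIATES = ["radiation", "chemotherapy", "trastuzumab", "hormone_therapy"]

#: Nested covariate sets mirroring the adjusted survival models: ancestry
#: only, + age/BMI, + stage, + treatments, + measured ROR-P, + ER status.
NESTED_COVARIATE_SETS = {
    "ancestry": ANCESTRY_COVARIATES,
    "age_bmi": ANCESTRY_COVARIATES + ["age", "bmi"],
    "stage": ANCESTRY_COVARIATES + ["age", "bmi", "stage"],
    "treatments": ANCESTRY_COVARIATES + ["age", "bmi", "stage"] + TREATMENT_COVARIATES,
    "measured_rorp": ANCESTRY_COVARIATES + ["measured_rorp"],
    "er": ANCESTRY_COVARIATES + ["er_status"],
}

_Z = stats.norm.ppf(0.975)


@dataclass
class AssociationResult:
    """A ratio-scale effect per SD of a standardized exposure."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int | None = None
    scale: str = "HR"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise InputError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket {self.estimate}"
            )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "scale": self.scale,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
            "events": self.events,
        }


@dataclass
class CoxModel:
    """A fitted Cox model plus the pieces needed for downstream diagnostics."""

    fitter: CoxPHFitter
    data: pd.DataFrame
    exposures: list[str]
    covariates: list[str]
    results: list[AssociationResult]

    @property
    def design_columns(self) -> list[str]:
        return list(self.fitter.params_.index)

    def linear_predictor(self) -> np.ndarray:
        X = self.data[self.design_columns].to_numpy(dtype=float)
        return X @ self.fitter.params_.to_numpy()


def cox_fit(
    records: pd.DataFrame,
    exposures: str | list[str],
    covariates: list[str] | str = "ancestry",
    time_col: str = "time",
    event_col: str = "event",
) -> CoxModel:
    """Cox proportional-hazards fit (Efron ties); one result per exposure.

    ``covariates`` may be a named nested set (key of NESTED_COVARIATE_SETS)
    or an explicit column list. Exposures are expected standardized so the
    hazard ratio reads per SD.
    """
    if isinstance(exposures, str):
        exposures = [exposures]
    if isinstance(covariates, str):
        try:
            covariates = NESTED_COVARIATE_SETS[covariates]
        except KeyError:
            raise InputError(
                f"unknown covariate set {covariates!r}; options: {list(NESTED_COVARIATE_SETS)}"
            ) from None
    cols = [time_col, event_col] + exposures + covariates
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise InputError(f"records missing columns: {missing}")
    df = records[cols].dropna()
    n_events = int(df[event_col].sum())
    if n_events < 2:
        raise InputError(f"need at least 2 events, found {n_events}")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # pragma: no cover - lifelines raises various types
        raise InputError(f"Cox model failed to converge: {exc}") from exc
    results = []
    for exp_col in exposures:
        coef = float(cph.params_[exp_col])
        se = float(cph.standard_errors_[exp_col])
        results.append(
            AssociationResult(
                label=exp_col,
                estimate=float(np.exp(coef)),
                ci_low=float(np.exp(coef - _Z * se)),
                ci_high=float(np.exp(coef + _Z * se)),
                p=float(2 * stats.norm.sf(abs(coef / se))),
                n=len(df),
                events=n_events,
                scale="HR",
            )
        )
    # reorder fitted data columns so linear_predictor aligns with params_
    ordered = [time_col, event_col] + list(cph.params_.index)
    return CoxModel(
        fitter=cph,
        data=df[ordered].rename(columns={}),
        exposures=exposures,
        covariates=[c for c in cph.params_.index if c not in exposures],
        results=results,
    )


def cox_nested_models(
    records: pd.DataFrame, exposure: str, sets: list[str] | None = None
) -> dict[str, AssociationResult]:
    """Fit the exposure under each nested covariate set; skip sets lacking columns."""
    out = {}
    for name in sets or list(NESTED_COVARIATE_SETS):
        needed = NESTED_COVARIATE_SETS[name]
        if any(c not in records.columns for c in needed):
            continue
        out[name] = cox_fit(records, exposure, needed).results[0]
    return out


@dataclass
class KMTertiles:
    groups: pd.Series
    curves: dict[str, pd.DataFrame]
    chi2: float
    df: int
    p: float
    cutpoints: tuple[float, float]


def km_tertiles(
    records: pd.DataFrame,
    exposure: str,
    time_col: str = "time",
    event_col: str = "event",
) -> KMTertiles:
    """Kaplan–Meier curves by exposure tertile plus the 2-df log-rank test.

    Tertiles are rank-based on the analyzed cases, so group sizes differ by
    at most one sample.
    """
    df = records[[time_col, event_col, exposure]].dropna()
    n = len(df)
    if n < 3:
        raise InputError("need at least 3 samples for tertiles")
    order = np.argsort(df[exposure].to_numpy(), kind="mergesort")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    groups = pd.Series(
        np.array(["T1", "T2", "T3"])[ranks * 3 // n], index=df.index, name="tertile"
    )
    x_sorted = df[exposure].to_numpy()[order]
    cutpoints = (float(x_sorted[n // 3]), float(x_sorted[2 * n // 3]))
    curves = {}
    for g in ("T1", "T2", "T3"):
        kmf = KaplanMeierFitter()
        sub = df[groups == g]
        kmf.fit(sub[time_col], sub[event_col], label=g)
        curves[g] = kmf.survival_function_
    lr = multivariate_logrank_test(df[time_col], groups, df[event_col])
    return KMTertiles(
        groups=groups,
        curves=curves,
        chi2=float(lr.test_statistic),
        df=2,
        p=float(lr.p_value),
        cutpoints=cutpoints,
    )


@dataclass
class MetaResult:
    """Random-effects synthesis of study-level ratio effects."""

    study_effects: np.ndarray  # log scale
    study_ses: np.ndarray
    tau2: float
    summary: float             # ratio scale
    ci_low: float
    ci_high: float
    p: float
    q: float
    q_p: float
    i2: float
    labels: list[str] = field(default_factory=list)


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """REML estimate of the between-study variance by bounded 1-D optimization."""
    if len(y) < 2:
        return 0.0

    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    upper = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1e-3)
    res = minimize_scalar(
        neg_restricted_ll, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    if neg_restricted_ll(0.0) <= res.fun:
        tau2 = 0.0
    return max(tau2, 0.0)


def random_effects_meta(
    results: list[AssociationResult] | pd.DataFrame,
) -> MetaResult:
    """REML random-effects meta-analysis of ratio-scale study results.

    Study SEs are recovered from Wald confidence intervals as
    ``(ln(hi) - ln(lo)) / (2 * 1.96)``. The summary is the inverse-variance
    weighted mean of log-effects with weights ``1 / (SE^2 + tau^2)``;
    heterogeneity is summarized by Cochran's Q (fixed-effect weights) and
    ``I^2 = max(0, (Q - df) / Q) * 100``.
    """
    if isinstance(results, pd.DataFrame):
        rows = results.to_dict("records")
        labels = [str(r.get("label", i)) for i, r in enumerate(rows)]
        est = np.array([r["estimate"] for r in rows], dtype=float)
        lo = np.array([r["ci_low"] for r in rows], dtype=float)
        hi = np.array([r["ci_high"] for r in rows], dtype=float)
    else:
        labels = [r.label for r in results]
        est = np.array([r.estimate for r in results], dtype=float)
        lo = np.array([r.ci_low for r in results], dtype=float)
        hi = np.array([r.ci_high for r in results], dtype=float)
    if len(est) < 1:
        raise InputError("meta-analysis needs at least one study")
    if np.any(lo <= 0) or np.any(est <= 0):
        raise InputError("ratio-scale estimates and CI bounds must be positive")
    y = np.log(est)
    se = (np.log(hi) - np.log(lo)) / (2 * 1.96)
    v = se**2
    tau2 = _reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(1.0 / np.sqrt(np.sum(w)))
    # Cochran's Q with fixed-effect weights
    w_fe = 1.0 / v
    mu_fe = np.sum(w_fe * y) / np.sum(w_fe)
    q = float(np.sum(w_fe * (y - mu_fe) ** 2))
    dfree = len(y) - 1
    q_p = float(stats.chi2.sf(q, dfree)) if dfree > 0 else 1.0
    i2 = float(max(0.0, (q - dfree) / q) * 100) if q > 0 and dfree > 0 else 0.0
    return MetaResult(
        study_effects=y,
        study_ses=se,
        tau2=tau2,
        summary=float(np.exp(mu)),
        ci_low=float(np.exp(mu - _Z * se_mu)),
        ci_high=float(np.exp(mu + _Z * se_mu)),
        p=float(2 * stats.norm.sf(abs(mu / se_mu))),
        q=q,
        q_p=q_p,
        i2=i2,
        labels=labels,
    )


def gronnesby_borgan(
    model: CoxModel, n_groups: int = 10
) -> tuple[float, int, float]:
    """Grønnesby–Borgan goodness-of-fit: score test for risk-group indicators.

    Samples are split into ``n_groups`` equal-size strata of the fitted
    linear predictor; the statistic is the Rao score test for adding the
    ``n_groups - 1`` group indicators to the fitted model, with that many
    degrees of freedom. Groups without events are merged into the adjacent
    lower-risk group (with a warning).
    """
    if n_groups < 2:
        raise InputError("n_groups must be >= 2")
    df = model.data
    time = df[df.columns[0]].to_numpy(dtype=float)
    event = df[df.columns[1]].to_numpy(dtype=int)
    lp = model.linear_predictor()
    n = len(lp)
    order = np.argsort(lp, kind="mergesort")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    groups = ranks * n_groups // n
    # merge event-free groups downward so every retained group has events
    merged = groups.copy()
    for g in range(n_groups):
        if event[merged == g].sum() == 0 and (merged == g).any():
            target = g - 1 if g > 0 else g + 1
            warnings.warn(f"risk group {g} has no events; merged with {target}", stacklevel=2)
            merged[merged == g] = target
    levels = np.unique(merged)
    if len(levels) < 2:
        raise InputError("fewer than 2 risk groups with events; test undefined")
    dummies = np.column_stack([(merged == g).astype(float) for g in levels[1:]])
    X_base = df[model.design_columns].to_numpy(dtype=float)
    stat, dfree = score_test(
        time, event, X_base, model.fitter.params_.to_numpy(), dummies
    )
    return stat, dfree, float(stats.chi2.sf(stat, dfree))


def _km_at(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    return float(kmf.survival_function_at_times(horizon).iloc[0])


def bootstrap_calibration(
    records: pd.DataFrame,
    exposure: str,
    covariates: list[str] | str = "ancestry",
    horizon: float = 5.0,
    n_boot: int = 200,
    n_strata: int = 10,
    seed: int | None = None,
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Optimism-corrected predicted vs observed survival at ``horizon``.

    Samples are grouped into ``n_strata`` equal-size strata of model-predicted
    risk; observed survival per stratum is Kaplan–Meier at the horizon. The
    bias correction subtracts the bootstrap optimism: for each of ``n_boot``
    resamples, the model is refit and the (observed - predicted) calibration
    error is evaluated on the bootstrap sample and on the original sample;
    the mean difference is removed from the apparent observed values.
    """
    model = cox_fit(records, exposure, covariates, time_col, event_col)
    df = model.data
    if horizon > df[time_col].max():
        raise InputError(f"horizon {horizon} exceeds the longest follow-up")

    def strata_errors(fit_model: CoxModel, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        X = data[fit_model.design_columns].to_numpy(dtype=float)
        lp = X @ fit_model.fitter.params_.to_numpy()
        surv = fit_model.fitter.predict_survival_function(
            data[fit_model.design_columns], times=[horizon]
        ).to_numpy()[0]
        n = len(lp)
        order = np.argsort(lp, kind="mergesort")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        grp = ranks * n_strata // n
        pred = np.empty(n_strata)
        err = np.empty(n_strata)
        for g in range(n_strata):
            m = grp == g
            pred[g] = surv[m].mean()
            obs = _km_at(
                data.loc[m, time_col].to_numpy(), data.loc[m, event_col].to_numpy(), horizon
            )
            err[g] = obs - pred[g]
        return pred, err

    pred_app, err_app = strata_errors(model, df)
    if n_boot == 0:
        warnings.warn("n_boot=0: returning apparent (uncorrected) calibration", stacklevel=2)
        optimism = np.zeros(n_strata)
    else:
        rng = np.random.default_rng(None if seed is None else [23, seed])
        diffs = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(df), len(df))
            boot = df.iloc[idx].reset_index(drop=True)
            try:
                bm = cox_fit(boot, exposure, model.covariates, time_col, event_col)
                _, err_boot = strata_errors(bm, boot)
                _, err_orig = strata_errors(bm, df)
            except Exception as exc:
                warnings.warn(f"bootstrap refit skipped: {exc}", stacklevel=2)
                continue
            diffs.append(err_boot - err_orig)
        optimism = np.mean(diffs, axis=0) if diffs else np.zeros(n_strata)
    observed_app = pred_app + err_app
    observed_corr = observed_app - optimism
    return pd.DataFrame(
        {
            "stratum": np.arange(1, n_strata + 1),
            "predicted": pred_app,
            "observed": observed_app,
            "observed_corrected": observed_corr,
        }
    )


def feature_association(
    prs: pd.Series,
    feature: pd.Series,
    covars: pd.DataFrame,
) -> dict:
    """Association between a standardized PRS and a tumor feature.

    Binary features: logistic regression of the feature on the PRS adjusted
    for PC1-10 (OR per SD), plus a two-sample t-test of the PRS across
    feature levels. Features with >= 3 categories: multinomial logistic
    regression (one contrast per non-reference level; reference = first
    category in sorted order) plus one-way ANOVA.
    """
    import statsmodels.api as sm

    df = pd.concat([prs.rename("prs"), feature.rename("feature"), covars], axis=1).dropna()
    levels = sorted(df["feature"].unique())
    if len(levels) < 2:
        raise InputError("feature has a single level; association undefined")
    X = sm.add_constant(df[["prs"] + ANCESTRY_COVARIATES].astype(float))
    n = len(df)
    if len(levels) == 2:
        ybin = (df["feature"] == levels[1]).astype(float)
        try:
            fit = sm.Logit(ybin, X).fit(disp=False)
        except Exception as exc:
            raise InputError(
                f"logistic fit failed (possible perfect separation; "
                f"penalized fits are out of scope): {exc}"
            ) from exc
        coef, se = fit.params["prs"], fit.bse["prs"]
        groups = [df.loc[df["feature"] == lev, "prs"] for lev in levels]
        tstat, tp = stats.ttest_ind(*groups, equal_var=False)
        return {
            "results": [
                AssociationResult(
                    label=f"{levels[1]} vs {levels[0]}",
                    estimate=float(np.exp(coef)),
                    ci_low=float(np.exp(coef - _Z * se)),
                    ci_high=float(np.exp(coef + _Z * se)),
                    p=float(fit.pvalues["prs"]),
                    n=n,
                    scale="OR",
                )
            ],
            "companion_test": {"name": "t-test", "statistic": float(tstat), "p": float(tp)},
        }
    cat = pd.Categorical(df["feature"], categories=levels)
    try:
        fit = sm.MNLogit(pd.Series(cat.codes, index=df.index), X).fit(disp=False)
    except Exception as exc:
        raise InputError(f"multinomial fit failed: {exc}") from exc
    results = []
    prs_ix = list(X.columns).index("prs")
    for j, lev in enumerate(levels[1:]):
        coef = float(fit.params.iloc[prs_ix, j])
        se = float(fit.bse.iloc[prs_ix, j])
        results.append(
            AssociationResult(
                label=f"{lev} vs {levels[0]}",
                estimate=float(np.exp(coef)),
                ci_low=float(np.exp(coef - _Z * se)),
                ci_high=float(np.exp(coef + _Z * se)),
                p=float(2 * stats.norm.sf(abs(coef / se))),
                n=n,
                scale="OR",
            )
        )
    groups = [df.loc[df["feature"] == lev, "prs"] for lev in levels]
    fstat, fp = stats.f_oneway(*groups)
    return {
        "results": results,
        "companion_test": {"name": "ANOVA", "statistic": float(fstat), "p": float(fp)},
    }


def prs_rorp_correlation(prs: pd.Series, measured_rorp: pd.Series) -> tuple[float, float]:
    """Pearson correlation between the PRS and measured ROR-P, with two-sided p."""
    df = pd.concat([prs.rename("prs"), measured_rorp.rename("rorp")], axis=1).dropna()
    if len(df) < 3:
        raise InputError("need at least 3 paired samples")
    if df["prs"].std() == 0 or df["rorp"].std() == 0:
        raise InputError("zero variance in one of the paired measures")
    r, p = stats.pearsonr(df["prs"], df["rorp"])
    return float(r), float(p)
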