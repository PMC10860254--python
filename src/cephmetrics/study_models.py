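"""Inferential models for the device-comparison study.

Each study record is one submission: a subject's per-submission
accuracy (MRE in mm) and tracing time (minutes) together with the
design covariates — device (tablet/desktop), cephalogram (A/B),
gender and analysis order.  Subjects contribute up to two records
(one per device), so responses are modelled with a linear mixed model
containing the design fixed effects and a random intercept per
subject.  Fixed effects are screened and selected by likelihood-ratio
tests on maximum-likelihood fits, and measurement-level group
comparisons use Welch's t-test (heterogeneous variances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyRecord",
    "LMEFit",
    "LRTResult",
    "SelectionResult",
    "EFFECTS",
    "records_to_frame",
    "fit_lme",
    "lrt",
    "select_model",
    "welch_t",
]

#: Candidate fixed effects and their dummy coding (reference level first).
#: Reference levels: image A, gender female, first order, desktop.
EFFECTS: dict[str, tuple[str, str]] = {
    "device": ("desktop", "tablet"),
    "image": ("A", "B"),
    "gender": ("female", "male"),
    "order": ("first", "second"),
}


@dataclass(frozen=True)
class StudyRecord:
    """One submission's responses and covariates."""

    subject_id: str
    device: str  # "tablet" | "desktop"
    image: str  # "A" | "B"
    gender: str  # "female" | "male"
    order: str  # "first" | "second"
    mre: float  # mm
    time: float | None = None  # minutes


def records_to_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Tidy frame with 0/1 dummies for the non-reference levels."""
    df = pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "device": [r.device for r in records],
            "image": [r.image for r in records],
            "gender": [r.gender for r in records],
            "order": [r.order for r in records],
            "mre": [r.mre for r in records],
            "time": [r.time for r in records],
        }
    )
    for effect, (ref, alt) in EFFECTS.items():
        df[effect] = pd.Categorical(df[effect], categories=[ref, alt])
        if df[effect].isna().any():
            bad = sorted(set(r for r in df[effect][df[effect].isna()].index))
            raise ValueError(f"unknown {effect} level in records {bad}")
        df[f"{effect}_{alt}"] = (df[effect] == alt).astype(float)
    return df


@dataclass(frozen=True)
class LMEFit:
    """A fitted random-intercept linear mixed model (ML)."""

    response: str
    effects: Mapping[str, tuple[float, float, float, float]]
    #: effect -> (estimate, ci_low, ci_high, p); "intercept" included
    fixed: tuple[str, ...]  # effect names beyond the intercept
    subject_sd: float  # random-intercept SD
    residual_sd: float
    llf: float  # maximized log-likelihood
    n_obs: int
    n_fixed: int  # number of fixed-effect coefficients incl. intercept
    converged: bool
    singular: bool  # random-intercept variance at (or near) zero

    def estimate(self, effect: str) -> float:
        return self.effects[effect][0]


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of nested ML fits."""

    statistic: float
    df: int
    p_value: float
    effect: str


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the two-stage likelihood-ratio model selection."""

    fit: LMEFit
    kept: tuple[str, ...]
    screen: Mapping[str, float]  # stage-1 p-value per candidate effect


def _design(df: pd.DataFrame, fixed: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = ["intercept"] + [f"{e}_{EFFECTS[e][1]}" for e in fixed]
    X = np.column_stack(
        [np.ones(len(df))] + [df[f"{e}_{EFFECTS[e][1]}"].to_numpy() for e in fixed]
    )
    return X, cols


def fit_lme(
    records: Sequence[StudyRecord] | pd.DataFrame,
    response: str = "mre",
    fixed: Sequence[str] = (),
) -> LMEFit:
    """Fit response ~ fixed effects + (1 | subject) by maximum likelihood.

    Wald 95% confidence intervals and normal-theory p-values are
    reported for the fixed effects.  A fit whose subject variance
    collapses to (near) zero is flagged ``singular``, not hidden; its
    fixed-effect estimates coincide with ordinary least squares.
    """
    import statsmodels.api as sm

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    unknown = set(fixed) - set(EFFECTS)
    if unknown:
        raise ValueError(f"unknown fixed effects {sorted(unknown)}")
    y = df[response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"missing values in response {response!r}")
    X, names = _design(df, fixed)

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=df["subject"].to_numpy())
        for method in ("bfgs", "lbfgs", "powell", "cg"):
            try:
                result = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(result.llf):
                break
            result = None
    if result is None:
        # subject variance at the boundary: the ML mixed model collapses
        # to OLS with ML error variance
        ols = sm.OLS(y, X).fit()
        sigma2 = max(float(ols.ssr / len(y)), 1e-24)
        z = stats.norm.ppf(0.975)
        effects = {}
        for i, col in enumerate(names):
            est, se = float(ols.params[i]), float(ols.bse[i])
            p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else float("nan")
            key = "intercept" if col == "intercept" else fixed[i - 1]
            effects[key] = (est, est - z * se, est + z * se, p)
        llf = -0.5 * len(y) * (np.log(2 * np.pi * sigma2) + 1.0)
        return LMEFit(
            response=response,
            effects=effects,
            fixed=tuple(fixed),
            subject_sd=0.0,
            residual_sd=float(np.sqrt(sigma2)),
            llf=float(llf),
            n_obs=len(df),
            n_fixed=len(names),
            converged=True,
            singular=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = np.asarray(result.fe_params, dtype=float)
        bse = np.asarray(result.bse_fe, dtype=float)
    z = stats.norm.ppf(0.975)
    effects: dict[str, tuple[float, float, float, float]] = {}
    for i, col in enumerate(names):
        est, se = params[i], bse[i]
        p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else float("nan")
        key = "intercept" if col == "intercept" else fixed[i - 1]
        effects[key] = (float(est), float(est - z * se), float(est + z * se), p)

    subject_var = float(np.asarray(result.cov_re)[0, 0])
    resid_var = float(result.scale)
    singular = subject_var <= 1e-8 * max(resid_var, 1e-12)
    return LMEFit(
        response=response,
        effects=effects,
        fixed=tuple(fixed),
        subject_sd=float(np.sqrt(max(subject_var, 0.0))),
        residual_sd=float(np.sqrt(resid_var)),
        llf=float(result.llf),
        n_obs=len(df),
        n_fixed=len(names),
        converged=bool(result.converged),
        singular=singular,
    )


def lrt(full: LMEFit, null: LMEFit, effect: str = "") -> LRTResult:
    """Likelihood-ratio test of a full ML fit against a nested null fit."""
    if full.response != null.response or full.n_obs != null.n_obs:
        raise ValueError("models were not fitted to the same data")
    if not set(null.fixed) <= set(full.fixed):
        raise ValueError("null model is not nested in the full model")
    df = full.n_fixed - null.n_fixed
    if df < 1:
        if full.fixed == null.fixed:
            return LRTResult(0.0, 0, 1.0, effect)
        raise ValueError("full model has no extra parameters")
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(stat, df))
    name = effect or ",".join(sorted(set(full.fixed) - set(null.fixed)))
    return LRTResult(stat, df, p, name)


def select_model(
    records: Sequence[StudyRecord] | pd.DataFrame,
    response: str = "mre",
    candidates: Sequence[str] = ("device", "image", "gender", "order"),
    alpha: float = 0.05,
) -> SelectionResult:
    """Two-stage likelihood-ratio selection of fixed effects.

    Stage 1 screens each candidate singly against the intercept-only
    model.  Stage 2 adds the screened effects in order of ascending
    stage-1 p-value (ties alphabetical), keeping each only if the
    incremental LRT against the previous model is significant at
    ``alpha``.  May return the intercept-only model.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    null = fit_lme(df, response, ())
    screen: dict[str, float] = {}
    for effect in candidates:
        single = fit_lme(df, response, (effect,))
        screen[effect] = lrt(single, null, effect).p_value

    significant = sorted(
        (e for e in candidates if screen[e] < alpha), key=lambda e: (screen[e], e)
    )
    kept: list[str] = []
    current = null
    for effect in significant:
        trial = fit_lme(df, response, tuple(kept + [effect]))
        if lrt(trial, current, effect).p_value < alpha:
            kept.append(effect)
            current = trial
    return SelectionResult(fit=current, kept=tuple(kept), screen=screen)


def welch_t(group1: Sequence[float], group2: Sequence[float]) -> tuple[float, float, float]:
    """Welch's t-test (heterogeneous variances): (t, df, p).

    Degrees of freedom follow Welch–Satterthwaite.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
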