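"""Average treatment effect estimators with cross-fitted nuisances.

Implements the four estimator families used for emulated-trial
analyses of a binary treatment and binary outcome:

- naive: unadjusted contrast of arm means (the bias reference);
- IPW: Hajek (self-normalised) inverse-propensity-weighted contrast;
- G-formula T-learner: per-arm outcome models, averaged counterfactual
  predictions over the whole cohort;
- AIPW: doubly robust augmented IPW via the influence-function
  pseudo-outcome psi;
- DML: partially linear residual-on-residual regression.

Nuisance models (propensity e(X), arm-specific outcome regressions
mu1(X), mu0(X)) are ridge logistic regressions or random forests, with
optional random-search hyperparameter tuning, always fit with K-fold
cross-fitting (out-of-fold predictions only) and propensity clipping.
Confidence intervals are nonparametric patient-level bootstrap
percentiles with the nuisances refit on every resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.stats import loguniform, randint
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "NuisanceSpec",
    "NuisancePredictions",
    "EffectEstimate",
    "PositivityError",
    "fit_nuisances",
    "naive_contrast",
    "estimate_ipw",
    "estimate_gformula_t",
    "estimate_aipw",
    "estimate_dml",
    "bootstrap_ci",
    "transform_estimand",
    "overlap_diagnostic",
    "misspecified_predictions",
]

NUISANCE_FAMILIES = ("ridge_logistic", "random_forest")

ESTIMATOR_NAMES = ("naive", "IPW", "Gformula_T", "AIPW", "DML")


class PositivityError(RuntimeError):
    """Raised when propensity estimates violate the overlap assumption."""


@dataclass(frozen=True)
class NuisanceSpec:
    """How to fit a nuisance model.

    With ``fixed_params`` set, those hyperparameters are used directly;
    otherwise ``search_budget`` random draws from ``param_ranges`` are
    scored by ``cv_folds``-fold log-loss inside each training fold.
    ``search_budget=1`` with no ranges falls back to library defaults
    tempered for stability (shallow subsampled forests).
    """

    family: str = "ridge_logistic"
    search_budget: int = 10
    cv_folds: int = 3
    param_ranges: Mapping[str, object] | None = None
    fixed_params: Mapping[str, object] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.family not in NUISANCE_FAMILIES:
            raise ValueError(
                f"unknown nuisance family {self.family!r}; options: {NUISANCE_FAMILIES}"
            )
        if self.search_budget < 1:
            raise ValueError("search_budget must be >= 1")
        if self.param_ranges is not None and not self.param_ranges:
            raise ValueError("param_ranges, when given, must be non-empty")


# Shallow, subsampled, feature-rich trees: at cohort scale (n ~ 10^4) this
# keeps probability estimates smooth and well calibrated while staying cheap
# enough to refit inside patient-level bootstraps.
_DEFAULT_FOREST = dict(
    n_estimators=30,
    max_depth=8,
    min_samples_leaf=50,
    max_features=0.7,
    max_samples=0.2,
)

_DEFAULT_RANGES = {
    "ridge_logistic": {"C": loguniform(1e-3, 1e2)},
    "random_forest": {
        "n_estimators": randint(30, 150),
        "max_depth": randint(3, 10),
        "min_samples_leaf": randint(20, 200),
    },
}


def _base_model(spec: NuisanceSpec, seed: int):
    if spec.family == "ridge_logistic":
        # scaling keeps the l2 penalty comparable across features and makes
        # the solver converge in a handful of iterations
        return Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(C=1.0, max_iter=200, solver="newton-cholesky"))]
        )
    return RandomForestClassifier(random_state=seed, n_jobs=1, **_DEFAULT_FOREST)


def _spec_params(spec: NuisanceSpec, params: Mapping[str, object]) -> dict:
    if spec.family == "ridge_logistic":
        return {f"clf__{k}": v for k, v in params.items()}
    return dict(params)


def _make_model(spec: NuisanceSpec, X: np.ndarray, y: np.ndarray, seed: int):
    """Instantiate (and possibly tune) a nuisance model on training data."""
    model = _base_model(spec, seed)
    if spec.fixed_params:
        model.set_params(**_spec_params(spec, spec.fixed_params))
        return model.fit(X, y)
    if spec.search_budget > 1:
        ranges = _spec_params(spec, spec.param_ranges or _DEFAULT_RANGES[spec.family])
        n_cv = min(spec.cv_folds, int(np.bincount(y).min()))
        if n_cv >= 2:
            search = RandomizedSearchCV(
                model,
                ranges,
                n_iter=spec.search_budget,
                cv=StratifiedKFold(n_cv, shuffle=True, random_state=seed),
                scoring="neg_log_loss",
                random_state=seed,
                n_jobs=1,
            )
            search.fit(X, y)
            return search.best_estimator_
    return model.fit(X, y)


@dataclass
class NuisancePredictions:
    """Out-of-fold nuisance predictions for every patient."""

    e_hat: np.ndarray  # clipped propensity estimates, in (0, 1)
    mu1: np.ndarray  # P(Y=1 | X, A=1)
    mu0: np.ndarray  # P(Y=1 | X, A=0)
    folds: np.ndarray  # fold id each patient was *predicted* in
    clip_bounds: tuple[float, float]
    n_clipped: int

    def validate(self) -> None:
        lo, hi = self.clip_bounds
        if ((self.e_hat <= 0) | (self.e_hat >= 1)).any():
            raise PositivityError("propensity estimates must be strictly inside (0, 1)")
        if ((self.e_hat < lo - 1e-12) | (self.e_hat > hi + 1e-12)).any():
            raise ValueError("propensity estimates exceed the clipping bounds")


def fit_nuisances(
    X: np.ndarray,
    arm: np.ndarray,
    outcome: np.ndarray,
    propensity_spec: NuisanceSpec | None = None,
    outcome_spec: NuisanceSpec | None = None,
    k_folds: int = 5,
    clip: float = 0.01,
    seed: int = 0,
) -> NuisancePredictions:
    """Cross-fitted propensity and T-learner outcome predictions.

    Folds are stratified on the treatment arm; each patient's
    predictions come from models that never saw their fold.  mu1 is fit
    on treated training patients only, mu0 on controls only.
    """
    if k_folds < 2:
        raise ValueError("cross-fitting requires k_folds >= 2")
    propensity_spec = propensity_spec or NuisanceSpec()
    outcome_spec = outcome_spec or propensity_spec
    propensity_spec.validate()
    outcome_spec.validate()

    X = np.asarray(X, dtype=float)
    a = np.asarray(arm, dtype=int)
    y = np.asarray(outcome, dtype=int)
    n = len(a)
    if X.shape[0] != n or len(y) != n:
        raise ValueError("X, arm and outcome must have matching lengths")

    e_hat = np.full(n, np.nan)
    mu1 = np.full(n, np.nan)
    mu0 = np.full(n, np.nan)
    fold_id = np.full(n, -1, dtype=int)

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for k, (train, test) in enumerate(skf.split(X, a)):
        a_tr = a[train]
        if a_tr.sum() == 0 or (1 - a_tr).sum() == 0:
            raise ValueError(
                f"training fold {k} has a single arm only; use larger folds or "
                "stratified folding on a bigger sample"
            )
        prop = _make_model(propensity_spec, X[train], a_tr, seed=seed * 1000 + k)
        e_hat[test] = _predict_prob(prop, X[test])

        treated_tr = train[a_tr == 1]
        control_tr = train[a_tr == 0]
        m1 = _fit_outcome(outcome_spec, X[treated_tr], y[treated_tr], seed * 1000 + 100 + k)
        m0 = _fit_outcome(outcome_spec, X[control_tr], y[control_tr], seed * 1000 + 200 + k)
        mu1[test] = m1(X[test])
        mu0[test] = m0(X[test])
        fold_id[test] = k

    n_clipped = int(((e_hat < clip) | (e_hat > 1 - clip)).sum())
    if n_clipped > 0.5 * n:
        warnings.warn(
            f"{n_clipped}/{n} propensity estimates clipped at [{clip}, {1 - clip}]: "
            "overlap is effectively violated",
            RuntimeWarning,
            stacklevel=2,
        )
    e_hat = np.clip(e_hat, clip, 1 - clip)
    return NuisancePredictions(e_hat, mu1, mu0, fold_id, (clip, 1 - clip), n_clipped)


def _predict_prob(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    if proba.shape[1] == 1:  # degenerate single-class training data
        return np.full(len(X), float(model.classes_[0]))
    return proba[:, 1]


def _fit_outcome(spec: NuisanceSpec, X: np.ndarray, y: np.ndarray, seed: int):
    if len(np.unique(y)) < 2:
        const = float(y.mean()) if len(y) else 0.5
        return lambda Xt: np.full(len(Xt), const)
    model = _make_model(spec, X, y, seed)
    return lambda Xt: np.clip(_predict_prob(model, Xt), 0.0, 1.0)


@dataclass
class EffectEstimate:
    """A treatment-effect estimate with provenance.

    ``estimand_values`` holds the risk difference and, when both arm
    means are identified by the estimator, the risk ratio and odds
    ratio.  ``ci`` is a percentile-bootstrap interval on the risk
    difference, None until :func:`bootstrap_ci` fills it in.
    """

    estimator: str
    point: float  # risk difference
    arm_means: tuple[float, float] | None  # (E[Y(1)], E[Y(0)]) estimates
    estimand_values: dict[str, float]
    ci: tuple[float, float] | None = None
    ci_level: float | None = None
    n_bootstrap: int | None = None
    provenance: dict = field(default_factory=dict)
    psi: np.ndarray | None = None  # per-patient pseudo-outcomes (AIPW)

    def with_ci(self, lower: float, upper: float, level: float, n_boot: int) -> "EffectEstimate":
        return replace(self, ci=(lower, upper), ci_level=level, n_bootstrap=n_boot)

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "risk_difference": self.point,
            "arm_means": self.arm_means,
            "estimands": self.estimand_values,
            "ci": self.ci,
            "ci_level": self.ci_level,
            "n_bootstrap": self.n_bootstrap,
            "provenance": self.provenance,
        }


def transform_estimand(arm_means: tuple[float, float]) -> dict[str, float]:
    """Risk difference, risk ratio and odds ratio from (E[Y(1)], E[Y(0)]).

    Both means must be strictly inside (0, 1) for the ratio estimands;
    boundary values make RR/OR undefined and raise.
    """
    p1, p0 = float(arm_means[0]), float(arm_means[1])
    rd = p1 - p0
    out = {"risk_difference": rd}
    if not (0.0 < p1 < 1.0 and 0.0 < p0 < 1.0):
        raise ValueError(
            f"risk ratio / odds ratio undefined for boundary arm means ({p1}, {p0})"
        )
    out["risk_ratio"] = p1 / p0
    out["odds_ratio"] = (p1 / (1 - p1)) / (p0 / (1 - p0))
    return out


def _estimate_from_means(name: str, y1_mean: float, y0_mean: float, **kw) -> EffectEstimate:
    try:
        values = transform_estimand((y1_mean, y0_mean))
    except ValueError:
        values = {"risk_difference": y1_mean - y0_mean}
    return EffectEstimate(
        estimator=name,
        point=y1_mean - y0_mean,
        arm_means=(y1_mean, y0_mean),
        estimand_values=values,
        **kw,
    )


def naive_contrast(arm: np.ndarray, outcome: np.ndarray) -> EffectEstimate:
    """Unadjusted difference of observed arm means (bias reference)."""
    a = np.asarray(arm, dtype=bool)
    y = np.asarray(outcome, dtype=float)
    if a.sum() == 0 or (~a).sum() == 0:
        raise ValueError("naive contrast needs both arms populated")
    return _estimate_from_means("naive", float(y[a].mean()), float(y[~a].mean()))


def _check_positivity(e_hat: np.ndarray) -> None:
    if ((e_hat <= 0) | (e_hat >= 1)).any():
        raise PositivityError(
            "propensity estimates at 0 or 1: clip them before weighting"
        )


def estimate_ipw(
    predictions: NuisancePredictions, arm: np.ndarray, outcome: np.ndarray
) -> EffectEstimate:
    """Hajek (self-normalised) IPW risk difference.

    Arm means are weighted averages sum(w*Y)/sum(w) with w = A/e and
    (1-A)/(1-e); self-normalisation keeps the estimate inside [-1, 1].
    """
    e = predictions.e_hat
    _check_positivity(e)
    a = np.asarray(arm, dtype=float)
    y = np.asarray(outcome, dtype=float)
    w1 = a / e
    w0 = (1 - a) / (1 - e)
    if w1.sum() == 0 or w0.sum() == 0:
        raise ValueError("IPW needs both arms populated")
    y1_mean = float((w1 * y).sum() / w1.sum())
    y0_mean = float((w0 * y).sum() / w0.sum())
    return _estimate_from_means("IPW", y1_mean, y0_mean)


def estimate_gformula_t(predictions: NuisancePredictions) -> EffectEstimate:
    """G-formula with a T-learner: mean counterfactual prediction gap."""
    y1_mean = float(predictions.mu1.mean())
    y0_mean = float(predictions.mu0.mean())
    return _estimate_from_means("Gformula_T", y1_mean, y0_mean)


def estimate_aipw(
    predictions: NuisancePredictions, arm: np.ndarray, outcome: np.ndarray
) -> EffectEstimate:
    """Doubly robust AIPW estimate; keeps per-patient pseudo-outcomes.

    psi_i = mu1 - mu0 + A(Y - mu1)/e - (1 - A)(Y - mu0)/(1 - e);
    the ATE estimate is mean(psi).  The two augmented arm means are
    retained so ratio estimands remain derivable.
    """
    e = predictions.e_hat
    _check_positivity(e)
    a = np.asarray(arm, dtype=float)
    y = np.asarray(outcome, dtype=float)
    mu1, mu0 = predictions.mu1, predictions.mu0
    term1 = mu1 + a * (y - mu1) / e
    term0 = mu0 + (1 - a) * (y - mu0) / (1 - e)
    psi = term1 - term0
    est = _estimate_from_means("AIPW", float(term1.mean()), float(term0.mean()))
    est.psi = psi
    return est


def estimate_dml(
    X: np.ndarray,
    arm: np.ndarray,
    outcome: np.ndarray,
    spec: NuisanceSpec | None = None,
    k_folds: int = 5,
    clip: float = 0.01,
    seed: int = 0,
) -> EffectEstimate:
    """Partially linear double machine learning.

    Cross-fits a marginal outcome regression m(X) = E[Y|X] and the
    propensity e(X), then regresses the outcome residuals on the
    treatment residuals; the slope is the constant-effect risk
    difference analogue.  Arm-specific means are not identified by this
    model, so only the risk difference is reported.
    """
    spec = spec or NuisanceSpec()
    spec.validate()
    if k_folds < 2:
        raise ValueError("cross-fitting requires k_folds >= 2")
    X = np.asarray(X, dtype=float)
    a = np.asarray(arm, dtype=int)
    y = np.asarray(outcome, dtype=int)
    n = len(a)

    e_hat = np.full(n, np.nan)
    m_hat = np.full(n, np.nan)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for k, (train, test) in enumerate(skf.split(X, a)):
        prop = _make_model(spec, X[train], a[train], seed=seed * 1000 + k)
        e_hat[test] = _predict_prob(prop, X[test])
        m = _fit_outcome(spec, X[train], y[train], seed * 1000 + 300 + k)
        m_hat[test] = m(X[test])
    e_hat = np.clip(e_hat, clip, 1 - clip)

    a_res = a - e_hat
    y_res = y - m_hat
    denom = float((a_res**2).sum())
    if denom < 1e-8 * n:
        raise ValueError(
            "treatment residuals have near-zero variance: no effective overlap, "
            "the partially linear model is ill-posed"
        )
    slope = float((a_res * y_res).sum() / denom)
    return EffectEstimate(
        estimator="DML",
        point=slope,
        arm_means=None,
        estimand_values={"risk_difference": slope},
    )


def misspecified_predictions(
    predictions: NuisancePredictions,
    arm: np.ndarray,
    outcome: np.ndarray,
    which: str,
) -> NuisancePredictions:
    """Deliberately degrade one nuisance, for double-robustness checks.

    ``constant_outcome`` replaces the outcome regressions with arm-wise
    intercepts (the T-learner collapsed to per-arm means);
    ``constant_propensity`` replaces the propensity with the marginal
    treated fraction.  The other nuisance is left untouched.
    """
    a = np.asarray(arm, dtype=bool)
    y = np.asarray(outcome, dtype=float)
    n = len(a)
    if which == "constant_outcome":
        return NuisancePredictions(
            predictions.e_hat,
            np.full(n, float(y[a].mean())),
            np.full(n, float(y[~a].mean())),
            predictions.folds,
            predictions.clip_bounds,
            predictions.n_clipped,
        )
    if which == "constant_propensity":
        return NuisancePredictions(
            np.full(n, float(a.mean())),
            predictions.mu1,
            predictions.mu0,
            predictions.folds,
            predictions.clip_bounds,
            0,
        )
    raise ValueError(
        f"which must be 'constant_outcome' or 'constant_propensity', got {which!r}"
    )


@dataclass
class BootstrapResult:
    lower: float
    upper: float
    level: float
    n_requested: int
    n_effective: int
    n_dropped: int
    estimates: np.ndarray


def bootstrap_ci(
    estimator_fn: Callable[[np.ndarray], float],
    n: int,
    B: int = 50,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap over patient-level resamples.

    ``estimator_fn`` receives an index array of length n (a resample
    with replacement) and must rerun the full estimation pipeline —
    nuisance refits included — returning the point estimate.  Replicates
    that fail because the resample degenerates (e.g. a single arm) are
    dropped and counted; more than 20% dropped raises.

    The default B=50 is small; intervals are noticeably noisy below
    B~200, so raise it when runtime allows.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    estimates = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            estimates.append(float(estimator_fn(idx)))
        except (ValueError, PositivityError):
            dropped += 1
    if dropped > 0.2 * B:
        raise RuntimeError(
            f"{dropped}/{B} bootstrap replicates degenerated; the sample is too "
            "small or imbalanced for patient-level resampling"
        )
    est = np.asarray(estimates)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(est, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapResult(float(lower), float(upper), level, B, len(est), dropped, est)


def overlap_diagnostic(
    predictions: NuisancePredictions, arm: np.ndarray, n_bins: int = 20
) -> dict:
    """Propensity overlap report: per-arm histograms, ranges, clipping.

    The overlap of e(X) between arms is the only causal assumption
    testable from data; the flag trips when a non-trivial share of
    estimates sit at the clipping bounds.
    """
    a = np.asarray(arm, dtype=bool)
    e = predictions.e_hat
    lo, hi = predictions.clip_bounds
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist_treated, _ = np.histogram(e[a], bins=edges)
    hist_control, _ = np.histogram(e[~a], bins=edges)
    clipped_frac = predictions.n_clipped / len(e)
    report = {
        "bin_edges": edges,
        "hist_treated": hist_treated,
        "hist_control": hist_control,
        "range_treated": (float(e[a].min()), float(e[a].max())) if a.any() else None,
        "range_control": (float(e[~a].min()), float(e[~a].max())) if (~a).any() else None,
        "clip_bounds": (lo, hi),
        "n_clipped": predictions.n_clipped,
        "clipped_fraction": clipped_frac,
        "flag": bool(clipped_frac > 0.01),
    }
    return report
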