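"""End-to-end estimation: tables -> cohort -> features -> effect estimate.

This is the path the vibration module sweeps and the examples call; it
wires the modules together without adding statistical content.  The
bootstrap resamples patients from the analysis feature matrix and
refits the nuisances on every resample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, CohortSpec, build_cohort
from .estimators import (
    EffectEstimate,
    NuisanceSpec,
    bootstrap_ci,
    estimate_aipw,
    estimate_dml,
    estimate_gformula_t,
    estimate_ipw,
    fit_nuisances,
    naive_contrast,
)
from .features import FeatureMatrix, confounder_subset
from .sim import EventTables

__all__ = ["AnalysisConfig", "estimate_effect", "estimate_from_features"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analytic choices downstream of the cohort specification."""

    aggregation: str = "last"
    estimator: str = "AIPW"
    nuisance: NuisanceSpec = NuisanceSpec()
    confounder_set: str = "full"
    k_folds: int = 5
    clip: float = 0.01
    n_bootstrap: int = 0
    ci_level: float = 0.95
    seed: int = 0
    #: re-fit imputation medians inside every bootstrap resample (strict
    #: resampling inference; default reuses the analysis-matrix medians)
    refit_imputation_per_resample: bool = False


def estimate_from_features(
    features: FeatureMatrix,
    arm: np.ndarray,
    outcome: np.ndarray,
    config: AnalysisConfig,
    raw_features: FeatureMatrix | None = None,
) -> EffectEstimate:
    """Run one estimator on a ready feature matrix, with optional bootstrap.

    ``raw_features`` (pre-imputation) is only needed when
    ``config.refit_imputation_per_resample`` is set, in which case every
    bootstrap resample re-computes its own imputation medians.
    """
    from .features import impute_encode

    X = features.data.to_numpy(dtype=float)
    a = np.asarray(arm, dtype=int)
    y = np.asarray(outcome, dtype=int)
    if config.refit_imputation_per_resample and raw_features is None:
        raise ValueError(
            "refit_imputation_per_resample requires the pre-imputation matrix"
        )

    def point(idx: np.ndarray | None = None) -> EffectEstimate:
        if idx is not None and config.refit_imputation_per_resample:
            resampled = raw_features.data.iloc[idx]
            re_fm = impute_encode(
                FeatureMatrix(
                    resampled,
                    dict(raw_features.roles),
                    dict(raw_features.groups),
                    raw_features.strategy,
                )
            )
            # align to the analysis matrix columns (a resample can drop a
            # rare one-hot level)
            Xs = re_fm.data.reindex(columns=features.data.columns, fill_value=0.0)
            Xs, as_, ys = Xs.to_numpy(dtype=float), a[idx], y[idx]
        else:
            Xs, as_, ys = (X, a, y) if idx is None else (X[idx], a[idx], y[idx])
        name = config.estimator.upper() if config.estimator.lower() != "gformula_t" else "Gformula_T"
        if name == "NAIVE":
            return naive_contrast(as_, ys)
        if name == "DML":
            return estimate_dml(
                Xs, as_, ys, config.nuisance, config.k_folds, config.clip, config.seed
            )
        preds = fit_nuisances(
            Xs, as_, ys, config.nuisance, None, config.k_folds, config.clip, config.seed
        )
        if name == "IPW":
            return estimate_ipw(preds, as_, ys)
        if name == "GFORMULA_T" or name == "Gformula_T":
            return estimate_gformula_t(preds)
        if name == "AIPW":
            return estimate_aipw(preds, as_, ys)
        raise ValueError(f"unknown estimator {config.estimator!r}")

    est = point()
    est.provenance.update(
        {
            "aggregation": features.strategy,
            "confounder_set": config.confounder_set,
            "nuisance_family": config.nuisance.family,
            "k_folds": config.k_folds,
            "clip": config.clip,
            "seed": config.seed,
        }
    )
    if config.n_bootstrap:
        boot = bootstrap_ci(
            lambda idx: point(idx).point,
            n=len(a),
            B=config.n_bootstrap,
            level=config.ci_level,
            seed=config.seed,
        )
        est = est.with_ci(boot.lower, boot.upper, config.ci_level, boot.n_effective)
        est.provenance["bootstrap_dropped"] = boot.n_dropped
    return est


def estimate_effect(
    tables: EventTables,
    cohort_spec: CohortSpec,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[EffectEstimate, Cohort]:
    """Full pipeline from raw tables to an effect estimate."""
    from .features import aggregate, impute_encode

    cohort, _ = build_cohort(tables, cohort_spec)
    raw = aggregate(cohort, tables, strategy=config.aggregation)
    features = impute_encode(raw)
    if config.confounder_set != "full":
        features = confounder_subset(features, config.confounder_set)
        raw = confounder_subset(raw, config.confounder_set)
    est = estimate_from_features(
        features,
        cohort.table["treated"].to_numpy(),
        cohort.table["outcome"].to_numpy(),
        config,
        raw_features=raw,
    )
    est.provenance["eligibility_window_h"] = cohort_spec.eligibility_window_h
    est.provenance["n"] = cohort.n
    est.provenance["n_treated"] = cohort.n_treated
    return est, cohort
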