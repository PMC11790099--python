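"""Patient-level feature construction from time-stamped events.

Collapses each patient's pre-baseline measurement history to one row
under a chosen aggregation strategy (first / last / first_and_last /
mean value before the cutoff), adds static covariates and pre-baseline
drug-exposure indicators, then median-imputes numerics and one-hot
encodes categoricals.  The cutoff defaults to the follow-up start t0,
so nothing measured at or after baseline can leak into the matrix.

Each column carries a causal role tag (confounder / effect_modifier /
post_treatment / instrumental) and a provenance group (sociodemographic
/ severity / labs / drugs) used by the vibration module to form
confounder subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np
import pandas as pd

from .cohort import Cohort
from .sim import EventTables

__all__ = [
    "FeatureMatrix",
    "aggregate",
    "impute_encode",
    "build_features",
    "confounder_subset",
    "AGGREGATION_STRATEGIES",
    "CONFOUNDER_SETS",
]

AGGREGATION_STRATEGIES = ("first", "last", "first_and_last", "mean")

#: named confounder subsets -> provenance groups retained
CONFOUNDER_SETS = {
    "full": ("sociodemographic", "severity", "labs", "drugs"),
    "no_drugs": ("sociodemographic", "severity", "labs"),
    "no_biology": ("sociodemographic", "drugs"),
    "sociodemographic_only": ("sociodemographic",),
}

ROLES = ("confounder", "effect_modifier", "post_treatment", "instrumental")

_DRUG_CLASSES = (
    "vasopressor",
    "ventilation",
    "beta_lactam",
    "carbapenem",
    "glycopeptide",
    "aminoglycoside",
)


@dataclass
class FeatureMatrix:
    """One row per cohort patient; metadata travels with the values.

    Attributes
    ----------
    data:
        DataFrame indexed by patient_id.
    roles:
        column -> causal role tag.
    groups:
        column -> provenance group (used for confounder subsets).
    strategy:
        aggregation strategy label.
    medians:
        imputation medians recorded by :func:`impute_encode` (None
        before imputation).
    """

    data: pd.DataFrame
    roles: dict[str, str]
    groups: dict[str, str]
    strategy: str
    medians: dict[str, float] | None = None

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    def validate(self) -> None:
        for col, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for column {col!r}")
        missing = set(self.data.columns) - set(self.roles)
        if missing:
            raise ValueError(f"columns without a role tag: {sorted(missing)}")

    def to_csv(self, path, sidecar_path=None) -> None:
        self.data.to_csv(path)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "strategy": self.strategy,
                        "roles": self.roles,
                        "groups": self.groups,
                        "medians": self.medians,
                    },
                    fh,
                    indent=1,
                )

    @classmethod
    def from_csv(cls, path, sidecar_path) -> "FeatureMatrix":
        data = pd.read_csv(path, index_col="patient_id")
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(data, meta["roles"], meta["groups"], meta["strategy"], meta["medians"])


def aggregate(
    cohort: Cohort,
    tables: EventTables,
    strategy: str = "last",
    cutoff: str = "t0",
) -> FeatureMatrix:
    """Aggregate pre-cutoff measurements and assemble the raw feature matrix.

    Parameters
    ----------
    strategy:
        ``first`` / ``last`` / ``first_and_last`` / ``mean`` value of
        each measured variable before the cutoff.  ``first_and_last``
        emits two columns per variable.
    cutoff:
        ``"t0"`` (follow-up start; default) or ``"treatment"`` — the
        latter uses each treated patient's own treatment time and is
        only there for leakage-sensitivity experiments.

    Variables never observed before the cutoff are left missing for
    :func:`impute_encode` to fill.
    """
    if strategy not in AGGREGATION_STRATEGIES:
        raise ValueError(
            f"unknown aggregation strategy {strategy!r}; "
            f"valid options: {list(AGGREGATION_STRATEGIES)}"
        )
    if cutoff not in ("t0", "treatment"):
        raise ValueError(f"cutoff must be 't0' or 'treatment', got {cutoff!r}")

    ctab = cohort.table
    idx = pd.Index(ctab["patient_id"], name="patient_id")
    cut = ctab["t0_h"].copy()
    if cutoff == "treatment":
        cut = ctab["treatment_time_h"].fillna(ctab["t0_h"])
    cut.index = idx

    meas = tables.measurements.merge(
        pd.DataFrame({"patient_id": idx, "_cut": cut.to_numpy()}), on="patient_id", how="inner"
    )
    meas = meas[meas["time_h"] < meas["_cut"]]
    # stable sort: ties at identical timestamps break by input record order
    meas = meas.sort_values(["patient_id", "variable", "time_h"], kind="stable")

    grouped = meas.groupby(["patient_id", "variable"])["value"]
    pieces: dict[str, pd.Series] = {}
    if strategy in ("first", "first_and_last"):
        firsts = grouped.first().unstack("variable")
        for var in firsts.columns:
            pieces[f"{var}_first"] = firsts[var]
    if strategy in ("last", "first_and_last"):
        lasts = grouped.last().unstack("variable")
        for var in lasts.columns:
            pieces[f"{var}_last"] = lasts[var]
    if strategy == "mean":
        means = grouped.mean().unstack("variable")
        for var in means.columns:
            pieces[f"{var}_mean"] = means[var]

    data = pd.DataFrame(index=idx)
    groups: dict[str, str] = {}
    roles: dict[str, str] = {}
    for name, series in pieces.items():
        data[name] = series.reindex(idx)
        var = name.rsplit("_", 1)[0]
        groups[name] = "severity" if var == "sofa" else "labs"
        roles[name] = "confounder"

    # static covariates
    static = ctab.set_index("patient_id")
    for col, grp in [
        ("age", "sociodemographic"),
        ("sex", "sociodemographic"),
        ("race", "sociodemographic"),
        ("emergency_admission", "sociodemographic"),
        ("septic_shock", "severity"),
    ]:
        data[col] = static[col]
        groups[col] = grp
        roles[col] = "confounder"

    # pre-cutoff drug exposure indicators
    iv = tables.interventions.merge(
        pd.DataFrame({"patient_id": idx, "_cut": cut.to_numpy()}), on="patient_id", how="inner"
    )
    iv = iv[iv["time_h"] < iv["_cut"]]
    present = set(tables.interventions["intervention"].unique()) & set(_DRUG_CLASSES)
    for cls in sorted(present):
        got = iv.loc[iv["intervention"] == cls, "patient_id"].unique()
        col = f"drug_{cls}"
        data[col] = np.isin(idx, got).astype(float)
        groups[col] = "drugs"
        roles[col] = "confounder"

    fm = FeatureMatrix(data, roles, groups, strategy)
    fm.validate()
    return fm


def impute_encode(matrix: FeatureMatrix) -> FeatureMatrix:
    """Median-impute numerics, one-hot encode categoricals.

    Medians are computed on the matrix itself and recorded for reuse on
    resamples; one-hot encoding drops the reference level so ridge
    models stay full-rank.  A numeric column with no observed values
    cannot be imputed and raises.
    """
    data = matrix.data.copy()
    roles = dict(matrix.roles)
    groups = dict(matrix.groups)
    medians: dict[str, float] = {}

    for col in list(data.columns):
        if data[col].dtype == object or isinstance(data[col].dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(data[col], prefix=col, drop_first=True, dtype=float)
            for dcol in dummies.columns:
                data[dcol] = dummies[dcol]
                roles[dcol] = roles[col]
                groups[dcol] = groups[col]
            data = data.drop(columns=[col])
            roles.pop(col)
            groups.pop(col)
        else:
            if data[col].isna().all():
                raise ValueError(
                    f"column {col!r} has no observed values and cannot be median-imputed"
                )
            if data[col].isna().any():
                med = float(data[col].median())
                data[col] = data[col].fillna(med)
                medians[col] = med
            data[col] = data[col].astype(float)

    out = FeatureMatrix(data, roles, groups, matrix.strategy, medians)
    out.validate()
    return out


def build_features(
    cohort: Cohort,
    tables: EventTables,
    strategy: str = "last",
    cutoff: str = "t0",
) -> FeatureMatrix:
    """Convenience: aggregate then impute/encode."""
    return impute_encode(aggregate(cohort, tables, strategy=strategy, cutoff=cutoff))


def confounder_subset(matrix: FeatureMatrix, subset: str) -> FeatureMatrix:
    """Restrict the matrix to a named confounder set (vibration axis)."""
    if subset not in CONFOUNDER_SETS:
        raise ValueError(
            f"unknown confounder set {subset!r}; valid options: {sorted(CONFOUNDER_SETS)}"
        )
    keep_groups = CONFOUNDER_SETS[subset]
    cols = [c for c in matrix.data.columns if matrix.groups[c] in keep_groups]
    return FeatureMatrix(
        matrix.data[cols].copy(),
        {c: matrix.roles[c] for c in cols},
        {c: matrix.groups[c] for c in cols},
        matrix.strategy,
        matrix.medians,
    )
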