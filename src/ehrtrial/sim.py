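"""Synthetic longitudinal ICU data with known causal ground truth.

Generates event tables shaped like a sepsis resuscitation-fluid cohort
(static demographics, repeated severity/lab measurements, drug
administrations, death/censoring times) together with each patient's
potential-outcome probabilities, so that analysis pipelines can be
checked against a known average treatment effect and known sources of
bias (severity confounding, immortal time, effect modification).

Model summary
-------------
A latent severity score ``z ~ N(0, 1)`` drives a SOFA-like score
(mean 6, SD 3.5, integers 0-24, re-measured with noise), a lactate
correlate, the odds of being treated (albumin on top of crystalloids)
and the odds of 28-day death.  Treatment is *intended* with probability
``e(X)`` (logistic in severity, emergency admission and septic shock,
intercept calibrated to the target treated fraction) and *realised*
only if the patient's latent untreated death time exceeds the drawn
treatment delay — the coupling that makes immortal-time bias
reproducible by design.  Potential outcomes are parameterised on the
risk-difference scale: ``p1 = clip(p0 + ATE + modifier terms)``.

Deaths that do occur are timed with a truncated log-normal
conditional-on-death distribution (median ~2.5 days), matching the
front-loaded mortality of ICU sepsis; the marginal 28-day death
probability always equals the assigned arm's potential-outcome
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtr, ndtri

__all__ = [
    "SimConfig",
    "EventTables",
    "GroundTruth",
    "simulate",
    "true_effects",
    "write_tables",
    "read_tables",
]

HOURS_PER_DAY = 24.0

#: modifier keys accepted in SimConfig.modifier_effects
MODIFIER_KEYS = ("age_ge_60", "male", "septic_shock")

#: intervention classes emitted by the simulator
INTERVENTION_CLASSES = (
    "crystalloid",
    "albumin",
    "vasopressor",
    "ventilation",
    "beta_lactam",
    "carbapenem",
    "glycopeptide",
    "aminoglycoside",
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Parameters
    ----------
    n_patients:
        Number of simulated ICU stays.
    seed:
        Seed fixing the whole output bit-for-bit.
    treated_fraction_target:
        Marginal intended-treatment probability; the propensity
        intercept is calibrated so the mean of e(X) equals this.
    baseline_mortality_28d:
        Marginal untreated 28-day mortality; the outcome intercept is
        calibrated likewise.
    true_ate_rd:
        Population risk difference added to every patient's p0 (before
        modifier terms); 0 gives an exact per-patient null.
    modifier_effects:
        Signed risk-difference increments keyed by ``age_ge_60``,
        ``male``, ``septic_shock``; added to p1 for members.
    confounding_strength:
        Log-odds coefficient of latent severity on treatment.
    severity_mortality_coef:
        Log-odds coefficient of latent severity on death.
    measurement_rate_per_hour:
        Poisson rate of repeat measurements per variable (an
        admission-time reading at t=0 is always attempted as well).
    missing_rate:
        Probability that any individual measurement row is dropped
        (completely at random).
    followup_anchor_window_h:
        First crystalloid administration (the follow-up anchor) is
        drawn uniformly in (0.5, this] hours from admission.
    treatment_delay_max_h:
        Albumin delay after the anchor is Uniform[0, this] hours.
    death_time_log_mean, death_time_log_sd:
        Parameters of the log-normal conditional death-time
        distribution (hours from follow-up start), truncated at the
        outcome horizon.
    outcome_horizon_d:
        Horizon in days for the mortality outcome (28 by default).
    anchor_presence_rate:
        Fraction of patients who receive crystalloids at all; the rest
        have no anchor event and are excluded by cohort building.
    """

    n_patients: int = 10_000
    seed: int = 0
    treated_fraction_target: float = 0.19
    baseline_mortality_28d: float = 0.28
    true_ate_rd: float = 0.0
    modifier_effects: Mapping[str, float] = field(default_factory=dict)
    confounding_strength: float = 0.5
    severity_mortality_coef: float = 1.0
    measurement_rate_per_hour: float = 0.15
    missing_rate: float = 0.25
    followup_anchor_window_h: float = 6.0
    treatment_delay_max_h: float = 24.0
    death_time_log_mean: float = 3.9
    death_time_log_sd: float = 0.6
    outcome_horizon_d: float = 28.0
    anchor_presence_rate: float = 0.97

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "treated_fraction_target",
            "baseline_mortality_28d",
            "missing_rate",
            "anchor_presence_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.treated_fraction_target < 1.0:
            raise ValueError(
                "treated_fraction_target must be in (0, 1), got "
                f"{self.treated_fraction_target}"
            )
        for name in (
            "measurement_rate_per_hour",
            "followup_anchor_window_h",
            "treatment_delay_max_h",
            "outcome_horizon_d",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        unknown = set(self.modifier_effects) - set(MODIFIER_KEYS)
        if unknown:
            raise ValueError(
                f"unknown modifier_effects keys {sorted(unknown)}; "
                f"valid keys are {list(MODIFIER_KEYS)}"
            )


@dataclass
class EventTables:
    """The four raw longitudinal tables handed to analysis code."""

    static: pd.DataFrame
    measurements: pd.DataFrame
    interventions: pd.DataFrame
    outcomes: pd.DataFrame

    def validate(self) -> None:
        ids = set(self.static["patient_id"])
        for name in ("measurements", "interventions", "outcomes"):
            tab = getattr(self, name)
            extra = set(tab["patient_id"]) - ids
            if extra:
                raise ValueError(f"{name} has patient ids missing from static: {sorted(extra)[:5]}")
        if (self.measurements["time_h"] < 0).any() or (self.interventions["time_h"] < 0).any():
            raise ValueError("event times must be non-negative")
        death = self.outcomes.set_index("patient_id")["death_time_h"]
        for name in ("measurements", "interventions"):
            tab = getattr(self, name)
            dt = tab["patient_id"].map(death)
            # events and death times are rounded to 0.01 h on output
            if (tab["time_h"] > dt.fillna(np.inf) + 0.01).any():
                raise ValueError(f"{name} contains events after the patient's death time")


@dataclass
class GroundTruth:
    """Per-patient causal truth, kept out of the analysis path.

    ``table`` has one row per patient: true propensity ``e``, potential
    outcome probabilities ``p0``/``p1``, individual effect
    ``tau = p1 - p0``, the potential outcomes actually drawn (``y0``,
    ``y1``), intended/realised treatment and the latent severity score.
    """

    table: pd.DataFrame

    @property
    def ate(self) -> float:
        """Sample average treatment effect, mean of tau."""
        return float(self.table["tau"].mean())


def _calibrate_intercept(offsets: np.ndarray, target: float) -> float:
    """Intercept b such that mean(expit(b + offsets)) == target."""

    def f(b: float) -> float:
        return float(expit(b + offsets).mean() - target)

    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _truncated_lognormal_quantile(
    q: np.ndarray, mu: float, sigma: float, upper: float, lower: np.ndarray | float = 0.0
) -> np.ndarray:
    """Quantile of a log-normal truncated to (lower, upper]."""
    lo = np.asarray(lower, dtype=float)
    g_lo = np.where(lo > 0, ndtr((np.log(np.maximum(lo, 1e-300)) - mu) / sigma), 0.0)
    g_hi = ndtr((np.log(upper) - mu) / sigma)
    p = g_lo + q * (g_hi - g_lo)
    return np.exp(mu + sigma * ndtri(np.clip(p, 1e-12, 1 - 1e-12)))


def simulate(config: SimConfig) -> tuple[EventTables, GroundTruth]:
    """Generate event tables and the matching causal ground truth.

    Returns
    -------
    (EventTables, GroundTruth)
        The tables contain only what a real extract would; everything
        counterfactual lives in the GroundTruth side table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    horizon_h = config.outcome_horizon_d * HOURS_PER_DAY

    # --- static covariates -------------------------------------------------
    age = np.clip(rng.normal(66.0, 16.0, n), 16.0, 100.0)
    male = rng.random(n) < 0.585
    race = rng.choice(
        np.array(["white", "black", "hispanic", "other"]),
        size=n,
        p=[0.67, 0.15, 0.08, 0.10],
    )
    emergency = rng.random(n) < 0.52
    septic_shock = rng.random(n) < 0.35
    weight = np.clip(rng.normal(82.0, 18.0, n), 40.0, 160.0)

    # Latent severity: independent of septic shock by construction, so that
    # shock carries its own direct effects and severity exchangeability under
    # confounding_strength=0 holds exactly for the SOFA-like score.
    z = rng.standard_normal(n)
    sofa_true = np.clip(np.round(6.0 + 3.5 * z), 0, 24)
    # the admission SOFA actually charted (and later emitted as the t=0
    # measurement row): clinicians act on this recorded value, so treatment
    # assignment below conditions on it, keeping ignorability given the
    # tables exact while severity still confounds through the latent z
    sofa_admission = np.clip(np.round(sofa_true + rng.normal(0.0, 1.0, n)), 0, 24)
    z_age = (age - 66.0) / 16.0

    # --- potential outcomes -------------------------------------------------
    out_offset = (
        config.severity_mortality_coef * z
        + 0.4 * z_age
        + 0.3 * emergency
        + 0.5 * septic_shock
    )
    b0 = _calibrate_intercept(out_offset, config.baseline_mortality_28d)
    p0 = expit(b0 + out_offset)

    # --- treatment propensity (intended) -----------------------------------
    # Realised treatment requires an anchor event and survival up to the
    # drawn delay, so the intended-treatment intercept is calibrated against
    # the expected *realised* fraction: E[e(X) * anchor * (1 - p0 * Gbar)],
    # with Gbar the mean pre-delay death probability share.
    prop_offset = (
        config.confounding_strength * (sofa_admission - 6.0) / 3.5
        - 1.1 * emergency
        + 0.8 * septic_shock
    )
    mu, sigma = config.death_time_log_mean, config.death_time_log_sd
    horizon_norm = ndtr((np.log(horizon_h) - mu) / sigma)
    dmax = max(config.treatment_delay_max_h, 1e-9)
    grid_t = np.linspace(0.0, dmax, 65)[1:]
    gbar = float(
        np.mean(ndtr((np.log(grid_t) - mu) / sigma)) / horizon_norm
    )  # E_D[G(D)] for D ~ U[0, dmax]
    realised_factor = config.anchor_presence_rate * (1.0 - p0 * gbar)

    def realised_fraction(b: float) -> float:
        return float((expit(b + prop_offset) * realised_factor).mean())

    a0 = brentq(
        lambda b: realised_fraction(b) - config.treated_fraction_target, -30.0, 30.0
    )
    e_true = expit(a0 + prop_offset)
    mods = dict(config.modifier_effects)
    modifier_term = (
        mods.get("age_ge_60", 0.0) * (age >= 60.0)
        + mods.get("male", 0.0) * male
        + mods.get("septic_shock", 0.0) * septic_shock
    )
    if config.true_ate_rd == 0.0 and not any(mods.values()):
        p1 = p0.copy()  # exact per-patient null, no clipping artefacts
    else:
        p1 = np.clip(p0 + config.true_ate_rd + modifier_term, 0.001, 0.999)
    tau = p1 - p0

    # Shared uniform couples the two potential outcomes per patient.
    u = rng.random(n)
    y0 = u < p0
    y1 = u < p1
    v = rng.random(n)  # death-time quantile

    # --- timing and treatment realisation ----------------------------------
    t_anchor = rng.uniform(0.5, max(config.followup_anchor_window_h, 0.5), n)
    delay = rng.uniform(0.0, config.treatment_delay_max_h, n)
    has_anchor = rng.random(n) < config.anchor_presence_rate
    intended = rng.random(n) < e_true

    mu, sigma = config.death_time_log_mean, config.death_time_log_sd
    # latent untreated death time (hours after the anchor), inf for survivors
    t_death0 = np.where(
        y0, _truncated_lognormal_quantile(v, mu, sigma, horizon_h), np.inf
    )
    # treated only if intended, anchored, and still alive at the drawn delay
    treated = intended & has_anchor & (t_death0 > delay)

    y = np.where(treated, y1, y0).astype(bool)
    # realised death time: controls keep the latent time; treated deaths are
    # redrawn conditional on exceeding the treatment delay so event ordering
    # stays consistent (treatment always precedes death).
    t_death_treated = _truncated_lognormal_quantile(v, mu, sigma, horizon_h, lower=delay)
    death_delay = np.where(treated, t_death_treated, t_death0)
    death_delay = np.where(y, death_delay, np.inf)

    death_time = t_anchor + death_delay  # hours from admission
    last_seen = np.where(np.isfinite(death_time), death_time, t_anchor + horizon_h)

    patient_id = np.arange(n)
    static = pd.DataFrame(
        {
            "patient_id": patient_id,
            "age": np.round(age, 1),
            "sex": np.where(male, "M", "F"),
            "race": race,
            "emergency_admission": emergency.astype(int),
            "septic_shock": septic_shock.astype(int),
            "admission_time_h": 0.0,
        }
    )

    outcomes = pd.DataFrame(
        {
            "patient_id": patient_id,
            "death_time_h": np.where(np.isfinite(death_time), np.round(death_time, 2), np.nan),
            "last_seen_h": np.round(last_seen, 2),
        }
    )

    interventions = _simulate_interventions(
        rng, patient_id, z, t_anchor, delay, has_anchor, treated, last_seen
    )
    measurements = _simulate_measurements(
        rng, config, patient_id, sofa_true, sofa_admission, z, weight, last_seen
    )

    tables = EventTables(static, measurements, interventions, outcomes)

    gt = pd.DataFrame(
        {
            "patient_id": patient_id,
            "propensity": e_true,
            "p0": p0,
            "p1": p1,
            "tau": tau,
            "y0": y0.astype(int),
            "y1": y1.astype(int),
            "intended_treatment": intended.astype(int),
            "treated": treated.astype(int),
            "latent_severity": z,
            "treatment_delay_h": delay,
            "latent_death_h": t_death0,  # untreated death delay from anchor, inf = survives
        }
    )
    return tables, GroundTruth(gt)


def _simulate_interventions(rng, patient_id, z, t_anchor, delay, has_anchor, treated, last_seen):
    n = len(patient_id)
    rows: list[pd.DataFrame] = []

    def add(mask: np.ndarray, cls: str, times: np.ndarray) -> None:
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[mask],
                    "time_h": np.round(times[mask], 2),
                    "intervention": cls,
                }
            )
        )

    add(has_anchor, "crystalloid", t_anchor)
    add(treated, "albumin", t_anchor + delay)

    # supportive care and antibiotics, administered before the anchor (ED /
    # early ICU) so they are usable pre-baseline features
    early = rng.uniform(0.0, 1.0, n) * np.maximum(t_anchor - 0.1, 0.1)
    for cls, logit_p in [
        ("vasopressor", -0.4 + 0.8 * z),
        ("ventilation", 1.2 + 0.3 * z),
    ]:
        given = rng.random(n) < expit(logit_p)
        add(given & (early < last_seen), cls, early)
    for cls, p in [
        ("beta_lactam", 0.31),
        ("carbapenem", 0.04),
        ("glycopeptide", 0.52),
        ("aminoglycoside", 0.02),
    ]:
        given = rng.random(n) < p
        t = rng.uniform(0.0, 1.0, n) * np.maximum(t_anchor - 0.1, 0.1)
        add(given & (t < last_seen), cls, t)

    out = pd.concat(rows, ignore_index=True)
    out = out.sort_values(["patient_id", "time_h", "intervention"], kind="stable")
    return out.reset_index(drop=True)


def _simulate_measurements(rng, config, patient_id, sofa_true, sofa_admission, z, weight, last_seen):
    n = len(patient_id)
    obs_window = np.minimum(last_seen, 72.0)

    frames: list[pd.DataFrame] = []
    for var in ("sofa", "lactate", "weight"):
        counts = rng.poisson(config.measurement_rate_per_hour * obs_window)
        total = int(counts.sum())
        pid = np.concatenate([np.repeat(patient_id, counts), patient_id])
        times = np.concatenate(
            [rng.random(total) * np.repeat(obs_window, counts), np.zeros(n)]
        )
        idx = pid  # patient index == patient_id here
        if var == "sofa":
            vals = np.clip(np.round(sofa_true[idx] + rng.normal(0.0, 1.0, len(idx))), 0, 24)
            vals[total:] = sofa_admission  # the charted admission score (t=0 rows)
        elif var == "lactate":
            vals = np.round(np.exp(0.75 + 0.25 * z[idx] + rng.normal(0.0, 0.35, len(idx))), 1)
        else:
            vals = np.round(weight[idx] + rng.normal(0.0, 1.5, len(idx)), 1)
        frame = pd.DataFrame(
            {
                "patient_id": pid,
                "time_h": np.round(times, 2),
                "variable": var,
                "value": vals,
            }
        )
        keep = rng.random(len(frame)) >= config.missing_rate
        if var == "sofa":
            # the severity score is computed, not drawn: the admission
            # value (the trailing block of t=0 rows) is never missing
            keep[total:] = True
        frames.append(frame[keep])
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["patient_id", "time_h", "variable"], kind="stable")
    return out.reset_index(drop=True)


def true_effects(
    ground_truth: GroundTruth,
    subgroup_definitions: Mapping[str, Callable[[pd.DataFrame], pd.Series] | pd.Series | np.ndarray],
    static: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """True subgroup ATEs: the mean of tau over each subgroup's members.

    ``subgroup_definitions`` maps a label to either a boolean mask aligned
    with the ground-truth table or a callable evaluated on the static
    table (which must then be provided).  A whole-population row is always
    included first; empty subgroups are flagged rather than raised.
    """
    gt = ground_truth.table
    rows = [
        {"subgroup": "population", "n": len(gt), "true_ate": float(gt["tau"].mean()), "empty": False}
    ]
    for label, definition in subgroup_definitions.items():
        if callable(definition):
            if static is None:
                raise ValueError("callable subgroup definitions require the static table")
            mask = np.asarray(definition(static.set_index("patient_id").loc[gt["patient_id"]].reset_index()))
        else:
            mask = np.asarray(definition)
        mask = mask.astype(bool)
        if mask.shape[0] != len(gt):
            raise ValueError(f"subgroup '{label}' mask length {mask.shape[0]} != n patients {len(gt)}")
        if not mask.any():
            rows.append({"subgroup": label, "n": 0, "true_ate": np.nan, "empty": True})
        else:
            rows.append(
                {
                    "subgroup": label,
                    "n": int(mask.sum()),
                    "true_ate": float(gt.loc[mask, "tau"].mean()),
                    "empty": False,
                }
            )
    return pd.DataFrame(rows)


# --- on-disk round trip -----------------------------------------------------

_TABLE_NAMES = ("static", "measurements", "interventions", "outcomes")


def write_tables(
    tables: EventTables,
    out_dir,
    ground_truth: GroundTruth | None = None,
    fmt: str = "csv",
) -> None:
    """Write the four event tables; ground truth goes to a separate
    ``ground_truth/`` subdirectory that analysis code never reads."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt not in ("csv", "parquet"):
        raise ValueError(f"fmt must be 'csv' or 'parquet', got {fmt!r}")
    for name in _TABLE_NAMES:
        df = getattr(tables, name)
        if fmt == "csv":
            df.to_csv(out / f"{name}.csv", index=False)
        else:
            df.to_parquet(out / f"{name}.parquet", index=False)
    if ground_truth is not None:
        side = out / "ground_truth"
        side.mkdir(exist_ok=True)
        if fmt == "csv":
            ground_truth.table.to_csv(side / "ground_truth.csv", index=False)
        else:
            ground_truth.table.to_parquet(side / "ground_truth.parquet", index=False)


def read_tables(in_dir, fmt: str = "csv") -> EventTables:
    from pathlib import Path

    p = Path(in_dir)
    loaded = {}
    for name in _TABLE_NAMES:
        if fmt == "csv":
            loaded[name] = pd.read_csv(p / f"{name}.csv")
        else:
            loaded[name] = pd.read_parquet(p / f"{name}.parquet")
    return EventTables(**loaded)
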