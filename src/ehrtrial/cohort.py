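"""PICOT cohort construction from raw event tables.

Turns the longitudinal tables into a patient-level case/control cohort
following an explicit emulated-trial specification: inclusion rules
(age, minimum follow-up, presence of the anchor event), follow-up start
at the first anchor administration, arm labelling by whether the
treatment event occurs inside a half-open eligibility window
``[t0, t0 + W)``, and a binary death-within-horizon outcome.  Every
exclusion is counted in a selection flowchart that telescopes exactly.

The eligibility window is deliberately a free parameter: lengthening it
while treatment initiation can be late reproduces immortal-time bias
(treated patients must survive until treatment), which is the design
flaw this module exists to make demonstrable.  Patients who die inside
the window before receiving treatment stay in the control arm on
purpose; "fixing" that silently would hide the bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .sim import EventTables, HOURS_PER_DAY

__all__ = ["CohortSpec", "Flowchart", "Cohort", "build_cohort", "vary_eligibility_window"]


@dataclass(frozen=True)
class CohortSpec:
    """Machine-readable PICOT specification of the emulated trial."""

    min_age: float = 18.0
    min_followup_h: float = 24.0
    anchor_event: str = "crystalloid"
    treatment_event: str = "albumin"
    eligibility_window_h: float = 24.0
    outcome_horizon_d: float = 28.0
    #: extra exclusion rules: (label, predicate on the static table
    #: returning a boolean keep-mask)
    exclusions: Sequence[tuple[str, Callable[[pd.DataFrame], pd.Series]]] = field(
        default_factory=tuple
    )

    def validate(self) -> None:
        if self.eligibility_window_h <= 0:
            raise ValueError("eligibility_window_h must be > 0")
        if self.outcome_horizon_d <= 0:
            raise ValueError("outcome_horizon_d must be > 0")

    def to_yaml(self, path) -> None:
        payload = {
            k: getattr(self, k)
            for k in (
                "min_age",
                "min_followup_h",
                "anchor_event",
                "treatment_event",
                "eligibility_window_h",
                "outcome_horizon_d",
            )
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass
class Flowchart:
    """Ordered record of selection steps: (label, n before, n excluded, n after)."""

    steps: list[tuple[str, int, int, int]]

    def validate(self) -> None:
        for (label, before, excl, after) in self.steps:
            if before - excl != after:
                raise ValueError(f"flowchart step '{label}' does not telescope")
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if prev[3] != nxt[1]:
                raise ValueError(
                    f"flowchart steps '{prev[0]}' -> '{nxt[0]}' do not chain"
                )

    @property
    def final_n(self) -> int:
        return self.steps[-1][3]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["rule", "n_before", "n_excluded", "n_after"]
        )

    def report(self) -> str:
        lines = ["Selection flowchart"]
        for label, before, excl, after in self.steps:
            lines.append(f"  {label}: {before} -> {after} (excluded {excl})")
        return "\n".join(lines)


@dataclass
class Cohort:
    """Patient-level analysis table: one row per included patient with
    follow-up start ``t0_h``, arm label ``treated``, binary ``outcome``
    (death within the horizon) and the static covariates."""

    table: pd.DataFrame
    spec: CohortSpec

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_treated(self) -> int:
        return int(self.table["treated"].sum())


def build_cohort(tables: EventTables, spec: CohortSpec) -> tuple[Cohort, Flowchart]:
    """Apply the PICOT rules and return the labelled cohort plus flowchart.

    Arm labelling: treated iff the treatment event occurs in
    ``[t0, t0 + eligibility_window_h)`` with t0 the first anchor event.
    Outcome: death within ``outcome_horizon_d`` days of t0; patients
    last seen alive before the horizon count as alive (no censoring
    model).
    """
    spec.validate()
    known_classes = set(tables.interventions["intervention"].unique())
    for what, name in (("anchor_event", spec.anchor_event), ("treatment_event", spec.treatment_event)):
        if name not in known_classes:
            raise ValueError(
                f"{what} {name!r} does not appear in the interventions table "
                f"(known classes: {sorted(known_classes)})"
            )

    static = tables.static.set_index("patient_id")
    steps: list[tuple[str, int, int, int]] = []
    included = static.index.to_numpy()

    def apply_step(label: str, keep_index: np.ndarray) -> None:
        nonlocal included
        before = len(included)
        included = included[np.isin(included, keep_index)]
        steps.append((label, before, before - len(included), len(included)))

    # inclusion: age
    keep = static.index[static["age"] >= spec.min_age].to_numpy()
    apply_step(f"age >= {spec.min_age:g} years", keep)

    # inclusion: anchor event present (defines follow-up start)
    anchors = tables.interventions[tables.interventions["intervention"] == spec.anchor_event]
    t0 = anchors.groupby("patient_id")["time_h"].min()
    apply_step(f"received {spec.anchor_event} (follow-up anchor)", t0.index.to_numpy())

    # inclusion: minimum follow-up after the anchor
    out = tables.outcomes.set_index("patient_id")
    followup = out["last_seen_h"].reindex(t0.index) - t0
    keep = followup.index[followup >= spec.min_followup_h].to_numpy()
    apply_step(f"follow-up >= {spec.min_followup_h:g} h", keep)

    for label, predicate in spec.exclusions:
        sub = static.loc[included]
        keep = sub.index[np.asarray(predicate(sub.reset_index()), dtype=bool)].to_numpy()
        apply_step(label, keep)

    flow = Flowchart(steps)
    flow.validate()

    idx = pd.Index(included, name="patient_id")
    t0_inc = t0.reindex(idx)

    # arm labelling inside the half-open eligibility window
    treat_events = tables.interventions[
        tables.interventions["intervention"] == spec.treatment_event
    ]
    first_treat = treat_events.groupby("patient_id")["time_h"].min().reindex(idx)
    rel = first_treat - t0_inc
    treated = (rel >= 0) & (rel < spec.eligibility_window_h)

    horizon_h = spec.outcome_horizon_d * HOURS_PER_DAY
    death = out["death_time_h"].reindex(idx)
    outcome = (death - t0_inc) <= horizon_h
    outcome &= death.notna()

    table = static.loc[idx].reset_index()
    table["t0_h"] = t0_inc.to_numpy()
    table["treated"] = treated.fillna(False).to_numpy().astype(int)
    table["treatment_time_h"] = first_treat.to_numpy()
    table["outcome"] = outcome.to_numpy().astype(int)
    table["death_time_h"] = death.to_numpy()

    return Cohort(table, spec), flow


def vary_eligibility_window(
    tables: EventTables, spec: CohortSpec, windows_h: Sequence[float]
) -> list[tuple[float, Cohort]]:
    """Rebuild the cohort for each eligibility window, all else fixed."""
    if not windows_h:
        raise ValueError("windows_h must be non-empty")
    if any(w <= 0 for w in windows_h):
        raise ValueError("eligibility windows must be positive")
    from dataclasses import replace

    out = []
    for w in windows_h:
        cohort, _ = build_cohort(tables, replace(spec, eligibility_window_h=float(w)))
        out.append((float(w), cohort))
    return out
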