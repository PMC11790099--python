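"""Conditional average treatment effects from causal pseudo-outcomes.

The DR-learner route: cross-fitted AIPW pseudo-outcomes psi_i (whose
mean is the ATE) are regressed on candidate effect modifiers with a
final ridge (or forest) model; the fitted values are per-patient
effect predictions tau_hat(x) on the risk-difference scale.  T-learner
prediction gaps mu1 - mu0 are accepted as an alternative signal.

Subgroup summaries follow box-plot conventions: median, 25th/75th
percentiles (linear interpolation) and whiskers at 1.5 x IQR clipped
to observed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CATEResult", "estimate_cate", "subgroup_report", "binary_modifiers"]


@dataclass
class CATEResult:
    """Per-patient effect predictions plus the final-model description."""

    tau_hat: np.ndarray
    modifier_names: list[str]
    coefficients: dict[str, float] | None  # None for forest final models
    intercept: float | None
    final_model: str


def binary_modifiers(static: pd.DataFrame, age_cut: float = 60.0) -> pd.DataFrame:
    """The four standard binary patient characteristics.

    Age dichotomised at ``age_cut`` (60 by default), male sex, septic
    shock, and white vs non-white race — all pre-treatment fields.
    """
    return pd.DataFrame(
        {
            "age_ge_60": (static["age"] >= age_cut).astype(float),
            "male": (static["sex"] == "M").astype(float),
            "septic_shock": static["septic_shock"].astype(float),
            "white": (static["race"] == "white").astype(float),
        },
        index=static.index,
    )


def estimate_cate(
    effect_signal: np.ndarray,
    modifiers: pd.DataFrame,
    final_model: str = "ridge",
    roles: dict[str, str] | None = None,
    ridge_alpha: float = 1.0,
    seed: int = 0,
) -> CATEResult:
    """Regress a per-patient causal signal on effect modifiers.

    Parameters
    ----------
    effect_signal:
        AIPW pseudo-outcomes psi (preferred; their conditional mean is
        the CATE) or T-learner prediction gaps, one value per patient.
    modifiers:
        Pre-treatment candidate modifiers, one column each.  Columns
        tagged ``post_treatment`` in ``roles`` are refused outright.
    final_model:
        ``ridge`` (interpretable coefficients, the default) or
        ``forest``.
    """
    if roles:
        leaky = [c for c in modifiers.columns if roles.get(c) == "post_treatment"]
        if leaky:
            raise ValueError(
                f"modifiers {leaky} are tagged post_treatment; using them to "
                "model effect heterogeneity leaks outcome information"
            )
    psi = np.asarray(effect_signal, dtype=float)
    if len(psi) != len(modifiers):
        raise ValueError("effect signal and modifiers must have equal length")
    M = modifiers.to_numpy(dtype=float)

    if final_model == "ridge":
        from sklearn.linear_model import Ridge

        model = Ridge(alpha=ridge_alpha)
        model.fit(M, psi)
        tau_hat = model.predict(M)
        coefs = dict(zip(modifiers.columns, map(float, model.coef_)))
        return CATEResult(tau_hat, list(modifiers.columns), coefs, float(model.intercept_), "ridge")
    if final_model == "forest":
        from sklearn.ensemble import RandomForestRegressor

        model = RandomForestRegressor(
            n_estimators=100, max_depth=5, min_samples_leaf=100, random_state=seed, n_jobs=1
        )
        model.fit(M, psi)
        return CATEResult(model.predict(M), list(modifiers.columns), None, None, "forest")
    raise ValueError(f"final_model must be 'ridge' or 'forest', got {final_model!r}")


def _box_summary(values: np.ndarray) -> dict[str, float]:
    q25, med, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    lo_bound, hi_bound = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = values[(values >= lo_bound) & (values <= hi_bound)]
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "mean": float(values.mean()),
    }


def subgroup_report(
    cate: CATEResult,
    modifiers: pd.DataFrame,
    out_plot=None,
) -> pd.DataFrame:
    """Box summaries of tau_hat for each level of each binary modifier.

    One row per (modifier, level); whiskers extend to the most extreme
    observed value within 1.5 x IQR of the quartiles.  Empty levels are
    flagged rather than dropped.
    """
    tau = np.asarray(cate.tau_hat, dtype=float)
    rows = []
    for col in modifiers.columns:
        flags = modifiers[col].to_numpy(dtype=float)
        for level in (1.0, 0.0):
            mask = flags == level
            label = col if level == 1.0 else f"not_{col}"
            if not mask.any():
                rows.append(
                    {"modifier": col, "level": int(level), "subgroup": label, "n": 0, "empty": True}
                )
                continue
            row = {
                "modifier": col,
                "level": int(level),
                "subgroup": label,
                "n": int(mask.sum()),
                "empty": False,
            }
            row.update(_box_summary(tau[mask]))
            rows.append(row)
    report = pd.DataFrame(rows)

    if out_plot is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ok = report[~report["empty"]]
        fig, ax = plt.subplots(figsize=(6, 0.5 * len(ok) + 1))
        ypos = np.arange(len(ok))[::-1]
        for y, (_, r) in zip(ypos, ok.iterrows()):
            ax.plot([r["whisker_low"], r["whisker_high"]], [y, y], color="k", lw=0.8)
            ax.add_patch(
                plt.Rectangle(
                    (r["q25"], y - 0.2), r["q75"] - r["q25"], 0.4, facecolor="#9ecae1"
                )
            )
            ax.plot([r["median"], r["median"]], [y - 0.2, y + 0.2], color="k", lw=1.5)
        ax.set_yticks(ypos)
        ax.set_yticklabels(ok["subgroup"], fontsize=8)
        ax.axvline(0.0, color="grey", lw=0.5, ls="--")
        ax.set_xlabel("predicted individual effect (risk difference)")
        fig.tight_layout()
        fig.savefig(out_plot, dpi=120)
        plt.close(fig)
    return report
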