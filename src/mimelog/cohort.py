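"""Cohort selection, longitudinal gradient estimation and group statistics.

Implements the observational procedures used around the feedback model:

* cross-sectional range restriction of euthyroid controls and LT4-treated
  patients (FT4 10-20 pmol/L, TSH 0.1-4.0 mIU/L by default, carcinoma
  follow-up patients excluded);
* longitudinal selection of treated patients with a dose change of at
  least 50 µg/day whose TSH stayed within the accurately measurable range,
  pairing each patient's maximum-TSH and minimum-TSH visits for gradient
  estimation;
* per-patient phi versus thyroid function (Kendall rank correlation);
* between-group comparison of the log TSH - FT4/FT3 slopes and of step-up
  deiodinase activity.

Rank correlations and linear-model fits are routine statistics delegated to
scipy/statsmodels; the selection rules, pairing convention and estimators
they feed are defined here and in :mod:`mimelog.estimators`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
import statsmodels.formula.api as smf

from .constants import ModelConstants, DEFAULT_CONSTANTS
from .estimators import VisitPair, estimate_phi, phi_quality, spina_gd

__all__ = [
    "FilterResult",
    "LongitudinalSelection",
    "filter_cross_sectional",
    "select_longitudinal",
    "phi_vs_function",
    "group_comparison",
]

CROSS_SECTIONAL_GROUPS = ("control", "treated_benign")


@dataclass(frozen=True)
class FilterResult:
    """Outcome of a range filter: retained records plus every excluded row
    with its reason code (malformed rows are reported, never silently
    dropped)."""

    records: pd.DataFrame
    excluded: pd.DataFrame  # columns: original index, patient_id, reason

    @property
    def exclusion_counts(self) -> dict[str, int]:
        if len(self.excluded) == 0:
            return {}
        return self.excluded["reason"].value_counts().to_dict()


@dataclass(frozen=True)
class LongitudinalSelection:
    """One treated patient's max-TSH / min-TSH visit pair with the gradient
    estimated from it."""

    patient_id: object
    pair: VisitPair
    dose_difference: float
    mean_ft4: float
    mean_tsh: float
    phi: float
    quality: str = field(default="physiological")


def _check_range(name: str, rng: tuple[float, float]) -> None:
    if not rng[0] < rng[1]:
        raise ValueError(f"{name} must satisfy low < high, got {rng}")


def filter_cross_sectional(
    records: pd.DataFrame,
    ft4_range: tuple[float, float] = (10.0, 20.0),
    tsh_range: tuple[float, float] = (0.1, 4.0),
) -> FilterResult:
    """Range-restrict records for the cross-sectional group comparison.

    Retains rows whose FT4 and TSH both lie inside the closed intervals;
    carcinoma follow-up patients (group ``carcinoma_longitudinal``) are
    excluded from this comparison. Rows with missing or non-positive
    hormone values are reported as ``malformed``. Idempotent.
    """
    _check_range("ft4_range", ft4_range)
    _check_range("tsh_range", tsh_range)
    reasons = pd.Series("", index=records.index, dtype=object)

    tsh = pd.to_numeric(records["tsh"], errors="coerce")
    ft4 = pd.to_numeric(records["ft4"], errors="coerce")
    malformed = tsh.isna() | ft4.isna() | (tsh <= 0) | (ft4 <= 0)
    reasons[malformed] = "malformed"

    carcinoma = (records["group"] == "carcinoma_longitudinal") & (reasons == "")
    reasons[carcinoma] = "carcinoma_excluded"

    ok = reasons == ""
    ft4_out = ok & ((ft4 < ft4_range[0]) | (ft4 > ft4_range[1]))
    reasons[ft4_out] = "ft4_out_of_range"
    ok = reasons == ""
    tsh_out = ok & ((tsh < tsh_range[0]) | (tsh > tsh_range[1]))
    reasons[tsh_out] = "tsh_out_of_range"

    keep = reasons == ""
    excluded = pd.DataFrame(
        {
            "index": records.index[~keep],
            "patient_id": records.loc[~keep, "patient_id"].to_numpy(),
            "reason": reasons[~keep].to_numpy(),
        }
    )
    return FilterResult(records=records[keep].copy(), excluded=excluded)


def select_longitudinal(
    records: pd.DataFrame,
    min_dose_change: float = 50.0,
    tsh_range: tuple[float, float] = (0.1, 4.0),
) -> tuple[list[LongitudinalSelection], pd.DataFrame]:
    """Select per-patient visit pairs for longitudinal gradient estimation.

    For each patient with at least two visits, the visit attaining the
    maximum TSH and the visit attaining the minimum TSH are paired (each
    contributing its own same-visit FT4; ties broken by the earliest visit
    index). The patient qualifies when the LT4 dose difference between the
    two selected visits is at least ``min_dose_change`` µg/day and both TSH
    values lie inside the closed ``tsh_range`` — jointly excluding patients
    with lesser dose alterations and those with complete TSH suppression,
    for whom the gradient cannot be reliably estimated.

    Returns (selections, exclusions); exclusions carry one reason code per
    rejected patient (``too_few_visits``, ``missing_values``,
    ``missing_dose``, ``tsh_out_of_range``, ``dose_change_too_small``,
    ``phi_undefined``).
    """
    _check_range("tsh_range", tsh_range)
    if min_dose_change < 0:
        raise ValueError("min_dose_change must be >= 0")

    selections: list[LongitudinalSelection] = []
    rejected: list[tuple[object, str]] = []

    for pid, visits in records.groupby("patient_id", sort=True):
        visits = visits.sort_values("visit")
        if len(visits) < 2:
            rejected.append((pid, "too_few_visits"))
            continue
        tsh = pd.to_numeric(visits["tsh"], errors="coerce")
        ft4 = pd.to_numeric(visits["ft4"], errors="coerce")
        if tsh.isna().any() or ft4.isna().any() or (tsh <= 0).any() or (ft4 <= 0).any():
            rejected.append((pid, "missing_values"))
            continue
        # idxmax/idxmin on the visit-sorted frame break ties at the earliest visit
        hi = visits.loc[tsh.idxmax()]
        lo = visits.loc[tsh.idxmin()]
        dose_hi, dose_lo = hi["lt4_dose"], lo["lt4_dose"]
        if pd.isna(dose_hi) or pd.isna(dose_lo):
            rejected.append((pid, "missing_dose"))
            continue
        in_range = all(
            tsh_range[0] <= t <= tsh_range[1] for t in (hi["tsh"], lo["tsh"])
        )
        if not in_range:
            rejected.append((pid, "tsh_out_of_range"))
            continue
        dose_diff = abs(float(dose_hi) - float(dose_lo))
        if dose_diff < min_dose_change:
            rejected.append((pid, "dose_change_too_small"))
            continue
        if hi["ft4"] == lo["ft4"]:
            rejected.append((pid, "phi_undefined"))
            continue
        pair = VisitPair(
            tsh_1=float(hi["tsh"]), ft4_1=float(hi["ft4"]),
            tsh_2=float(lo["tsh"]), ft4_2=float(lo["ft4"]),
        )
        phi = estimate_phi(pair)
        selections.append(
            LongitudinalSelection(
                patient_id=pid,
                pair=pair,
                dose_difference=dose_diff,
                mean_ft4=(pair.ft4_1 + pair.ft4_2) / 2.0,
                mean_tsh=(pair.tsh_1 + pair.tsh_2) / 2.0,
                phi=phi,
                quality=phi_quality(phi),
            )
        )
    exclusions = pd.DataFrame(rejected, columns=["patient_id", "reason"])
    return selections, exclusions


def selections_to_frame(selections: list[LongitudinalSelection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in selections],
            "phi": [s.phi for s in selections],
            "mean_ft4": [s.mean_ft4 for s in selections],
            "mean_tsh": [s.mean_tsh for s in selections],
            "dose_difference": [s.dose_difference for s in selections],
            "quality": [s.quality for s in selections],
        }
    )


def phi_vs_function(selections: list[LongitudinalSelection], min_n: int = 5) -> dict:
    """Correlate per-patient gradients with thyroid function.

    Returns the per-patient table plus Kendall tau of phi against mean FT4
    and against mean TSH, each reported with its n and p-value. With fewer
    than ``min_n`` patients, or a degenerate (constant) column, the
    correlation is reported as undefined rather than computed.
    """
    table = selections_to_frame(selections)
    result: dict = {"table": table, "n": len(table)}
    for key, col in (("tau_phi_ft4", "mean_ft4"), ("tau_phi_tsh", "mean_tsh")):
        if len(table) < min_n:
            result[key] = {"n": len(table), "tau": float("nan"), "p": float("nan"),
                           "note": f"fewer than {min_n} patients"}
        elif table["phi"].nunique() < 2 or table[col].nunique() < 2:
            result[key] = {"n": len(table), "tau": float("nan"), "p": float("nan"),
                           "note": "degenerate (constant) column"}
        else:
            tau, p = kendalltau(table["phi"], table[col])
            result[key] = {"n": len(table), "tau": float(tau), "p": float(p)}
    return result


def _slope_contrast(combined: pd.DataFrame, x: str) -> dict:
    """ln(TSH) ~ x per group plus the two-group interaction contrast."""
    sub = combined.dropna(subset=[x, "tsh"])
    sub = sub[sub["tsh"] > 0]
    out: dict = {"n": len(sub), "dropped": len(combined) - len(sub)}
    slopes = {}
    for grp, d in sub.groupby("grp"):
        fit = smf.ols(f"log_tsh ~ {x}", data=d).fit()
        slopes[grp] = float(fit.params[x])
    out["slopes"] = slopes
    inter = smf.ols(f"log_tsh ~ {x} * grp", data=sub).fit()
    term = f"{x}:grp[T.treated]"
    out["slope_contrast"] = float(inter.params[term])
    out["slope_contrast_p"] = float(inter.pvalues[term])
    return out


def group_comparison(
    control_records: pd.DataFrame,
    treated_records: pd.DataFrame,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Compare the TSH-FT4/FT3 relationships and deiodinase activity of a
    control and an LT4-treated group (both already range-filtered).

    Reports per-group slopes of ln(TSH) on FT4 and on FT3, the between-group
    slope contrasts (interaction term of a two-group linear model), per-group
    step-up deiodinase activity (SPINA-GD) with its rank correlation with
    TSH, and — in the treated group — the rank correlation of G_D with the
    weight-adjusted LT4 dose (µg/kg/day). Records missing a needed field are
    excluded pairwise, with counts reported.
    """
    control = control_records.assign(grp="control")
    treated = treated_records.assign(grp="treated")
    combined = pd.concat([control, treated], ignore_index=True)
    combined["log_tsh"] = np.log(
        pd.to_numeric(combined["tsh"], errors="coerce").where(lambda s: s > 0)
    )

    report: dict = {
        "n_control": len(control_records),
        "n_treated": len(treated_records),
        "tsh_ft4": _slope_contrast(combined, "ft4"),
        "tsh_ft3": _slope_contrast(combined, "ft3"),
    }

    gd_block: dict = {}
    for grp, d in combined.groupby("grp"):
        valid = d.dropna(subset=["ft4", "ft3", "tsh"])
        valid = valid[(valid["ft4"] > 0) & (valid["ft3"] >= 0) & (valid["tsh"] > 0)]
        gd = np.array(
            [spina_gd(row.ft4, row.ft3, constants) for row in valid.itertuples()]
        )
        entry = {"n": len(valid), "dropped": len(d) - len(valid),
                 "mean": float(np.mean(gd)) if len(gd) else float("nan")}
        if len(gd) >= 5 and len(np.unique(gd)) > 1:
            tau, p = kendalltau(gd, valid["tsh"])
            entry["tau_gd_tsh"] = {"tau": float(tau), "p": float(p)}
        else:
            entry["tau_gd_tsh"] = {"tau": float("nan"), "p": float("nan")}
        if grp == "treated":
            dosed = valid.dropna(subset=["lt4_dose", "weight"])
            dosed = dosed[dosed["weight"] > 0]
            entry["n_with_dose"] = len(dosed)
            if len(dosed) >= 5:
                gd_d = np.array(
                    [spina_gd(r.ft4, r.ft3, constants) for r in dosed.itertuples()]
                )
                per_kg = dosed["lt4_dose"] / dosed["weight"]
                tau, p = kendalltau(gd_d, per_kg)
                entry["tau_gd_dose_per_kg"] = {"tau": float(tau), "p": float(p)}
            else:
                entry["tau_gd_dose_per_kg"] = {"tau": float("nan"), "p": float("nan")}
        gd_block[grp] = entry
    report["spina_gd"] = gd_block
    return report
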