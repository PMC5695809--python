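"""Synthetic-cohort generator emulating the observational study structure.

Generates delimited-text cohorts with three groups mirroring the clinical
design around which the pipeline is built:

* ``control`` — euthyroid subjects whose (FT4, TSH) pairs are set points of
  the feedback model with structural parameters drawn per subject;
* ``treated_benign`` — LT4-treated patients with a steeper TSH-FT4 gradient,
  displaced hormone ranges, an LT4 dose, and deiodinase activity inversely
  linked to weight-adjusted dose;
* ``carcinoma_longitudinal`` — a two-visit follow-up cohort with dose
  changes, in which each patient's gradient phi is constructed as a
  decreasing function of thyroid function (mean FT4), plus non-qualifying
  patients (small dose change, or complete TSH suppression).

Every measured value derives from the model plus configurable measurement
noise (multiplicative log-normal on TSH, additive Gaussian on FT4/FT3);
``noise_scale=0`` yields records lying exactly on their generating set
points. Ground-truth parameters are returned alongside the records for
recovery tests. Deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import _solve_triples
from .constants import ModelConstants, DEFAULT_CONSTANTS
from .estimators import ft3_from_gd

__all__ = ["CohortConfig", "generate_synthetic_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Group sizes follow the clinical design (268 euthyroid controls, 170
    LT4-treated patients with benign disease, 64 longitudinal carcinoma
    follow-up patients). Structural-parameter ranges for controls match the
    healthy-population simulation design (S uniform 100-600 mIU/L, phi
    uniform 0.27-0.50 L/pmol, G_T spanning 1.67-7.51 pmol/s); the treated
    group gets a steeper gradient and an extended capacity range, displacing
    its set points. Noise defaults: log-normal TSH with sigma 0.05, Gaussian
    FT4/FT3 with sd 0.5/0.2 pmol/L.
    """

    n_control: int = 268
    n_treated: int = 170
    n_longitudinal: int = 64

    control_gt: tuple[float, float] = (1.67, 7.51)
    control_s: tuple[float, float] = (100.0, 600.0)
    control_phi: tuple[float, float] = (0.27, 0.50)

    treated_gt: tuple[float, float] = (3.0, 14.0)
    treated_s: tuple[float, float] = (100.0, 600.0)
    treated_phi: tuple[float, float] = (0.40, 0.60)

    tsh_sigma_log: float = 0.05
    ft4_sigma: float = 0.5
    ft3_sigma: float = 0.2
    noise_scale: float = 1.0

    weight_mean: float = 75.0
    weight_sd: float = 12.0
    control_gd_mean: float = 30.0
    control_gd_sd: float = 5.0
    # treated G_D declines with weight-adjusted dose (µg/kg/day)
    treated_gd_intercept: float = 33.0
    treated_gd_slope: float = -7.0
    treated_gd_sd: float = 2.0
    treated_dose_per_kg: tuple[float, float] = (1.0, 2.2)

    # longitudinal design: two visits separated in FT4, phi declining with mean FT4
    long_ft4_mean: tuple[float, float] = (11.0, 27.0)
    long_ft4_separation: tuple[float, float] = (3.0, 7.0)
    long_phi_intercept: float = 0.65
    long_phi_slope: float = 0.02  # phi = intercept - slope * mean FT4 (+ jitter)
    long_phi_jitter: float = 0.02
    long_phi_floor: float = 0.05
    long_dose_base: tuple[float, float] = (75.0, 150.0)
    long_dose_change: tuple[float, float] = (50.0, 100.0)
    long_small_dose_change: tuple[float, float] = (0.0, 40.0)
    n_long_small_dose: int = 6
    n_long_suppressed: int = 6

    tsh_measurable: tuple[float, float] = (0.1, 4.0)

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_treated, self.n_longitudinal) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_long_small_dose + self.n_long_suppressed > self.n_longitudinal:
            raise ValueError("non-qualifying longitudinal counts exceed the group size")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for name in ("control_gt", "control_s", "control_phi", "treated_gt",
                     "treated_s", "treated_phi", "long_ft4_mean",
                     "long_ft4_separation", "tsh_measurable"):
            low, high = getattr(self, name)
            if not low < high:
                raise ValueError(f"{name} must satisfy low < high")

    def as_dict(self) -> dict:
        return {
            k: (v if not isinstance(v, tuple) else ",".join(map(str, v)))
            for k, v in dataclasses.asdict(self).items()
        }


def _noise(rng, config, tsh, ft4):
    """Measurement noise: multiplicative log-normal TSH, additive Gaussian FT4."""
    scale = config.noise_scale
    tsh_obs = tsh * np.exp(scale * config.tsh_sigma_log * rng.standard_normal(len(tsh)))
    ft4_obs = ft4 + scale * config.ft4_sigma * rng.standard_normal(len(ft4))
    return tsh_obs, np.clip(ft4_obs, 0.5, None)


def _cross_sectional_group(
    rng, config: CohortConfig, constants: ModelConstants, group: str, n: int, id_prefix: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    treated = group == "treated_benign"
    gt_rng = config.treated_gt if treated else config.control_gt
    s_rng = config.treated_s if treated else config.control_s
    phi_rng = config.treated_phi if treated else config.control_phi

    g_t = rng.uniform(*gt_rng, n)
    s = rng.uniform(*s_rng, n)
    phi = rng.uniform(*phi_rng, n)
    points = _solve_triples(g_t, s, phi, constants, tol=1e-9)

    weight = np.clip(rng.normal(config.weight_mean, config.weight_sd, n), 45.0, 130.0)
    if treated:
        per_kg = rng.uniform(*config.treated_dose_per_kg, n)
        dose = per_kg * weight
        gd = config.treated_gd_intercept + config.treated_gd_slope * per_kg
        gd = gd + config.treated_gd_sd * rng.standard_normal(n)
    else:
        dose = np.full(n, np.nan)
        gd = rng.normal(config.control_gd_mean, config.control_gd_sd, n)
    gd = np.clip(gd, 5.0, None)

    tsh_obs, ft4_obs = _noise(rng, config, points["tsh"].to_numpy(), points["ft4"].to_numpy())
    ft3_true = np.array([ft3_from_gd(g, f, constants) for g, f in zip(gd, points["ft4"])])
    ft3_obs = np.clip(
        ft3_true + config.noise_scale * config.ft3_sigma * rng.standard_normal(n), 0.2, None
    )

    ids = [f"{id_prefix}{i:04d}" for i in range(n)]
    records = pd.DataFrame(
        {
            "patient_id": ids, "group": group, "visit": 1,
            "tsh": tsh_obs, "ft4": ft4_obs, "ft3": ft3_obs,
            "lt4_dose": dose, "weight": weight,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": ids, "group": group,
            "g_t": g_t, "s": s, "phi": phi,
            "ft4_true": points["ft4"], "tsh_true": points["tsh"],
            "ft3_true": ft3_true, "gd_true": gd,
            "qualifies": np.nan, "reason": "",
        }
    )
    return records, truth


def _longitudinal_group(
    rng, config: CohortConfig, constants: ModelConstants
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = config.n_longitudinal
    n_small, n_supp = config.n_long_small_dose, config.n_long_suppressed
    categories = (
        ["small_dose"] * n_small + ["suppressed"] * n_supp
        + ["qualifying"] * (n - n_small - n_supp)
    )
    rng.shuffle(categories)

    rec_rows, truth_rows = [], []
    tsh_lo_floor = config.tsh_measurable[0] + 0.02
    tsh_hi_cap = config.tsh_measurable[1] - 0.5
    for i, category in enumerate(categories):
        pid = f"L{i:04d}"
        mean_ft4 = rng.uniform(*config.long_ft4_mean)
        phi = config.long_phi_intercept - config.long_phi_slope * mean_ft4
        phi += config.long_phi_jitter * rng.standard_normal()
        phi = float(np.clip(phi, config.long_phi_floor, 1.0))

        sep = rng.uniform(*config.long_ft4_separation)
        # cap the separation so both TSH values can stay inside the measurable range
        sep = min(sep, 0.95 * np.log(tsh_hi_cap / tsh_lo_floor) / phi)
        ft4_lo, ft4_hi = mean_ft4 - sep / 2.0, mean_ft4 + sep / 2.0

        if category == "suppressed":
            # complete TSH suppression at both visits: gradient not estimable
            tsh_at_hi = rng.uniform(0.01, 0.05)
        else:
            upper = min(0.9, tsh_hi_cap * np.exp(-phi * sep))
            tsh_at_hi = rng.uniform(tsh_lo_floor, max(upper, tsh_lo_floor + 0.01))
        s = tsh_at_hi * np.exp(phi * ft4_hi)
        tsh_at_lo = s * np.exp(-phi * ft4_lo)

        dose_lo = rng.uniform(*config.long_dose_base)
        change_rng = (
            config.long_small_dose_change if category == "small_dose"
            else config.long_dose_change
        )
        dose_hi = dose_lo + rng.uniform(*change_rng)

        # higher dose drives the higher-FT4 (lower-TSH) visit; visit order randomised
        visits = [
            {"ft4": ft4_lo, "tsh": tsh_at_lo, "dose": dose_lo},
            {"ft4": ft4_hi, "tsh": tsh_at_hi, "dose": dose_hi},
        ]
        if rng.random() < 0.5:
            visits.reverse()

        weight = float(np.clip(rng.normal(config.weight_mean, config.weight_sd), 45.0, 130.0))
        gd = float(np.clip(rng.normal(25.0, 4.0), 5.0, None))
        tsh_true = np.array([v["tsh"] for v in visits])
        ft4_true = np.array([v["ft4"] for v in visits])
        tsh_obs, ft4_obs = _noise(rng, config, tsh_true, ft4_true)
        for visit_idx, v in enumerate(visits, start=1):
            ft3_true = ft3_from_gd(gd, v["ft4"], constants)
            ft3_obs = max(
                0.2,
                ft3_true + config.noise_scale * config.ft3_sigma * rng.standard_normal(),
            )
            rec_rows.append(
                {
                    "patient_id": pid, "group": "carcinoma_longitudinal",
                    "visit": visit_idx,
                    "tsh": tsh_obs[visit_idx - 1], "ft4": ft4_obs[visit_idx - 1],
                    "ft3": ft3_obs, "lt4_dose": v["dose"], "weight": weight,
                }
            )
        reason = {"qualifying": "", "small_dose": "dose_change_too_small",
                  "suppressed": "tsh_out_of_range"}[category]
        truth_rows.append(
            {
                "patient_id": pid, "group": "carcinoma_longitudinal",
                "g_t": np.nan, "s": s, "phi": phi,
                "ft4_true": mean_ft4, "tsh_true": float(np.mean(tsh_true)),
                "ft3_true": np.nan, "gd_true": gd,
                "qualifies": category == "qualifying", "reason": reason,
            }
        )
    return pd.DataFrame(rec_rows), pd.DataFrame(truth_rows)


def generate_synthetic_cohort(
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (records, truth) for the three study groups.

    ``records`` follows the standard cohort schema (one row per visit);
    ``truth`` carries each subject's generating parameters, plus — for
    longitudinal patients — whether they qualify for gradient estimation
    and the reason code when they do not.
    """
    streams = np.random.SeedSequence(seed).spawn(3)
    rec_c, truth_c = _cross_sectional_group(
        np.random.default_rng(streams[0]), config, constants, "control",
        config.n_control, "C",
    )
    rec_t, truth_t = _cross_sectional_group(
        np.random.default_rng(streams[1]), config, constants, "treated_benign",
        config.n_treated, "T",
    )
    rec_l, truth_l = _longitudinal_group(np.random.default_rng(streams[2]), config, constants)
    records = pd.concat([rec_c, rec_t, rec_l], ignore_index=True)
    truth = pd.concat([truth_c, truth_t, truth_l], ignore_index=True)
    return records, truth
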