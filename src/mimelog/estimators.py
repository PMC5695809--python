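"""Closed-form estimators of structural parameters from observed hormones.

Because the intra-individual TSH-FT4 relationship is log-linear, two paired
measurements taken at different operating points identify both the gradient
and the intercept of an individual's inverted pituitary response:

    phi = ln(TSH_2 / TSH_1) / (FT4_1 − FT4_2)
    S   = TSH_1 · exp(phi · FT4_1)

The difference ordering pairs the TSH ratio at times (2, 1) with the FT4
difference at times (1, 2): under the physiological inverse relationship
(TSH falls when FT4 rises) this yields phi > 0, and makes the S identity
hold equally at either time point. Noisy real-world pairs can produce a
negative phi; the value is returned as-is and callers consult
``phi_quality`` rather than receive an exception, since the empirical
distribution of phi is itself of interest.

SPINA-GD estimates the summed activity of the step-up (T4→T3 converting)
deiodinases from a single equilibrium (FT4, FT3) pair:

    G_D = beta_31·(K_M1 + [FT4])·(1 + K30·[TBG])·[FT3] / (alpha_31·[FT4]),

reported in nmol/s. Hormone inputs are pmol/L and the Michaelis constant is
configured in nmol/L; all are converted to molar internally (single
conversion layer, see ``_PMOL_PER_L_TO_MOL_PER_L``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import ModelConstants, DEFAULT_CONSTANTS

__all__ = ["VisitPair", "estimate_phi", "estimate_s", "spina_gd", "phi_quality"]

# unit conversion layer: hormone assays report pmol/L, binding constants are molar
_PMOL_PER_L_TO_MOL_PER_L = 1e-12
_NMOL_PER_L_TO_MOL_PER_L = 1e-9
_MOL_PER_S_TO_NMOL_PER_S = 1e9


@dataclass(frozen=True)
class VisitPair:
    """Paired (TSH, FT4) measurements of one individual at two time points.

    Hormone values strictly positive; ``ft4_1 != ft4_2`` is required for the
    gradient to be identifiable."""

    tsh_1: float
    ft4_1: float
    tsh_2: float
    ft4_2: float
    time_1: float | None = None
    time_2: float | None = None

    def __post_init__(self) -> None:
        for name in ("tsh_1", "ft4_1", "tsh_2", "ft4_2"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"VisitPair.{name} must be finite and > 0, got {value!r}")

    def swapped(self) -> "VisitPair":
        return VisitPair(
            tsh_1=self.tsh_2, ft4_1=self.ft4_2, tsh_2=self.tsh_1, ft4_2=self.ft4_1,
            time_1=self.time_2, time_2=self.time_1,
        )


def estimate_phi(pair: VisitPair) -> float:
    """Gradient of the individual TSH-FT4 relationship from a visit pair,
    phi = ln(TSH_2/TSH_1)/(FT4_1 − FT4_2), in L/pmol.

    Symmetric under swapping the two time points. Raises ``ValueError`` when
    FT4 is identical at both visits (gradient unidentifiable).
    """
    dft4 = pair.ft4_1 - pair.ft4_2
    if dft4 == 0.0:
        raise ValueError("gradient undefined: FT4 identical at both visits")
    return math.log(pair.tsh_2 / pair.tsh_1) / dft4


def estimate_s(pair: VisitPair, phi: float) -> float:
    """Maximum pituitary TSH response S = TSH_1·exp(phi·FT4_1), in mIU/L.

    With ``phi = estimate_phi(pair)`` the same value results from time
    point 2 — the identity used as an internal consistency check in tests.
    """
    if not math.isfinite(phi):
        raise ValueError(f"phi must be finite, got {phi!r}")
    return pair.tsh_1 * math.exp(phi * pair.ft4_1)


def phi_quality(phi: float) -> str:
    """Quality flag for an estimated gradient: ``'physiological'`` (phi > 0),
    ``'flat'`` (phi == 0) or ``'non_physiological'`` (phi < 0, as can arise
    from measurement noise in near-flat pairs)."""
    if phi > 0:
        return "physiological"
    if phi == 0:
        return "flat"
    return "non_physiological"


def spina_gd(
    ft4: float, ft3: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Global step-up deiodinase activity (SPINA-GD) in nmol/s.

    ``ft4``/``ft3`` in pmol/L; linear in FT3 at fixed FT4. FT4 = 0 is
    rejected (the estimator divides by the substrate concentration).
    """
    if not ft4 > 0:
        raise ValueError(f"FT4 must be > 0, got {ft4!r}")
    if ft3 < 0:
        raise ValueError(f"FT3 must be >= 0, got {ft3!r}")
    ft4_m = ft4 * _PMOL_PER_L_TO_MOL_PER_L
    ft3_m = ft3 * _PMOL_PER_L_TO_MOL_PER_L
    km1_m = constants.k_m1 * _NMOL_PER_L_TO_MOL_PER_L
    gd_mol_per_s = (
        constants.beta_31
        * (km1_m + ft4_m)
        * (1.0 + constants.k30 * constants.tbg)
        * ft3_m
        / (constants.alpha_31 * ft4_m)
    )
    return gd_mol_per_s * _MOL_PER_S_TO_NMOL_PER_S


def ft3_from_gd(
    gd_nmol_s: float, ft4: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Invert the SPINA-GD estimator for FT3 (pmol/L) given activity and FT4.

    Used by the synthetic-cohort generator so that generated FT3 values are
    exactly consistent with their generating deiodinase activity."""
    if not ft4 > 0:
        raise ValueError(f"FT4 must be > 0, got {ft4!r}")
    if gd_nmol_s < 0:
        raise ValueError(f"G_D must be >= 0, got {gd_nmol_s!r}")
    ft4_m = ft4 * _PMOL_PER_L_TO_MOL_PER_L
    km1_m = constants.k_m1 * _NMOL_PER_L_TO_MOL_PER_L
    ft3_m = (
        gd_nmol_s / _MOL_PER_S_TO_NMOL_PER_S
        * constants.alpha_31 * ft4_m
        / (constants.beta_31 * (km1_m + ft4_m) * (1.0 + constants.k30 * constants.tbg))
    )
    return ft3_m / _PMOL_PER_L_TO_MOL_PER_L
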