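"""Equilibrium model of pituitary-thyroid feedback and its set-point solver.

The model couples two characteristic response curves (nullclines) in the
(FT4, TSH) plane:

* the *inverted pituitary response* — exponential feedback inhibition of TSH
  release by FT4,

      TSH = S · exp(−phi · FT4),

  log-linear in FT4 with intercept ln(S) and gradient phi;

* the *thyroid response* — Michaelis-Menten feedforward stimulation of T4
  secretion by TSH,

      FT4 = K_T · TSH / (D_T + TSH),

  saturating at the maximum stimulated T4 level K_T, with half-maximum at
  the receptor EC50 D_T.

K_T derives from the thyroid's secretory capacity G_T and constants for
distribution, elimination and plasma protein binding:

      K_T = alpha_T · G_T / (beta_T · (1 + K41·[TBG] + K42·[TTR])).

An individual's *set point* is the unique intersection of the two curves:
the pituitary curve is strictly decreasing and the thyroid curve strictly
increasing, so the fixed-point residual g(FT4) = FT4 − thyroid(pituitary(FT4))
is strictly increasing and brackets a single root on [0, K_T].

Units throughout: FT4/FT3 pmol/L, TSH mIU/L, G_T pmol/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import ModelConstants, DEFAULT_CONSTANTS

__all__ = [
    "PituitaryParams",
    "ThyroidParams",
    "SetPoint",
    "pituitary_response",
    "thyroid_response",
    "compute_kt",
    "solve_set_point",
    "pituitary_nullcline",
    "thyroid_nullcline",
]


@dataclass(frozen=True)
class PituitaryParams:
    """Maximum pituitary TSH response ``s`` (intercept, mIU/L) and gradient
    ``phi`` (L/pmol) of the exponential TSH-FT4 relationship.

    ``phi = 0`` is admitted as the degenerate flat-feedback case; negative
    phi is rejected (a positive feedback would destroy uniqueness)."""

    s: float
    phi: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"intercept S must be > 0, got {self.s!r}")
        if self.phi < 0:
            raise ValueError(f"gradient phi must be >= 0, got {self.phi!r}")


@dataclass(frozen=True)
class ThyroidParams:
    """Thyroid secretory capacity ``g_t`` (pmol/s) with the derived maximum
    stimulated T4 level ``k_t`` (pmol/L)."""

    g_t: float
    k_t: float = field(default=0.0)
    constants: ModelConstants = field(default=DEFAULT_CONSTANTS, repr=False)

    def __post_init__(self) -> None:
        if not self.g_t > 0:
            raise ValueError(f"secretory capacity G_T must be > 0, got {self.g_t!r}")
        if self.k_t == 0.0:
            object.__setattr__(self, "k_t", compute_kt(self.g_t, self.constants))
        if not self.k_t > 0:
            raise ValueError(f"K_T must be > 0, got {self.k_t!r}")


@dataclass(frozen=True)
class SetPoint:
    """An equilibrium (FT4, TSH) pair at a nullcline intersection."""

    ft4: float
    tsh: float

    def __post_init__(self) -> None:
        if self.ft4 < 0 or self.tsh < 0:
            raise ValueError(f"set point must be non-negative, got {self!r}")

    def residuals(
        self,
        pituitary: PituitaryParams,
        thyroid: ThyroidParams,
        constants: ModelConstants | None = None,
    ) -> tuple[float, float]:
        """(|TSH − S e^{−phi FT4}|, |FT4 − K_T TSH/(D_T+TSH)|) — both vanish
        at a solved set point."""
        constants = constants or thyroid.constants
        r_pit = abs(self.tsh - pituitary_response(self.ft4, pituitary))
        r_thy = abs(self.ft4 - thyroid_response(self.tsh, thyroid, constants))
        return r_pit, r_thy


def pituitary_response(ft4, params: PituitaryParams):
    """Inverted pituitary response: TSH = S·exp(−phi·FT4).

    Accepts a scalar or array of FT4 (pmol/L, non-negative); returns TSH in
    mIU/L. Strictly decreasing in FT4 for phi > 0.
    """
    ft4 = np.asarray(ft4, dtype=float)
    if np.any(ft4 < 0) or np.any(~np.isfinite(ft4)):
        raise ValueError("FT4 must be finite and non-negative")
    out = params.s * np.exp(-params.phi * ft4)
    return float(out) if out.ndim == 0 else out


def thyroid_response(tsh, params: ThyroidParams, constants: ModelConstants | None = None):
    """Thyroid response: FT4 = K_T·TSH/(D_T + TSH).

    Strictly increasing and concave in TSH, saturating at K_T. ``constants``
    defaults to those carried by ``params``.
    """
    constants = constants or params.constants
    tsh = np.asarray(tsh, dtype=float)
    if np.any(tsh < 0) or np.any(~np.isfinite(tsh)):
        raise ValueError("TSH must be finite and non-negative")
    out = params.k_t * tsh / (constants.d_t + tsh)
    return float(out) if out.ndim == 0 else out


def compute_kt(g_t: float, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Maximum stimulated T4 level from secretory capacity.

    K_T = alpha_T·G_T / (beta_T·(1 + K41·[TBG] + K42·[TTR])), in pmol/L for
    G_T in pmol/s; linear and homogeneous in G_T.
    """
    if not g_t > 0:
        raise ValueError(f"G_T must be > 0, got {g_t!r}")
    return constants.alpha_t * g_t / (constants.beta_t * constants.t4_binding_factor)


def solve_set_point(
    pituitary: PituitaryParams,
    thyroid: ThyroidParams,
    constants: ModelConstants | None = None,
    tol: float = 1e-9,
) -> SetPoint:
    """Solve the nullcline intersection for the individual set point.

    Finds the unique root of g(FT4) = FT4 − thyroid(pituitary(FT4)) on
    [0, K_T] by bracketed root-finding (g(0) ≤ 0 and g(K_T) > 0 for any
    valid positive parameters, and g is strictly increasing). ``tol`` is the
    absolute tolerance on FT4* in pmol/L.
    """
    constants = constants or thyroid.constants
    if not tol > 0:
        raise ValueError(f"tol must be > 0, got {tol!r}")
    s, phi, k_t, d_t = pituitary.s, pituitary.phi, thyroid.k_t, constants.d_t

    if phi == 0.0:
        # flat pituitary nullcline: TSH* = S exactly, closed form
        return SetPoint(ft4=k_t * s / (d_t + s), tsh=s)

    def g(ft4: float) -> float:
        tsh = s * np.exp(-phi * ft4)
        return ft4 - k_t * tsh / (d_t + tsh)

    g0, gk = g(0.0), g(k_t)
    if not (g0 <= 0.0 < gk):  # cannot occur for valid positive parameters
        raise RuntimeError(
            f"set-point root not bracketed on [0, K_T]: g(0)={g0}, g(K_T)={gk} "
            f"(S={s}, phi={phi}, K_T={k_t}, D_T={d_t})"
        )
    ft4_star = brentq(g, 0.0, k_t, xtol=tol, rtol=4 * np.finfo(float).eps)
    tsh_star = s * float(np.exp(-phi * ft4_star))
    return SetPoint(ft4=float(ft4_star), tsh=tsh_star)


def pituitary_nullcline(ft4_grid, params: PituitaryParams) -> np.ndarray:
    """Evaluate the inverted pituitary response on a grid.

    Returns an array of shape (n, 2) with columns (FT4, TSH)."""
    ft4 = np.atleast_1d(np.asarray(ft4_grid, dtype=float))
    if ft4.size == 0:
        raise ValueError("ft4_grid must be non-empty")
    return np.column_stack([ft4, pituitary_response(ft4, params)])


def thyroid_nullcline(
    tsh_grid, params: ThyroidParams, constants: ModelConstants | None = None
) -> np.ndarray:
    """Evaluate the thyroid response on a grid; shape (n, 2), columns (FT4, TSH)."""
    tsh = np.atleast_1d(np.asarray(tsh_grid, dtype=float))
    if tsh.size == 0:
        raise ValueError("tsh_grid must be non-empty")
    return np.column_stack([thyroid_response(tsh, params, constants), tsh])
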