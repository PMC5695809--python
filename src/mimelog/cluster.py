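"""Monte-Carlo simulation of set-point clusters in a hypothetical population.

Each individual carries three structural parameters: thyroid secretory
capacity G_T (swept deterministically over a grid), and pituitary intercept
S and gradient phi (sampled from configurable distributions). Crossing
``n_s`` draws of S with ``n_phi`` draws of phi and every grid level of G_T
and solving each set point yields a cluster of n_s × n_phi × |grid|
equilibrium (FT4, TSH) points — the cloud that, for a healthy population,
covers a kite-shaped region of the (FT4, TSH) plane rather than the
rectangle implied by independent univariate reference intervals.

The *adaptive* mode emulates set-point adaptation (e.g. under LT4
treatment): the gradient phi is not fixed across the functional range but
drifts upward with G_T via a monotone linkage, by default a linear ramp of
the sampled mean from 0 at the grid minimum to ``phi_increment`` at the
grid maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .constants import ModelConstants, DEFAULT_CONSTANTS
from .model import PituitaryParams, ThyroidParams, compute_kt, solve_set_point

__all__ = [
    "Distribution",
    "SamplingSpec",
    "SetPointCluster",
    "make_gt_grid",
    "simulate_cluster",
    "simulate_adaptive_cluster",
    "cluster_summary",
]

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class Distribution:
    """A named sampling distribution: ``uniform(low, high)`` or
    ``normal(mean, sd)``. Draws violating a positivity floor are redrawn
    (rejection), so supports never include non-positive S or negative phi."""

    name: str
    params: tuple[float, float]

    def __post_init__(self) -> None:
        if self.name not in ("uniform", "normal"):
            raise ValueError(f"unknown distribution {self.name!r}; use 'uniform' or 'normal'")
        if self.name == "uniform" and not self.params[0] < self.params[1]:
            raise ValueError(f"uniform requires low < high, got {self.params}")
        if self.name == "normal" and not self.params[1] > 0:
            raise ValueError(f"normal requires sd > 0, got {self.params}")

    def sample(self, rng: np.random.Generator, size: int, floor: float) -> np.ndarray:
        """Draw ``size`` values, redrawing any value <= ``floor`` (for S) or
        < ``floor`` (phi uses floor 0.0 and 0 is admissible)."""
        out = self._draw(rng, size)
        for _ in range(1000):
            bad = out < floor if floor == 0.0 else out <= floor
            if not bad.any():
                return out
            out[bad] = self._draw(rng, int(bad.sum()))
        raise RuntimeError(f"rejection sampling failed for {self} with floor {floor}")

    def _draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "uniform":
            return rng.uniform(self.params[0], self.params[1], size)
        return rng.normal(self.params[0], self.params[1], size)


@dataclass(frozen=True)
class SamplingSpec:
    """Design of a cluster simulation.

    ``gt_grid`` is a strictly increasing positive sequence of G_T values in
    pmol/s; ``n_s`` draws of S and ``n_phi`` draws of phi are crossed with
    every grid level (Cartesian product). ``adaptive`` switches on the
    G_T-linked gradient ramp of height ``phi_increment`` (L/pmol over the
    grid span); ``phi_per_individual`` controls whether adaptive base draws
    are independent per cluster member or shared per phi-draw index.
    """

    gt_grid: tuple[float, ...]
    s_distribution: Distribution = Distribution("uniform", (100.0, 600.0))
    phi_distribution: Distribution = Distribution("uniform", (0.27, 0.50))
    n_s: int = 50
    n_phi: int = 50
    seed: int = 0
    adaptive: bool = False
    phi_increment: float = 0.2
    phi_per_individual: bool = True

    def __post_init__(self) -> None:
        grid = np.asarray(self.gt_grid, dtype=float)
        if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("gt_grid must be non-empty, positive and strictly increasing")
        if self.n_s < 1 or self.n_phi < 1:
            raise ValueError("n_s and n_phi must be >= 1")
        if self.adaptive and self.phi_increment < 0:
            raise ValueError("phi_increment must be >= 0")

    @property
    def size(self) -> int:
        return self.n_s * self.n_phi * len(self.gt_grid)


@dataclass(frozen=True)
class SetPointCluster:
    """A solved cluster: one row per member with its generating triple
    (g_t, s, phi) and equilibrium (ft4, tsh). ``points`` has exactly
    ``spec.size`` rows."""

    points: pd.DataFrame
    spec: SamplingSpec
    constants: ModelConstants = field(default=DEFAULT_CONSTANTS, repr=False)

    COLUMNS = ("g_t", "s", "phi", "ft4", "tsh")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.points.columns)
        if missing:
            raise ValueError(f"cluster table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.points)


def make_gt_grid(low: float, high: float, step: float) -> np.ndarray:
    """Arithmetic G_T sequence low, low+step, … up to ``high`` (inclusive
    within a small tolerance when representable on the lattice).

    Built by index arithmetic (low + k·step) rather than repeated addition
    so long grids do not accumulate floating-point drift. For the healthy-
    cohort design (1.67, 7.51, 0.2) this yields 30 values ending at 7.47 —
    7.51 is not on the lattice.
    """
    if not (low > 0 and low < high and step > 0):
        raise ValueError(f"need 0 < low < high and step > 0, got {(low, high, step)}")
    n = int(math.floor((high - low) / step + _GRID_TOL)) + 1
    return low + step * np.arange(n)


def _solve_triples(g_t, s, phi, constants: ModelConstants, tol: float) -> pd.DataFrame:
    """Solve one set point per (G_T, S, phi) row; abort with the offending
    triple on any solver failure."""
    kt_cache: dict[float, float] = {}
    ft4 = np.empty(len(g_t))
    tsh = np.empty(len(g_t))
    for i, (g, s_i, phi_i) in enumerate(zip(g_t, s, phi)):
        k_t = kt_cache.get(g)
        if k_t is None:
            k_t = kt_cache[g] = compute_kt(g, constants)
        try:
            sp = solve_set_point(
                PituitaryParams(s=s_i, phi=phi_i),
                ThyroidParams(g_t=g, k_t=k_t, constants=constants),
                constants,
                tol=tol,
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"set-point solve failed for (G_T={g}, S={s_i}, phi={phi_i}): {exc}"
            ) from exc
        ft4[i], tsh[i] = sp.ft4, sp.tsh
    return pd.DataFrame({"g_t": g_t, "s": s, "phi": phi, "ft4": ft4, "tsh": tsh})


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent sub-streams for the S and phi draws, derived from one
    top-level seed so adding draws of one parameter does not perturb the
    other."""
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def simulate_cluster(
    spec: SamplingSpec,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    tol: float = 1e-9,
) -> SetPointCluster:
    """Fixed-gradient cluster: n_s S-draws × n_phi phi-draws × G_T grid,
    every member solved to ``tol``. Deterministic given ``spec.seed``."""
    rng_s, rng_phi = _rngs(spec.seed)
    s_draws = spec.s_distribution.sample(rng_s, spec.n_s, floor=0.0)
    phi_draws = spec.phi_distribution.sample(rng_phi, spec.n_phi, floor=0.0)

    grid = np.asarray(spec.gt_grid, dtype=float)
    g_t, s, phi = (
        a.ravel() for a in np.meshgrid(grid, s_draws, phi_draws, indexing="ij")
    )
    points = _solve_triples(g_t, s, phi, constants, tol)
    return SetPointCluster(points=points, spec=spec, constants=constants)


def simulate_adaptive_cluster(
    spec: SamplingSpec,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    tol: float = 1e-9,
) -> SetPointCluster:
    """Adaptive-gradient cluster: the phi of each member is a base draw from
    ``spec.phi_distribution`` plus a linear ramp in G_T rising from 0 at the
    grid minimum to ``spec.phi_increment`` at the grid maximum. Negative
    effective gradients are redrawn. Zero ``phi_increment`` degenerates to
    the fixed-gradient sampling distribution."""
    if not spec.adaptive:
        spec = replace(spec, adaptive=True)
    rng_s, rng_phi = _rngs(spec.seed)
    s_draws = spec.s_distribution.sample(rng_s, spec.n_s, floor=0.0)

    grid = np.asarray(spec.gt_grid, dtype=float)
    span = grid[-1] - grid[0]
    ramp_by_level = (
        spec.phi_increment * (grid - grid[0]) / span if span > 0 else np.zeros_like(grid)
    )

    n_levels = len(grid)
    if spec.phi_per_individual:
        base = spec.phi_distribution.sample(
            rng_phi, n_levels * spec.n_s * spec.n_phi, floor=0.0
        ).reshape(n_levels, spec.n_s, spec.n_phi)
    else:
        shared = spec.phi_distribution.sample(rng_phi, spec.n_phi, floor=0.0)
        base = np.broadcast_to(shared, (n_levels, spec.n_s, spec.n_phi)).copy()
    phi_eff = base + ramp_by_level[:, None, None]
    # ramp is non-negative and draws are floored at 0, so phi_eff >= 0 holds
    g_t = np.repeat(grid, spec.n_s * spec.n_phi)
    s = np.tile(np.repeat(s_draws, spec.n_phi), n_levels)
    points = _solve_triples(g_t, s, phi_eff.ravel(), constants, tol)
    return SetPointCluster(points=points, spec=spec, constants=constants)


def cluster_summary(cluster: SetPointCluster, quantiles=(0.025, 0.25, 0.5, 0.75, 0.975)) -> dict:
    """Per-axis quantiles and a convex-hull descriptor of the point cloud.

    ``hull_area_fraction`` — hull area over the area of the bounding
    rectangle [min FT4, max FT4] × [min TSH, max TSH] — quantifies how far
    the cloud is from filling the rectangle implied by independent
    univariate reference intervals (the kite-vs-rectangle contrast).
    Degenerate clouds (fewer than 3 distinct points, or collinear) report a
    zero hull area.
    """
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    pts = cluster.points
    q = np.asarray(quantiles, dtype=float)
    summary = {
        "n": len(pts),
        "ft4_quantiles": dict(zip(q.tolist(), np.quantile(pts["ft4"], q).tolist())),
        "tsh_quantiles": dict(zip(q.tolist(), np.quantile(pts["tsh"], q).tolist())),
    }
    xy = pts[["ft4", "tsh"]].to_numpy()
    rect_area = float(np.ptp(xy[:, 0]) * np.ptp(xy[:, 1]))
    hull_area = 0.0
    if len(np.unique(xy, axis=0)) >= 3:
        try:
            hull_area = float(ConvexHull(xy).volume)  # 2-D: volume is the area
        except Exception:
            hull_area = 0.0  # collinear cloud
    summary["rect_area"] = rect_area
    summary["hull_area"] = hull_area
    summary["hull_area_fraction"] = hull_area / rect_area if rect_area > 0 else float("nan")
    return summary


def plot_cluster(cluster: SetPointCluster, path, overlay: pd.DataFrame | None = None) -> None:
    """Scatter of the cluster with log-scaled TSH axis; optional overlay of
    an observed cohort with 'ft4'/'tsh' columns. Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(cluster.points["ft4"], cluster.points["tsh"], s=2, c="black",
               alpha=0.3, label="simulated set points")
    if overlay is not None:
        ax.scatter(overlay["ft4"], overlay["tsh"], s=8, c="tab:blue",
                   alpha=0.6, label="observed")
    ax.set_yscale("log")
    ax.set_xlabel("FT4 (pmol/L)")
    ax.set_ylabel("TSH (mIU/L)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
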