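"""Closed-form results and diagnostics for reaction-norm populations.

Covers the linear three-trait norm ``y = a + b(u - c) + e``: the environment
``u0`` where phenotypic variance is minimal (the adaptive peak along the cue
axis, a population property), the Lande-style reference environment implied by
a G-matrix covariance, the PSD feasibility bounds on moving the reference via
G-matrix elements, and empirical assimilation metrics for step-response
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evolve import Trajectory, equilibrium_summary
from .model import psd_factor

__all__ = [
    "LinearThreeTraitParams",
    "variance_minimum_env",
    "empirical_variance_curve",
    "lande_reference_env",
    "psd_slope_bound",
    "psd_elevation_bound",
    "AssimilationReport",
    "assimilation_metrics",
]


@dataclass
class LinearThreeTraitParams:
    """Means and (co)variances of the linear norm ``y = a + b(u - c) + e``."""

    a_bar: float = 0.0
    b_bar: float = 1.0
    c_bar: float = 0.0
    Gaa: float = 0.0
    Gbb: float = 0.0
    Gcc: float = 0.0
    Gab: float = 0.0
    Gac: float = 0.0
    Gbc: float = 0.0
    sigma_e_sq: float = 0.0

    def __post_init__(self) -> None:
        G = self.G_matrix
        w = np.linalg.eigvalsh(G)
        tol = 1e-10 * max(np.abs(np.diag(G)).max(), 1.0)
        if w.min() < -tol:
            raise ValueError(
                f"G matrix assembled from parameters is not PSD "
                f"(min eigenvalue {w.min():.3g})"
            )
        if self.sigma_e_sq < 0:
            raise ValueError("sigma_e_sq must be non-negative")

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.a_bar, self.b_bar, self.c_bar])

    @property
    def G_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.Gaa, self.Gab, self.Gac],
                [self.Gab, self.Gbb, self.Gbc],
                [self.Gac, self.Gbc, self.Gcc],
            ]
        )


def variance_minimum_env(p: LinearThreeTraitParams) -> float:
    """Environment of minimal phenotypic variance: ``c̄ + (b̄ Gbc - Gab)/Gbb``.

    Reduces to ``u0 = c̄`` when ``Gab = Gbc = 0``.  Requires slope variance
    ``Gbb > 0``; with no slope variation the variance curve is flat and the
    minimum undefined.
    """
    if p.Gbb <= 0:
        raise ValueError("variance minimum undefined for Gbb <= 0 (flat curve)")
    return float(p.c_bar + (p.b_bar * p.Gbc - p.Gab) / p.Gbb)


def empirical_variance_curve(
    p: LinearThreeTraitParams,
    u_grid: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> tuple:
    """Monte-Carlo phenotypic variance across a cue grid, with its argmin.

    One common sample of ``n`` individuals is reused at every grid point
    (common random numbers), so the variance curve and its minimizer carry no
    between-point sampling jitter.  The argmin is refined parabolically
    around the discrete grid minimum when it is interior.

    Returns ``(variances, u0_hat)``.
    """
    u_grid = np.atleast_1d(np.asarray(u_grid, dtype=float))
    if u_grid.size == 0:
        raise ValueError("empty cue grid")
    F = psd_factor(p.G_matrix)
    z = p.mean + rng.standard_normal((n, 3)) @ F.T
    e = np.sqrt(p.sigma_e_sq) * rng.standard_normal(n)
    base = z[:, 0] + e - z[:, 1] * z[:, 2]  # a + e - b*c
    b = z[:, 1]
    variances = np.array(
        [np.var(base + b * u, ddof=1) for u in u_grid]
    )
    i = int(np.argmin(variances))
    u0_hat = u_grid[i]
    if 0 < i < len(u_grid) - 1:
        x0, x1, x2 = u_grid[i - 1 : i + 2]
        v0, v1, v2 = variances[i - 1 : i + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        if denom != 0:
            A = (x2 * (v1 - v0) + x1 * (v0 - v2) + x0 * (v2 - v1)) / denom
            Bc = (x2**2 * (v0 - v1) + x1**2 * (v2 - v0) + x0**2 * (v1 - v2)) / denom
            if A > 0:
                u0_hat = -Bc / (2 * A)
    return variances, float(u0_hat)


def lande_reference_env(Gab: float, Gbb: float) -> float:
    """Reference environment implied by slope-elevation covariance: -Gab/Gbb."""
    if Gbb <= 0:
        raise ValueError("lande_reference_env undefined for Gbb <= 0")
    return float(-Gab / Gbb)


def psd_slope_bound(Gaa: float, ratio: float) -> float:
    """Largest slope variance Gbb compatible with |Gab| <= sqrt(Gaa Gbb).

    ``ratio`` is the target Gab/Gbb (i.e. minus the desired reference
    environment).  A ratio of zero leaves Gbb unbounded.
    """
    if Gaa <= 0:
        raise ValueError("Gaa must be positive")
    if ratio == 0:
        raise ValueError("ratio = 0 leaves the slope variance unbounded")
    return float(Gaa / ratio**2)


def psd_elevation_bound(Gbb: float, ratio: float) -> float:
    """Smallest elevation variance Gaa compatible with |Gab| <= sqrt(Gaa Gbb)."""
    if Gbb <= 0:
        raise ValueError("Gbb must be positive")
    return float(ratio**2 * Gbb)


@dataclass
class AssimilationReport:
    """Pre/post-step comparison of slopes, positions and mean fitness."""

    slope_deltas: dict
    elevation_deltas: dict
    reference_deltas: dict
    fitness_delta: float
    fitness_se: float
    peak_slope_excursion: float
    complete: bool
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "slope_deltas": self.slope_deltas,
            "elevation_deltas": self.elevation_deltas,
            "reference_deltas": self.reference_deltas,
            "fitness_delta": self.fitness_delta,
            "fitness_se": self.fitness_se,
            "peak_slope_excursion": self.peak_slope_excursion,
            "complete": self.complete,
            "details": self.details,
        }


def assimilation_metrics(
    traj: Trajectory,
    pre_window: tuple,
    post_window: tuple,
    slope_tol: float = 0.05,
    expected_reference_step: dict | None = None,
    reference_tol: float = 0.3,
) -> AssimilationReport:
    """Quantify genetic assimilation between two stationary windows.

    Complete genetic assimilation: after a step in the mean environment the
    slope means and the mean fitness return to their pre-step stationary
    values, while elevation and reference means move to new equilibria (the
    reference means tracking the cue-mean step).  Windows use generation
    positions with Python slice semantics and must not overlap.

    ``expected_reference_step`` optionally maps reference trait names (e.g.
    ``"z_c_1"``) to the applied cue-mean step; when given, the complete flag
    additionally requires each reference delta to match within
    ``reference_tol``.
    """
    if not pre_window[1] <= post_window[0]:
        raise ValueError("pre and post windows overlap")
    pre = equilibrium_summary(traj, pre_window)
    post = equilibrium_summary(traj, post_window)

    slope = [n for n in traj.trait_names if n.startswith("z_b")]
    elev = [n for n in traj.trait_names if n.startswith("z_a")]
    ref = [n for n in traj.trait_names if n.startswith("z_c")]

    slope_deltas = {
        n: float(abs(post.loc[n, "mean"] - pre.loc[n, "mean"])) for n in slope
    }
    elevation_deltas = {
        n: float(post.loc[n, "mean"] - pre.loc[n, "mean"]) for n in elev
    }
    reference_deltas = {
        n: float(post.loc[n, "mean"] - pre.loc[n, "mean"]) for n in ref
    }
    fitness_delta = float(post.loc["W_bar", "mean"] - pre.loc["W_bar", "mean"])
    fitness_se = float(
        np.sqrt(pre.loc["W_bar", "se"] ** 2 + post.loc["W_bar", "se"] ** 2)
    )

    # Largest transient slope deviation from the pre-step stationary means,
    # over the generations between the two windows.
    lo, hi = pre_window[1], post_window[0]
    peak = 0.0
    if hi > lo:
        between = traj.means[1:][lo:hi]
        for n in slope:
            j = traj.trait_names.index(n)
            dev = np.max(np.abs(between[:, j] - pre.loc[n, "mean"]))
            peak = max(peak, float(dev))

    slopes_ok = all(d < slope_tol for d in slope_deltas.values())
    fitness_ok = abs(fitness_delta) < 2.0 * fitness_se if fitness_se > 0 else True
    refs_ok = True
    if expected_reference_step is not None:
        for n, step in expected_reference_step.items():
            if abs(reference_deltas.get(n, np.nan) - step) > reference_tol:
                refs_ok = False
    complete = slopes_ok and fitness_ok and refs_ok
    return AssimilationReport(
        slope_deltas=slope_deltas,
        elevation_deltas=elevation_deltas,
        reference_deltas=reference_deltas,
        fitness_delta=fitness_delta,
        fitness_se=fitness_se,
        peak_slope_excursion=peak,
        complete=complete,
        details={
            "slopes_ok": slopes_ok,
            "fitness_ok": fitness_ok,
            "references_ok": refs_ok,
            "pre_window": list(pre_window),
            "post_window": list(post_window),
        },
    )
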