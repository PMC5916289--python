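"""Propagation of the population mean with the augmented breeder's equation.

Per generation the mean trait vector moves by

    dz = G_aug @ beta,    beta = P_aug^{-1} cov(W_i, z_i) / W_bar,

where the selection covariance cov(W, z) and the mean fitness W_bar are
Monte-Carlo estimates over ``n`` individuals sampled from the current
multinormal trait distribution.  G_aug and P_aug are constant: only the means
evolve; sampling noise is an estimator artifact, not drift.

Traits with zero phenotypic variance (zero row/column of P_aug, e.g. pinned
reference traits with G_cc = 0) are excluded from the inverted subspace; their
selection gradient is zero by convention and their means stay exactly
constant whenever the matching rows of G_aug are zero.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .environment import EnvironmentModel, draw_generation
from .fitness import FitnessSpec, individual_fitness
from .model import (
    PopulationState,
    ReactionNormSpec,
    phenotype_batch,
    psd_factor,
    validate_state,
)

__all__ = [
    "BreederStep",
    "Trajectory",
    "SimulationConfig",
    "sample_individuals",
    "breeder_update",
    "simulate",
    "equilibrium_summary",
]

_VARIANCE_TOL = 1e-12


@dataclass
class BreederStep:
    """Diagnostics of one generation's update (all over the flat layout)."""

    selection_cov: np.ndarray
    mean_fitness: float
    gradient: np.ndarray
    delta_mean: np.ndarray


@dataclass
class Trajectory:
    """Per-generation record of a simulation run.

    ``means`` has ``n_generations + 1`` rows; row 0 is the initial state and
    row ``t`` the mean after the update of generation ``t``.  ``w_bar``,
    ``beta``, ``u`` and ``theta`` have one row per generation (the realized
    environment and selection response of that generation).
    """

    trait_names: list
    means: np.ndarray
    w_bar: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    theta: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_generations(self) -> int:
        return self.w_bar.shape[0]

    def to_frame(self, include_initial: bool = False) -> pd.DataFrame:
        """One row per generation; optionally prepend the initial state."""
        T = self.n_generations
        data = {"t": np.arange(1, T + 1)}
        for j, name in enumerate(self.trait_names):
            data[name] = self.means[1:, j]
        data["W_bar"] = self.w_bar
        for j, name in enumerate(self.trait_names):
            data[f"beta_{name}"] = self.beta[:, j]
        for j in range(self.u.shape[1]):
            data[f"u_{j + 1}"] = self.u[:, j]
        for j in range(self.theta.shape[1]):
            data[f"theta_{j + 1}"] = self.theta[:, j]
        frame = pd.DataFrame(data)
        if include_initial:
            init = {c: [np.nan] for c in frame.columns}
            init["t"] = [0]
            for j, name in enumerate(self.trait_names):
                init[name] = [self.means[0, j]]
            frame = pd.concat([pd.DataFrame(init), frame], ignore_index=True)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Trajectory":
        cols = list(frame.columns)
        for required in ("t", "W_bar"):
            if required not in cols:
                raise ValueError(
                    f"trajectory table is missing required column '{required}'"
                )
        trait_names = [c for c in cols if c.startswith("z_")]
        if not trait_names:
            raise ValueError("trajectory table has no trait columns (z_*)")
        T = len(frame)
        means = np.vstack(
            [frame[trait_names].to_numpy()[:1], frame[trait_names].to_numpy()]
        )
        beta_cols = [f"beta_{n}" for n in trait_names]
        beta = (
            frame[beta_cols].to_numpy()
            if all(c in cols for c in beta_cols)
            else np.zeros((T, len(trait_names)))
        )
        u_cols = sorted(
            (c for c in cols if c.startswith("u_")), key=lambda c: int(c[2:])
        )
        th_cols = sorted(
            (c for c in cols if c.startswith("theta_")), key=lambda c: int(c[6:])
        )
        u = frame[u_cols].to_numpy() if u_cols else np.zeros((T, 0))
        theta = frame[th_cols].to_numpy() if th_cols else np.zeros((T, 0))
        return cls(
            trait_names=trait_names,
            means=means,
            w_bar=frame["W_bar"].to_numpy(dtype=float),
            beta=np.asarray(beta, dtype=float),
            u=np.asarray(u, dtype=float),
            theta=np.asarray(theta, dtype=float),
            metadata={"source": "table"},
        )

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class SimulationConfig:
    """Complete description of one simulation run."""

    spec: ReactionNormSpec
    state: PopulationState
    fitness: FitnessSpec
    environment: EnvironmentModel
    n_individuals: int
    n_generations: int
    seed: int
    notes: dict = field(default_factory=dict)


def _child_rng(seed: int, stream: int, t: int) -> np.random.Generator:
    # Deterministic per-generation streams: the environment stream (0, t) is
    # identical across runs that differ only in n_individuals.
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(stream, t))
    return np.random.Generator(np.random.PCG64(ss))


def sample_individuals(
    state: PopulationState,
    spec: ReactionNormSpec,
    n: int,
    rng: np.random.Generator,
    trait_factor: np.ndarray | None = None,
    resid_factor: np.ndarray | None = None,
) -> tuple:
    """Sample n individuals: traits ~ N(mean, P_aug), residuals ~ N(0, resid_cov).

    Residuals are independent of traits.  The optional precomputed factors
    avoid refactorizing constant covariances inside simulation loops.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    if trait_factor is None:
        trait_factor = psd_factor(state.P_aug)
    if resid_factor is None:
        resid_factor = psd_factor(state.resid_cov)
    z = state.mean + rng.standard_normal((n, trait_factor.shape[1])) @ trait_factor.T
    e = rng.standard_normal((n, resid_factor.shape[1])) @ resid_factor.T
    return z, e


def _selection_stats(W: np.ndarray, z: np.ndarray) -> tuple:
    """Sample mean fitness and unbiased cov(W, z) over individuals."""
    n = W.shape[0]
    w_bar = float(W.mean())
    dz = z - z.mean(axis=0)
    s = dz.T @ (W - w_bar) / (n - 1)
    return w_bar, s


class _GradientSolver:
    """Solve P_aug beta = s on the positive-variance trait subspace."""

    def __init__(self, P_aug: np.ndarray):
        diag = np.diag(P_aug)
        scale = max(diag.max(), 1.0) if diag.size else 1.0
        self.active = diag > _VARIANCE_TOL * scale
        self.dim = P_aug.shape[0]
        if self.active.any():
            block = P_aug[np.ix_(self.active, self.active)]
            try:
                self._cho = cho_factor(block)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "P_aug is singular on its positive-variance block; drop "
                    "zero-variance or collinear traits from the state"
                ) from err
        else:
            self._cho = None

    def __call__(self, s: np.ndarray, w_bar: float) -> np.ndarray:
        beta = np.zeros(self.dim)
        if self._cho is not None:
            beta[self.active] = cho_solve(self._cho, s[self.active]) / w_bar
        return beta


def breeder_update(
    state: PopulationState,
    spec: ReactionNormSpec,
    fitness_spec: FitnessSpec,
    u: np.ndarray,
    theta: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> tuple:
    """One generation of the augmented multivariate breeder's equation.

    Returns the new :class:`PopulationState` (updated mean, unchanged
    covariances) and a :class:`BreederStep` with the Monte-Carlo selection
    covariance, mean fitness, gradient and mean change.
    """
    if n < 2:
        raise ValueError("breeder_update needs n >= 2 individuals")
    report = validate_state(state, spec)
    if not report:
        raise ValueError(
            "invalid population state: " + "; ".join(report.violations)
        )
    solver = _GradientSolver(state.P_aug)
    z, e = sample_individuals(state, spec, n, rng)
    y = phenotype_batch(spec, z, e, u)
    W = individual_fitness(fitness_spec, y, theta, z[:, spec.slice_b])
    w_bar, s = _selection_stats(W, z)
    beta = solver(s, w_bar)
    delta = state.G_aug @ beta
    step = BreederStep(
        selection_cov=s, mean_fitness=w_bar, gradient=beta, delta_mean=delta
    )
    return state.with_mean(state.mean + delta), step


def simulate(config: SimulationConfig, progress=None) -> Trajectory:
    """Run a full simulation: iterate environment draws and breeder updates.

    Deterministic given ``config.seed``: environment draws use one child
    stream per generation and individual sampling another, so the realized
    environment sequence does not depend on ``n_individuals``.  ``progress``
    is an optional callback ``(t, w_bar, max_abs_beta)`` invoked at 10%
    milestones.
    """
    spec, state = config.spec, config.state
    report = validate_state(state, spec)
    if not report:
        raise ValueError(
            "invalid population state: " + "; ".join(report.violations)
        )
    env = config.environment
    if env.q != spec.n_cues or env.m != spec.n_phenotypes:
        raise ValueError("environment dimensions do not match the reaction norm")
    T = int(config.n_generations)
    n = int(config.n_individuals)
    if T < 0:
        raise ValueError("n_generations must be >= 0")
    if T > 0 and n < 2:
        raise ValueError("n_individuals must be >= 2")

    dim = spec.dim
    means = np.empty((T + 1, dim))
    means[0] = state.mean
    w_bar_arr = np.empty(T)
    beta_arr = np.empty((T, dim))
    u_arr = np.empty((T, env.q))
    theta_arr = np.empty((T, env.m))

    trait_factor = psd_factor(state.P_aug)
    resid_factor = psd_factor(state.resid_cov)
    solver = _GradientSolver(state.P_aug)
    G = state.G_aug
    slice_b = spec.slice_b
    env.factor()  # pre-build

    milestone = max(1, T // 10)
    mean = state.mean.copy()
    cur = state
    for g in range(T):
        t = g + 1
        u, theta = draw_generation(env, t, _child_rng(config.seed, 0, t))
        rng = _child_rng(config.seed, 1, t)
        z, e = sample_individuals(
            cur, spec, n, rng, trait_factor=trait_factor, resid_factor=resid_factor
        )
        y = phenotype_batch(spec, z, e, u)
        W = individual_fitness(config.fitness, y, theta, z[:, slice_b])
        w_bar, s = _selection_stats(W, z)
        beta = solver(s, w_bar)
        mean = mean + G @ beta
        if not np.all(np.isfinite(mean)):
            raise RuntimeError(
                f"non-finite mean state at generation {t}; check fitness "
                f"width and covariance scales (W_bar={w_bar:.3g})"
            )
        cur = cur.with_mean(mean)
        means[t] = mean
        w_bar_arr[g] = w_bar
        beta_arr[g] = beta
        u_arr[g] = u
        theta_arr[g] = theta
        if progress is not None and (t % milestone == 0 or t == T):
            progress(t, w_bar, float(np.max(np.abs(beta))))

    metadata = {
        "seed": int(config.seed),
        "n_individuals": n,
        "n_generations": T,
        "config_hash": config_hash(config),
    }
    metadata.update(config.notes)
    return Trajectory(
        trait_names=list(spec.trait_names),
        means=means,
        w_bar=w_bar_arr,
        beta=beta_arr,
        u=u_arr,
        theta=theta_arr,
        metadata=metadata,
    )


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of the numerical content of a configuration."""
    payload = {
        "spec": config.spec.to_dict(),
        "mean": config.state.mean.tolist(),
        "G_aug": config.state.G_aug.tolist(),
        "P_aug": config.state.P_aug.tolist(),
        "resid_cov": config.state.resid_cov.tolist(),
        "fitness": config.fitness.to_dict(),
        "environment": config.environment.to_dict(),
        "n_individuals": int(config.n_individuals),
        "n_generations": int(config.n_generations),
        "seed": int(config.seed),
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def equilibrium_summary(
    traj: Trajectory, window: tuple, n_batches: int = 20
) -> pd.DataFrame:
    """Time averages with batch-means standard errors over a window.

    ``window = (lo, hi)`` selects generations ``lo:hi`` (0-based positions
    into the per-generation records, Python slice semantics).  The returned
    frame is indexed by quantity (trait means, ``W_bar``, gradient
    components) with columns ``mean`` and ``se``.  A window of length 1 has
    undefined standard errors (NaN, with a warning).
    """
    lo, hi = int(window[0]), int(window[1])
    T = traj.n_generations
    if not (0 <= lo < hi <= T):
        raise ValueError(f"window {window} is empty or outside 0..{T}")
    M = traj.means[1:][lo:hi]
    wb = traj.w_bar[lo:hi]
    be = traj.beta[lo:hi]
    series = np.column_stack([M, wb[:, None], be])
    names = (
        list(traj.trait_names)
        + ["W_bar"]
        + [f"beta_{n}" for n in traj.trait_names]
    )
    mean = series.mean(axis=0)
    L = series.shape[0]
    if L < 2:
        warnings.warn(
            "window of length 1: standard errors are undefined", stacklevel=2
        )
        se = np.full(series.shape[1], np.nan)
    else:
        B = min(n_batches, L)
        batches = np.array_split(series, B, axis=0)
        bm = np.array([b.mean(axis=0) for b in batches])
        se = bm.std(axis=0, ddof=1) / np.sqrt(B)
    out = pd.DataFrame({"mean": mean, "se": se}, index=names)
    out.attrs["window"] = (lo, hi)
    out.attrs["n"] = L
    return out
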