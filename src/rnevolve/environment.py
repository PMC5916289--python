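"""Stationary stochastic environments with optional step changes in means.

Each generation receives one joint multinormal draw of the developmental cue
vector ``u_t`` (q entries) and the fitness optimum ``theta_t`` (m entries).
Draws are white across generations (no autocorrelation); non-stationarity
enters only through a schedule of step changes in the means, as in the
step-response experiments.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import psd_factor

__all__ = [
    "EnvironmentStep",
    "EnvironmentModel",
    "draw_generation",
    "chevin_lande_theta",
    "build_two_cue_selection_environment",
    "environment_to_frame",
]


@dataclass
class EnvironmentStep:
    """Mean shift applied from generation ``t`` onward."""

    t: int
    mu_u: np.ndarray
    mu_theta: np.ndarray

    def __post_init__(self) -> None:
        self.t = int(self.t)
        self.mu_u = np.atleast_1d(np.asarray(self.mu_u, dtype=float))
        self.mu_theta = np.atleast_1d(np.asarray(self.mu_theta, dtype=float))


@dataclass
class EnvironmentModel:
    """Joint distribution of (u, theta) with a step schedule on the means.

    ``joint_cov`` is the (q+m, q+m) covariance of the stacked vector
    ``(u_1..u_q, theta_1..theta_m)``; it is constant over time.
    """

    mu_u: np.ndarray
    mu_theta: np.ndarray
    joint_cov: np.ndarray
    steps: tuple = ()

    def __post_init__(self) -> None:
        self.mu_u = np.atleast_1d(np.asarray(self.mu_u, dtype=float))
        self.mu_theta = np.atleast_1d(np.asarray(self.mu_theta, dtype=float))
        self.joint_cov = np.atleast_2d(np.asarray(self.joint_cov, dtype=float))
        d = self.q + self.m
        if self.joint_cov.shape != (d, d):
            raise ValueError(
                f"joint_cov shape {self.joint_cov.shape} != {(d, d)}"
            )
        steps = []
        for s in self.steps:
            if not isinstance(s, EnvironmentStep):
                s = EnvironmentStep(*s)
            if s.mu_u.shape != (self.q,) or s.mu_theta.shape != (self.m,):
                raise ValueError("step means do not match environment dimensions")
            steps.append(s)
        ts = [s.t for s in steps]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("step generations must be strictly increasing")
        self.steps = tuple(steps)
        self._step_ts = ts
        self._factor = None

    @property
    def q(self) -> int:
        return self.mu_u.shape[0]

    @property
    def m(self) -> int:
        return self.mu_theta.shape[0]

    def means_at(self, t: int) -> tuple:
        """Active (mu_u, mu_theta) at generation ``t`` under the schedule."""
        i = bisect.bisect_right(self._step_ts, int(t)) - 1
        if i < 0:
            return self.mu_u, self.mu_theta
        s = self.steps[i]
        return s.mu_u, s.mu_theta

    def factor(self) -> np.ndarray:
        if self._factor is None:
            self._factor = psd_factor(self.joint_cov)
        return self._factor

    def to_dict(self) -> dict:
        return {
            "mu_u": list(map(float, self.mu_u)),
            "mu_theta": list(map(float, self.mu_theta)),
            "joint_cov": self.joint_cov.tolist(),
            "steps": [
                {
                    "t": s.t,
                    "mu_u": list(map(float, s.mu_u)),
                    "mu_theta": list(map(float, s.mu_theta)),
                }
                for s in self.steps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentModel":
        return cls(
            mu_u=d["mu_u"],
            mu_theta=d["mu_theta"],
            joint_cov=np.asarray(d["joint_cov"], dtype=float),
            steps=tuple(
                EnvironmentStep(s["t"], s["mu_u"], s["mu_theta"])
                for s in d.get("steps", ())
            ),
        )


def draw_generation(
    model: EnvironmentModel, t: int, rng: np.random.Generator
) -> tuple:
    """One joint (u, theta) draw for generation ``t``.

    Means follow the step schedule active at ``t``; the covariance is
    constant.  Successive calls with independent streams give a white
    environment process.
    """
    mu_u, mu_theta = model.means_at(t)
    F = model.factor()
    x = np.concatenate([mu_u, mu_theta]) + F @ rng.standard_normal(F.shape[1])
    return x[: model.q], x[model.q :]


def chevin_lande_theta(eps_s: np.ndarray, B: float = 1.0) -> float:
    """Optimum from two selection environments: ``theta = B (eps1 + eps2)``.

    The scaling ``B`` makes the mean optimum ``B (mu_U1 + mu_U2)`` when the
    selection environments share the developmental means.
    """
    eps_s = np.atleast_1d(np.asarray(eps_s, dtype=float))
    return float(B * np.sum(eps_s))


def build_two_cue_selection_environment(
    mu_cue: np.ndarray = (1.0, 1.0),
    var_eps: float = 0.5,
    corr_cues: float = 0.5,
    corr_dev_sel: float = 0.8,
    B: float = 1.0,
) -> EnvironmentModel:
    """Two correlated cues with an optimum built from selection environments.

    Latent environments ``(eps_1d, eps_2d, eps_1s, eps_2s)`` share variance
    ``var_eps``; correlation between cue indices is ``corr_cues`` and between
    the developmental and selection stage of the same construction
    ``corr_dev_sel`` (cross terms follow the Kronecker-product structure,
    which guarantees a PSD covariance).  Cues are the developmental pair,
    the optimum is ``theta = B (eps_1s + eps_2s)``.
    """
    mu_cue = np.atleast_1d(np.asarray(mu_cue, dtype=float))
    if mu_cue.shape != (2,):
        raise ValueError("mu_cue must have two entries")
    C_cue = np.array([[1.0, corr_cues], [corr_cues, 1.0]])
    C_stage = np.array([[1.0, corr_dev_sel], [corr_dev_sel, 1.0]])
    cov_eps = var_eps * np.kron(C_stage, C_cue)  # order: (1d, 2d, 1s, 2s)
    # Linear map (eps) -> (u1, u2, theta)
    M = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, B, B],
        ]
    )
    joint_cov = M @ cov_eps @ M.T
    mu_theta = chevin_lande_theta(mu_cue, B=B)
    return EnvironmentModel(mu_u=mu_cue, mu_theta=[mu_theta], joint_cov=joint_cov)


def environment_to_frame(
    model: EnvironmentModel, n_generations: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw a whole environment sequence as a tidy table (t, u_*, theta_*)."""
    rows = np.empty((n_generations, model.q + model.m))
    for t in range(n_generations):
        u, th = draw_generation(model, t, rng)
        rows[t, : model.q] = u
        rows[t, model.q :] = th
    cols = [f"u_{j + 1}" for j in range(model.q)] + [
        f"theta_{i + 1}" for i in range(model.m)
    ]
    frame = pd.DataFrame(rows, columns=cols)
    frame.insert(0, "t", np.arange(n_generations))
    return frame
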