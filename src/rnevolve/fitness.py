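"""Gaussian stabilizing selection on the multivariate phenotype.

Individual fitness decays with the squared mismatch between the expressed
phenotype ``y`` and the optimum ``theta`` drawn for the generation:

    W = W_max * exp(-D / (2 omega^2)) * exp(-sum_k cost_k z_b_k^2 / (2 omega^2))

with ``D = sum_j (y_j - theta_j)^2`` (default) or ``(sum_j (y_j - theta_j))^2``
for the alternative squared-sum form.  The optional second factor is a cost of
plasticity on slope magnitude; with no cost coefficients the fitness path is
bit-identical to the cost-free form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitnessSpec", "individual_fitness", "mean_fitness"]

MISMATCH_FORMS = ("sum_of_squares", "squared_sum")


@dataclass
class FitnessSpec:
    """Gaussian fitness parameters.

    omega_sq is the width of the fitness function (squared phenotype units);
    larger omega_sq means weaker stabilizing selection.  cost_coeffs, if
    given, is a non-negative vector over the slope traits.
    """

    omega_sq: float
    w_max: float = 1.0
    cost_coeffs: np.ndarray | None = None
    mismatch_form: str = "sum_of_squares"

    def __post_init__(self) -> None:
        self.omega_sq = float(self.omega_sq)
        self.w_max = float(self.w_max)
        if self.omega_sq <= 0:
            raise ValueError("omega_sq must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        if self.mismatch_form not in MISMATCH_FORMS:
            raise ValueError(
                f"mismatch_form must be one of {MISMATCH_FORMS}; "
                f"got {self.mismatch_form!r}"
            )
        if self.cost_coeffs is not None:
            cc = np.atleast_1d(np.asarray(self.cost_coeffs, dtype=float))
            if np.any(cc < 0):
                raise ValueError("cost_coeffs must be non-negative")
            self.cost_coeffs = cc

    @property
    def has_cost(self) -> bool:
        return self.cost_coeffs is not None and bool(np.any(self.cost_coeffs > 0))

    def to_dict(self) -> dict:
        return {
            "omega_sq": self.omega_sq,
            "w_max": self.w_max,
            "cost_coeffs": None
            if self.cost_coeffs is None
            else list(map(float, self.cost_coeffs)),
            "mismatch_form": self.mismatch_form,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitnessSpec":
        return cls(
            omega_sq=d["omega_sq"],
            w_max=d.get("w_max", 1.0),
            cost_coeffs=d.get("cost_coeffs"),
            mismatch_form=d.get("mismatch_form", "sum_of_squares"),
        )


def _mismatch(spec: FitnessSpec, y: np.ndarray, theta: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    dev = np.atleast_1d(y - theta) if y.ndim <= 1 else y - theta
    if dev.shape[-1] != np.atleast_1d(theta).shape[-1]:
        raise ValueError("phenotype and optimum dimensions do not match")
    if spec.mismatch_form == "sum_of_squares":
        return np.sum(dev**2, axis=-1)
    return np.sum(dev, axis=-1) ** 2


def individual_fitness(
    spec: FitnessSpec,
    y: np.ndarray,
    theta: np.ndarray,
    z_b: np.ndarray | None = None,
) -> np.ndarray:
    """Fitness of one individual (or a batch, last axis = phenotypes).

    ``z_b`` is only consulted when the spec carries cost coefficients.
    Returns values in (0, w_max].
    """
    D = _mismatch(spec, y, theta)
    W = spec.w_max * np.exp(-D / (2.0 * spec.omega_sq))
    if spec.has_cost:
        if z_b is None:
            raise ValueError("cost_coeffs set but no slope traits supplied")
        z_b = np.asarray(z_b, dtype=float)
        if z_b.shape[-1] != spec.cost_coeffs.shape[0]:
            raise ValueError("z_b length does not match cost_coeffs")
        cost = np.sum(spec.cost_coeffs * z_b**2, axis=-1)
        W = W * np.exp(-cost / (2.0 * spec.omega_sq))
    return W


def mean_fitness(
    spec: FitnessSpec,
    y_sample: np.ndarray,
    theta: np.ndarray,
    z_b_sample: np.ndarray | None = None,
) -> float:
    """Monte-Carlo mean fitness over a sample of individuals (strictly > 0)."""
    y_sample = np.asarray(y_sample, dtype=float)
    if y_sample.size == 0:
        raise ValueError("empty fitness sample")
    W = individual_fitness(spec, y_sample, theta, z_b_sample)
    return float(np.mean(W))
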