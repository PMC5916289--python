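"""Trait-space types and polynomial reaction-norm evaluation.

A reaction norm maps an environmental cue vector ``u`` to the phenotype an
individual expresses.  Here reaction norms are parametrized by three groups of
quantitative traits:

* elevation traits ``z_a`` (one per phenotype),
* slope/shape traits ``z_b`` (coefficients of cue-product monomials),
* reference traits ``z_c`` (one per cue; the cue value where the plastic part
  of the norm vanishes — an evolvable "perception" trait).

The phenotype of an individual is

    y = z_a + Z_b @ prods(u - z_c) + e_resid

where ``prods`` expands the shifted cues into the monomial basis declared by a
:class:`ReactionNormSpec` (e.g. ``u1-c1``, ``(u1-c1)^2``, ``(u1-c1)(u2-c2)``).
The population state carries the mean trait vector together with the additive
genetic covariance ``G_aug`` and the phenotypic-trait covariance ``P_aug``
over the flat trait layout ``(z_a | active z_b, column-major | z_c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "ReactionNormSpec",
    "IndividualTraits",
    "PopulationState",
    "ValidationReport",
    "expand_cue_products",
    "phenotype",
    "phenotype_batch",
    "validate_state",
]

# Relative eigenvalue tolerance for PSD checks (float-safe boundary cases).
PSD_TOL_SCALE = 1e-10


@dataclass
class ReactionNormSpec:
    """Structure of a polynomial (cue-product) reaction norm.

    Parameters
    ----------
    n_phenotypes : int
        Number of phenotypic variables ``m``.
    n_cues : int
        Number of environmental cues ``q``.
    products : sequence of q-tuples of non-negative ints
        Exponent vectors of the ``p`` cue-product monomials; entry ``k`` with
        exponents ``e_k`` stands for ``prod_j (u_j - z_c_j)**e_kj``.  Every
        monomial must have total degree >= 1 (the constant term is the
        elevation trait, not a product).
    coeff_mask : (m, p) array-like of bool, optional
        Which slope coefficients are structurally present; absent entries are
        fixed at zero and carry no trait.  Default: all present.
    """

    n_phenotypes: int
    n_cues: int
    products: tuple
    coeff_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        m, q = int(self.n_phenotypes), int(self.n_cues)
        if m < 1 or q < 1:
            raise ValueError("n_phenotypes and n_cues must be >= 1")
        self.n_phenotypes, self.n_cues = m, q
        prods = tuple(tuple(int(e) for e in expo) for expo in self.products)
        if len(prods) < 1:
            raise ValueError("at least one cue product is required (p >= 1)")
        for expo in prods:
            if len(expo) != q:
                raise ValueError(
                    f"exponent vector {expo} does not match n_cues={q}"
                )
            if any(e < 0 for e in expo):
                raise ValueError(f"negative exponent in {expo}")
            if sum(expo) < 1:
                raise ValueError(
                    f"cue product {expo} has total degree 0; every product "
                    "must involve at least one cue"
                )
        self.products = prods
        if self.coeff_mask is None:
            mask = np.ones((m, self.p), dtype=bool)
        else:
            mask = np.asarray(self.coeff_mask, dtype=bool)
            if mask.shape != (m, self.p):
                raise ValueError(
                    f"coeff_mask shape {mask.shape} != (m, p) = {(m, self.p)}"
                )
        self.coeff_mask = mask
        if not mask.any():
            raise ValueError("coeff_mask has no active slope coefficients")

    # -- layout -----------------------------------------------------------

    @property
    def p(self) -> int:
        """Number of cue-product monomials."""
        return len(self.products)

    @cached_property
    def active_entries(self) -> tuple:
        """Active ``(row, col)`` slope positions in column-major order."""
        m, p = self.n_phenotypes, self.p
        return tuple(
            (r, c) for c in range(p) for r in range(m) if self.coeff_mask[r, c]
        )

    @property
    def n_active(self) -> int:
        return len(self.active_entries)

    @property
    def dim(self) -> int:
        """Flat trait dimension m + n_active + q."""
        return self.n_phenotypes + self.n_active + self.n_cues

    @property
    def slice_a(self) -> slice:
        return slice(0, self.n_phenotypes)

    @property
    def slice_b(self) -> slice:
        return slice(self.n_phenotypes, self.n_phenotypes + self.n_active)

    @property
    def slice_c(self) -> slice:
        return slice(self.n_phenotypes + self.n_active, self.dim)

    @cached_property
    def trait_names(self) -> list:
        names = [f"z_a_{i + 1}" for i in range(self.n_phenotypes)]
        names += [f"z_b_b{r + 1}{c + 1}" for r, c in self.active_entries]
        names += [f"z_c_{j + 1}" for j in range(self.n_cues)]
        return names

    # -- slope (de)flattening ---------------------------------------------

    def flatten_zb(self, Zb: np.ndarray) -> np.ndarray:
        """Extract the active entries of an (m, p) slope matrix, column-major."""
        Zb = np.asarray(Zb, dtype=float)
        if Zb.shape != (self.n_phenotypes, self.p):
            raise ValueError(f"Z_b shape {Zb.shape} != {(self.n_phenotypes, self.p)}")
        return np.array([Zb[r, c] for r, c in self.active_entries])

    def unflatten_zb(self, z_b: np.ndarray) -> np.ndarray:
        """Rebuild the (m, p) slope matrix; masked-out entries are zero."""
        z_b = np.asarray(z_b, dtype=float)
        if z_b.shape != (self.n_active,):
            raise ValueError(f"z_b length {z_b.shape} != ({self.n_active},)")
        Zb = np.zeros((self.n_phenotypes, self.p))
        for k, (r, c) in enumerate(self.active_entries):
            Zb[r, c] = z_b[k]
        return Zb

    # -- constructors ------------------------------------------------------

    @classmethod
    def linear(cls, n_cues: int = 1, n_phenotypes: int = 1) -> "ReactionNormSpec":
        """First-order norm: one linear slope per cue, all coefficients active."""
        prods = tuple(
            tuple(1 if j == k else 0 for j in range(n_cues)) for k in range(n_cues)
        )
        return cls(n_phenotypes=n_phenotypes, n_cues=n_cues, products=prods)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_phenotypes": self.n_phenotypes,
            "n_cues": self.n_cues,
            "products": [list(e) for e in self.products],
            "coeff_mask": self.coeff_mask.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNormSpec":
        return cls(
            n_phenotypes=d["n_phenotypes"],
            n_cues=d["n_cues"],
            products=tuple(tuple(e) for e in d["products"]),
            coeff_mask=np.asarray(d["coeff_mask"], dtype=bool)
            if d.get("coeff_mask") is not None
            else None,
        )


@dataclass
class IndividualTraits:
    """One individual's reaction-norm traits and phenotypic residual."""

    z_a: np.ndarray
    z_b: np.ndarray
    z_c: np.ndarray
    e_resid: np.ndarray

    def __post_init__(self) -> None:
        self.z_a = np.atleast_1d(np.asarray(self.z_a, dtype=float))
        self.z_b = np.atleast_1d(np.asarray(self.z_b, dtype=float))
        self.z_c = np.atleast_1d(np.asarray(self.z_c, dtype=float))
        self.e_resid = np.atleast_1d(np.asarray(self.e_resid, dtype=float))
        for name in ("z_a", "z_b", "z_c", "e_resid"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    def check(self, spec: ReactionNormSpec) -> None:
        if self.z_a.shape != (spec.n_phenotypes,):
            raise ValueError("z_a length does not match spec")
        if self.z_b.shape != (spec.n_active,):
            raise ValueError("z_b length does not match spec")
        if self.z_c.shape != (spec.n_cues,):
            raise ValueError("z_c length does not match spec")
        if self.e_resid.shape != (spec.n_phenotypes,):
            raise ValueError("e_resid length does not match spec")


@dataclass
class PopulationState:
    """Population mean state with constant (co)variance structure.

    ``mean`` is the flat mean trait vector over the spec's layout.  ``G_aug``
    is the additive genetic covariance over the same layout, ``P_aug`` the
    phenotypic-trait covariance (``P_aug - G_aug`` is the covariance of the
    non-additive trait component and must be PSD).  ``resid_cov`` is the
    covariance of the phenotype-level residual ``e_resid``.
    """

    mean: np.ndarray
    G_aug: np.ndarray
    P_aug: np.ndarray
    resid_cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.G_aug = np.atleast_2d(np.asarray(self.G_aug, dtype=float))
        self.P_aug = np.atleast_2d(np.asarray(self.P_aug, dtype=float))
        self.resid_cov = np.atleast_2d(np.asarray(self.resid_cov, dtype=float))

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def with_mean(self, mean: np.ndarray) -> "PopulationState":
        return PopulationState(
            mean=np.asarray(mean, dtype=float),
            G_aug=self.G_aug,
            P_aug=self.P_aug,
            resid_cov=self.resid_cov,
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_state`: ``ok`` plus named violations."""

    ok: bool
    violations: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def expand_cue_products(
    spec: ReactionNormSpec, u: np.ndarray, z_c: np.ndarray
) -> np.ndarray:
    """Evaluate the p cue-product monomials at shifted cues ``u - z_c``.

    ``u`` and ``z_c`` may carry leading batch dimensions; they broadcast
    against each other.  Entry ``k`` of the result equals
    ``prod_j (u_j - z_c_j)**e_kj``.
    """
    u = np.asarray(u, dtype=float)
    z_c = np.asarray(z_c, dtype=float)
    if u.shape[-1] != spec.n_cues or z_c.shape[-1] != spec.n_cues:
        raise ValueError(
            f"cue vectors must have length q={spec.n_cues}; "
            f"got u{u.shape}, z_c{z_c.shape}"
        )
    d = u - z_c
    out = np.ones(d.shape[:-1] + (spec.p,))
    for k, expo in enumerate(spec.products):
        for j, e in enumerate(expo):
            if e == 1:
                out[..., k] *= d[..., j]
            elif e > 1:
                out[..., k] *= d[..., j] ** e
    return out


def phenotype(
    spec: ReactionNormSpec, ind: IndividualTraits, u: np.ndarray
) -> np.ndarray:
    """Phenotype of one individual: ``y = z_a + Z_b @ prods(u - z_c) + e``."""
    ind.check(spec)
    u = np.asarray(u, dtype=float)
    prods = expand_cue_products(spec, u, ind.z_c)
    Zb = spec.unflatten_zb(ind.z_b)
    return ind.z_a + Zb @ prods + ind.e_resid


def phenotype_batch(
    spec: ReactionNormSpec,
    traits: np.ndarray,
    e_resid: np.ndarray | None,
    u: np.ndarray,
) -> np.ndarray:
    """Phenotypes for an (n, dim) block of flat trait vectors at cue ``u``."""
    traits = np.asarray(traits, dtype=float)
    if traits.ndim != 2 or traits.shape[1] != spec.dim:
        raise ValueError(f"traits must be (n, {spec.dim}); got {traits.shape}")
    prods = expand_cue_products(spec, u, traits[:, spec.slice_c])
    y = traits[:, spec.slice_a].copy()
    b0 = spec.slice_b.start
    for k, (r, c) in enumerate(spec.active_entries):
        y[:, r] += traits[:, b0 + k] * prods[:, c]
    if e_resid is not None:
        y += np.asarray(e_resid, dtype=float)
    return y


def _min_eig_violation(M: np.ndarray, name: str, violations: list) -> None:
    diag = np.diag(M)
    tol = PSD_TOL_SCALE * max(np.abs(diag).max(), 0.0) if diag.size else 0.0
    if not np.allclose(M, M.T, atol=max(tol, 1e-12)):
        violations.append(f"{name} is not symmetric")
        return
    w = np.linalg.eigvalsh((M + M.T) / 2.0)
    if w.min() < -max(tol, 1e-15 * max(np.abs(diag).max(), 1.0)):
        violations.append(
            f"{name} is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )


def validate_state(
    state: PopulationState, spec: ReactionNormSpec
) -> ValidationReport:
    """Check dimensions, symmetry, and PSD of G_aug, P_aug and P_aug - G_aug.

    Returns a :class:`ValidationReport` rather than raising, so callers can
    surface all violations at once.
    """
    violations: list = []
    dim = spec.dim
    if state.mean.shape != (dim,):
        violations.append(f"mean has shape {state.mean.shape}, expected ({dim},)")
    if state.G_aug.shape != (dim, dim):
        violations.append(f"G_aug has shape {state.G_aug.shape}, expected {(dim, dim)}")
    if state.P_aug.shape != (dim, dim):
        violations.append(f"P_aug has shape {state.P_aug.shape}, expected {(dim, dim)}")
    m = spec.n_phenotypes
    if state.resid_cov.shape != (m, m):
        violations.append(
            f"resid_cov has shape {state.resid_cov.shape}, expected {(m, m)}"
        )
    if violations:
        return ValidationReport(ok=False, violations=violations)
    _min_eig_violation(state.G_aug, "G_aug", violations)
    _min_eig_violation(state.P_aug, "P_aug", violations)
    _min_eig_violation(state.P_aug - state.G_aug, "P_aug - G_aug", violations)
    _min_eig_violation(state.resid_cov, "resid_cov", violations)
    if not np.all(np.isfinite(state.mean)):
        violations.append("mean contains non-finite values")
    return ValidationReport(ok=not violations, violations=violations)


def psd_factor(M: np.ndarray) -> np.ndarray:
    """Factor F with F @ F.T = M for a (possibly singular) PSD matrix.

    Eigenvalues below the PSD tolerance are clipped to zero, so boundary
    states (pinned traits, degenerate environments) sample exactly on the
    support of the distribution.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    Ms = (M + M.T) / 2.0
    w, V = np.linalg.eigh(Ms)
    tol = PSD_TOL_SCALE * max(np.abs(np.diag(Ms)).max(), 0.0)
    if w.min() < -max(tol, 1e-12):
        raise np.linalg.LinAlgError(
            f"matrix is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)
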