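"""Deterministic quadrature oracle for one breeder-equation update step.

Brute-force tensor Gauss-Hermite integration of the selection response for
the univariate linear norm ``y = a + b(u - c) + e`` under Gaussian fitness.
Independent of the simulator code path: works directly from the trait
distribution and the definition

    delta = G P^{-1} cov(W, z) / W_bar.
"""

import numpy as np


def quadrature_delta_mean(
    mean,
    G,
    P,
    sigma_e_sq,
    u,
    theta,
    omega_sq,
    w_max=1.0,
    n_nodes=32,
    include_c=True,
):
    """Deterministic mean change for one generation.

    ``mean`` is (a_bar, b_bar, c_bar); ``G`` and ``P`` are 3x3 trait
    covariances (``P`` must be nonsingular on the traits it is asked to
    invert).  With ``include_c=False`` the reference trait is held fixed at
    ``c_bar`` (zero variance) and only the (a, b) block is inverted — the
    classic two-trait reduction.

    Returns ``(delta, w_bar, beta)`` over the full 3-trait layout.
    """
    mean = np.asarray(mean, dtype=float)
    G = np.asarray(G, dtype=float)
    P = np.asarray(P, dtype=float)
    idx = [0, 1, 2] if include_c else [0, 1]
    Pm = P[np.ix_(idx, idx)]
    L = np.linalg.cholesky(Pm)

    # Probabilists' Hermite nodes: weight exp(-x^2/2)/sqrt(2pi).
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / w.sum()

    k = len(idx) + 1  # traits + residual dimension
    grids = np.meshgrid(*([x] * k), indexing="ij")
    wts = np.ones_like(grids[0])
    for g in np.meshgrid(*([w] * k), indexing="ij"):
        wts = wts * g
    xi = np.stack([g.ravel() for g in grids[:-1]], axis=1)
    e = np.sqrt(sigma_e_sq) * grids[-1].ravel()
    wts = wts.ravel()

    z = mean[idx] + xi @ L.T
    a = z[:, 0]
    b = z[:, 1]
    c = z[:, 2] if include_c else np.full(a.shape, mean[2])
    y = a + b * (u - c) + e
    W = w_max * np.exp(-((y - theta) ** 2) / (2.0 * omega_sq))

    w_bar = float(np.sum(wts * W))
    s = np.array([np.sum(wts * W * z[:, j]) for j in range(len(idx))])
    s -= w_bar * mean[idx]
    beta_sub = np.linalg.solve(Pm, s) / w_bar
    beta = np.zeros(3)
    beta[idx] = beta_sub
    delta = G @ beta
    return delta, w_bar, beta
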