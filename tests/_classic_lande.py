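"""Independent classic two-cue simulator (fixed reference environments).

A self-contained Monte-Carlo implementation of the standard linear model
``y = a + b1 u1 + b2 u2 + e`` with Gaussian stabilizing selection and the
plain (unaugmented) breeder's equation over the three traits (a, b1, b2).
Used as a cross-check for the augmented simulator's Gcc = 0 reduction; it
shares no code with the package's evolution engine.
"""

import numpy as np


def simulate_classic_two_cue(
    G3,
    sigma_e_sq,
    env_mean,
    env_cov,
    omega_sq,
    w_max,
    init_mean,
    n,
    n_generations,
    seed,
):
    """Returns the (T+1, 3) array of mean traits (a, b1, b2) over time.

    ``env_mean``/``env_cov`` describe the joint (u1, u2, theta) distribution;
    draws are white across generations.
    """
    rng = np.random.default_rng(seed)
    G3 = np.asarray(G3, dtype=float)
    env_mean = np.asarray(env_mean, dtype=float)
    Lz = np.linalg.cholesky(G3)
    Le = np.linalg.cholesky(np.asarray(env_cov, dtype=float))
    mean = np.asarray(init_mean, dtype=float).copy()
    out = np.empty((n_generations + 1, 3))
    out[0] = mean
    for t in range(n_generations):
        u1, u2, theta = env_mean + Le @ rng.standard_normal(3)
        z = mean + rng.standard_normal((n, 3)) @ Lz.T
        e = np.sqrt(sigma_e_sq) * rng.standard_normal(n)
        y = z[:, 0] + z[:, 1] * u1 + z[:, 2] * u2 + e
        W = w_max * np.exp(-((y - theta) ** 2) / (2.0 * omega_sq))
        w_bar = W.mean()
        s = (z - z.mean(axis=0)).T @ (W - w_bar) / (n - 1)
        mean = mean + G3 @ np.linalg.solve(G3, s) / w_bar
        out[t + 1] = mean
    return out
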