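"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's solver path: the covariance
objective is maximized by exhaustive search over a degree grid of
unit-constraint filters in 3 dimensions.
"""

import numpy as np


def whitened_stats(covs, z):
    """Mean covariance, target-weighted covariance and an inverse-sqrt
    whitener, computed directly from per-epoch covariances."""
    z = np.asarray(z, dtype=float)
    zs = (z - z.mean()) / z.std()
    c_mean = covs.mean(axis=0)
    c_z = np.einsum("e,ecd->cd", zs, covs) / len(zs)
    evals, evecs = np.linalg.eigh(c_mean)
    w_inv_sqrt = evecs @ np.diag(evals**-0.5) @ evecs.T
    w_sqrt = evecs @ np.diag(evals**0.5) @ evecs.T
    return c_mean, c_z, w_inv_sqrt, w_sqrt


def brute_force_top_direction(covs, z, step_deg=1.0):
    """Grid-search the whitened unit sphere for the direction maximizing
    the bandpower-target covariance; returns the whitened direction.

    The unit-norm whitened direction u maps to a filter w = C^{-1/2} u
    with unit projected variance, and the objective is u^T M u with
    M = C^{-1/2} C_z C^{-1/2}.
    """
    _, c_z, w_inv_sqrt, _ = whitened_stats(covs, z)
    m = w_inv_sqrt @ c_z @ w_inv_sqrt
    theta = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    phi = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    u = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    ).reshape(-1, 3)
    vals = np.einsum("nc,cd,nd->n", u, m, u)
    return u[np.argmax(vals)]


def angular_error_deg(u, v):
    """Angle between two directions, ignoring sign."""
    c = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
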