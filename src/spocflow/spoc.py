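"""Source Power Comodulation (SPoC, lambda variant).

Given narrowband-filtered epochs ``x(e, t)`` and a per-epoch continuous
target ``z(e)``, SPoC finds spatial filters ``w`` maximizing the
covariance between the projected per-epoch bandpower
``Phi(e) = Var[w^T x](e)`` and the (standardized) target, subject to the
unit-variance constraint ``Var[w^T x](t) = 1`` on the training data::

    w_opt = argmax_w Cov[Phi(e), z(e)]   s.t.  Var[w^T x] = 1

With per-epoch covariances ``C(e)`` this is the generalized eigenvalue
problem ``C_z w = lambda C w`` where ``C_z = mean_e[z(e) C(e)]`` and
``C = mean_e[C(e)]``; eigenvalues equal the achieved power-target
covariances.  We solve it by symmetric whitening: eigendecompose
``C^{-1/2} C_z C^{-1/2}`` (numerically stable, and the whitened-data
limit ``C = I`` reduces to a plain eigendecomposition of ``C_z``).

Predictions for unseen epochs are the projected bandpower
``z_est(e) = Var[w_tr^T x_te](e) = w^T C_te(e) w`` and the activation
pattern of a filter is ``a = C w``; on a held-out fold the fold pattern
is ``a_j = C_te,j w_tr``.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .containers import EpochSet

__all__ = [
    "SpocModel",
    "RankSelection",
    "epoch_covariances",
    "fit",
    "fit_from_covariances",
    "predict",
    "fold_pattern",
    "rank_select",
]


@dataclass
class SpocModel:
    """Fitted SPoC decomposition.

    ``filters`` columns are eigenvalue-ordered (descending) spatial
    filters, each rescaled to unit projected variance on the training
    data; ``patterns = C @ filters`` are the corresponding activation
    patterns; ``eigenvalues[k]`` equals the covariance between the k-th
    component's bandpower and the standardized target.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    patterns: np.ndarray
    train_covariance: np.ndarray
    z_mean: float
    z_std: float
    band: tuple[float, float] | str = "broadband"
    window: tuple[float, float] = (0.0, 0.0)

    @property
    def n_components(self) -> int:
        return self.filters.shape[1]


@dataclass
class RankSelection:
    """Eigenvalue-spectrum based choice of component ranks to pursue."""

    selected_ranks: np.ndarray
    residuals: np.ndarray
    sigma_r: float


def epoch_covariances(epochs: EpochSet | np.ndarray) -> np.ndarray:
    """Per-epoch channel covariance matrices, shape ``(n_e, n_c, n_c)``.

    Sample covariance over the epoch's samples, mean-centered per channel
    (``ddof=1``).
    """
    data = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    x = data - data.mean(axis=2, keepdims=True)
    n_t = x.shape[2]
    return np.einsum("ect,edt->ecd", x, x) / (n_t - 1)


def fit_from_covariances(
    covs: np.ndarray,
    z: np.ndarray,
    shrinkage: float = 0.0,
    eig_floor: float = 1e-10,
) -> SpocModel:
    """Fit SPoC from precomputed per-epoch covariances.

    ``z`` is standardized internally (training statistics are stored on
    the model).  ``shrinkage`` blends the mean covariance toward a scaled
    identity before whitening, for ill-conditioned channel counts.
    """
    covs = np.asarray(covs, dtype=float)
    z = np.asarray(z, dtype=float)
    if not np.isfinite(covs).all() or not np.isfinite(z).all():
        raise ValueError("non-finite input")
    n_e, n_c, _ = covs.shape
    if len(z) != n_e:
        raise ValueError("target length does not match number of epochs")

    z_mean, z_std = float(z.mean()), float(z.std(ddof=0))
    if z_std == 0:
        raise ValueError("target variable is constant")
    zs = (z - z_mean) / z_std

    c_mean = covs.mean(axis=0)
    if shrinkage > 0:
        c_mean = (1 - shrinkage) * c_mean + shrinkage * (
            np.trace(c_mean) / n_c
        ) * np.eye(n_c)
    c_z = np.einsum("e,ecd->cd", zs, covs) / n_e

    # symmetric whitening with an eigenvalue floor for rank deficiency
    evals, evecs = np.linalg.eigh(c_mean)
    floor = eig_floor * np.trace(c_mean)
    if np.any(evals < floor):
        warnings.warn("mean covariance is (near-)rank-deficient; regularized whitening")
        evals = np.maximum(evals, floor)
    whitener = evecs @ np.diag(evals**-0.5) @ evecs.T

    m = whitener @ c_z @ whitener
    m = 0.5 * (m + m.T)
    lam, u = np.linalg.eigh(m)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    w = whitener @ u[:, order]

    # enforce the unit projected-variance constraint exactly; directions in
    # a floored null space cannot be scaled meaningfully, so clip from below
    proj_var = np.einsum("ck,cd,dk->k", w, c_mean, w)
    w = w / np.sqrt(np.maximum(proj_var, floor))[None, :]

    patterns = c_mean @ w
    # sign convention: largest-|entry| of each pattern column is positive
    flip = np.sign(patterns[np.abs(patterns).argmax(axis=0), np.arange(n_c)])
    flip[flip == 0] = 1.0
    w *= flip[None, :]
    patterns *= flip[None, :]

    return SpocModel(
        filters=w,
        eigenvalues=lam,
        patterns=patterns,
        train_covariance=c_mean,
        z_mean=z_mean,
        z_std=z_std,
    )


def fit(epochs: EpochSet, z: np.ndarray, shrinkage: float = 0.0) -> SpocModel:
    """Fit SPoC on an (already narrowband-filtered) EpochSet."""
    model = fit_from_covariances(epoch_covariances(epochs), z, shrinkage=shrinkage)
    model.band = epochs.band
    model.window = epochs.window
    return model


def predict(
    model: SpocModel, epochs: EpochSet | np.ndarray, rank: int = 0
) -> np.ndarray:
    """Per-epoch bandpower of the rank-th component on new epochs."""
    covs = epochs if (isinstance(epochs, np.ndarray) and epochs.ndim == 3 and epochs.shape[1] == epochs.shape[2]) else None
    if covs is None:
        if isinstance(epochs, EpochSet):
            if epochs.n_channels != model.filters.shape[0]:
                raise ValueError(
                    f"channel mismatch: model has {model.filters.shape[0]}, "
                    f"data has {epochs.n_channels}"
                )
        covs = epoch_covariances(epochs)
    if covs.shape[1] != model.filters.shape[0]:
        raise ValueError("channel mismatch between model and data")
    w = model.filters[:, rank]
    return np.einsum("c,ecd,d->e", w, covs, w)


def fold_pattern(w_tr: np.ndarray, test_epochs: EpochSet | np.ndarray) -> np.ndarray:
    """Activation pattern of a training filter on held-out data:
    ``a_j = C_te @ w_tr`` with ``C_te`` the mean test-epoch covariance."""
    covs = test_epochs if (
        isinstance(test_epochs, np.ndarray)
        and test_epochs.ndim == 3
        and test_epochs.shape[1] == test_epochs.shape[2]
    ) else epoch_covariances(test_epochs)
    return covs.mean(axis=0) @ np.asarray(w_tr)


def rank_select(eigenvalues: np.ndarray, n_sigma: float = 1.5) -> RankSelection:
    """Pick component ranks whose eigenvalue stands out of the spectrum.

    A least-squares line is removed from the descending eigenvalue
    spectrum; ranks whose residual exceeds ``n_sigma`` standard deviations
    of the residuals *and* whose eigenvalue is positive are selected.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    n_c = len(lam)
    if n_c < 3:
        raise ValueError("need at least 3 eigenvalues to detrend a spectrum")
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    idx = np.arange(n_c)
    coef = np.polyfit(idx, lam, 1)
    residuals = lam - np.polyval(coef, idx)
    sigma = float(residuals.std(ddof=0))
    # a numerically perfect line has no outliers to speak of
    if sigma <= 1e-10 * max(np.abs(lam).max(), 1e-30):
        selected = np.array([], dtype=int)
    else:
        selected = np.flatnonzero((residuals > n_sigma * sigma) & (lam > 0))
    return RankSelection(selected_ranks=selected, residuals=residuals, sigma_r=sigma)
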