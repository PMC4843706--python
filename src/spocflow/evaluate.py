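"""Chronological cross-validation and the component-selection battery.

A candidate component (a SPoC rank within one band/metric configuration)
is judged by how well its cross-validated bandpower predictions track
the true per-trial target:

* ``R_all``   — Pearson correlation of the concatenated out-of-fold
  predictions with the true target.
* ``R_folds`` — mean of the fold-wise correlations; unlike ``R_all`` it
  is insensitive to slow session trends shared across folds, so the pair
  discriminates genuine single-trial predictors from trend followers.
* ``H_folds`` — number of folds whose correlation sign agrees with the
  sign of ``R_all`` (zero counts as agreement); a homogeneity score.
* ``z-AUC``   — ROC area of the predictions against a median split of
  the true target (chance level 0.5).
* ``AAUC_SNR`` — mean excess of z-AUC over chance when the *training*
  labels are progressively corrupted with white noise over an SNR grid;
  robust components keep separating well past moderate label noise.

Folds are contiguous chronological blocks (earlier folds take the
remainder), which respects the nonstationarity of a recording session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import spoc
from .containers import EpochSet

__all__ = [
    "CvScheme",
    "ComponentEvaluation",
    "SelectionThresholds",
    "crossval_predict",
    "r_all",
    "r_folds",
    "h_folds",
    "z_auc",
    "aauc_snr",
    "select_components",
    "classify_predictor",
    "DEFAULT_SNR_GRID_DB",
]

DEFAULT_SNR_GRID_DB: tuple[float, ...] = (-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0)


@dataclass
class CvScheme:
    """K contiguous chronological folds; sizes differ by at most one."""

    k: int = 5

    def folds(self, n: int) -> list[np.ndarray]:
        if n < 2 * self.k:
            raise ValueError(f"need at least {2 * self.k} trials for {self.k} folds")
        return list(np.array_split(np.arange(n), self.k))


@dataclass
class ComponentEvaluation:
    """Everything known about one evaluated component."""

    z_true: np.ndarray
    z_est: np.ndarray
    rank: int
    fold_correlations: np.ndarray
    fold_patterns: list[np.ndarray]
    r_all: float
    r_folds: float
    h_folds: int
    z_auc: float
    aauc_snr: float | None = None
    n_epochs: int = 0
    valid: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class SelectionThresholds:
    """Defaults follow the 85th-percentile construction of the selection
    battery: z-AUC >= 0.59, AAUC_SNR >= 0.18, all K folds sign-consistent,
    and at least 150 trials."""

    z_auc_min: float = 0.59
    aauc_min: float = 0.18
    h_folds_min: int = 5
    n_e_min: int = 150


# ---------------------------------------------------------------------------
# scores


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def r_all(z_true: np.ndarray, z_est: np.ndarray) -> float:
    """Overall Pearson correlation of true and predicted targets.
    NaN flags a degenerate (zero-variance) input."""
    return _pearson(z_true, z_est)


def r_folds(z_true: np.ndarray, z_est: np.ndarray, scheme: CvScheme) -> float:
    """Mean of the fold-wise Pearson correlations."""
    folds = scheme.folds(len(z_true))
    return float(np.mean([_pearson(z_true[f], z_est[f]) for f in folds]))


def h_folds(overall_r: float, fold_correlations: np.ndarray) -> int:
    """Count folds whose correlation sign matches ``overall_r``'s sign;
    a zero on either side counts as a match (unit step at 0 is 1)."""
    prod = np.sign(overall_r) * np.sign(np.asarray(fold_correlations))
    return int(np.sum(prod >= 0))


def z_auc(z_true: np.ndarray, z_est: np.ndarray, split_percentile: float = 50.0) -> float:
    """ROC AUC of predictions against a percentile split of the truth.

    Trials strictly above the ``split_percentile`` of ``z_true`` form the
    positive class; ties are handled by midranks.  Returns NaN when the
    split is single-class.
    """
    z_true = np.asarray(z_true, dtype=float)
    labels = z_true > np.percentile(z_true, split_percentile)
    if labels.all() or not labels.any():
        return np.nan
    return float(roc_auc_score(labels, np.asarray(z_est, dtype=float)))


# ---------------------------------------------------------------------------
# cross-validated prediction


def crossval_predict(
    epochs: EpochSet | np.ndarray,
    z: np.ndarray,
    scheme: CvScheme = CvScheme(),
    rank: int = 0,
    shrinkage: float = 0.0,
    covs: np.ndarray | None = None,
    z_score_against: np.ndarray | None = None,
) -> ComponentEvaluation:
    """Out-of-fold bandpower predictions plus the full score battery.

    For each fold the model is fitted on the remaining folds (target
    standardized with training statistics only), the held-out fold is
    predicted via the projected bandpower, and the fold pattern
    ``a_j = C_te,j w_tr`` is recorded.  ``covs`` may carry precomputed
    per-epoch covariances to avoid recomputation across repeated calls.

    ``z_score_against`` scores the battery against a different "true"
    target than the training labels ``z`` (used by the label-noise
    stress test, where training labels are corrupted but separability is
    judged against the clean target).
    """
    if covs is None:
        covs = spoc.epoch_covariances(epochs)
    z = np.asarray(z, dtype=float)
    z_ref = z if z_score_against is None else np.asarray(z_score_against, dtype=float)
    n = len(z)
    folds = scheme.folds(n)
    z_est = np.full(n, np.nan)
    fold_corr = np.full(scheme.k, np.nan)
    patterns: list[np.ndarray] = []
    flags: list[str] = []
    valid = True
    for j, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        try:
            model = spoc.fit_from_covariances(covs[train_idx], z[train_idx], shrinkage=shrinkage)
        except (ValueError, np.linalg.LinAlgError) as exc:
            flags.append(f"fold {j}: fit failed ({exc})")
            valid = False
            patterns.append(np.full(covs.shape[1], np.nan))
            continue
        if rank >= model.n_components:
            raise ValueError(f"rank {rank} out of range for {model.n_components} components")
        w = model.filters[:, rank]
        z_est[test_idx] = np.einsum("c,ecd,d->e", w, covs[test_idx], w)
        patterns.append(covs[test_idx].mean(axis=0) @ w)
        fold_corr[j] = _pearson(z_ref[test_idx], z_est[test_idx])

    overall = _pearson(z_ref, z_est) if valid else np.nan
    auc = z_auc(z_ref, z_est) if valid else np.nan
    if np.isnan(auc):
        flags.append("z_auc undefined")
    return ComponentEvaluation(
        z_true=z_ref,
        z_est=z_est,
        rank=rank,
        fold_correlations=fold_corr,
        fold_patterns=patterns,
        r_all=overall,
        r_folds=float(np.nanmean(fold_corr)) if valid else np.nan,
        h_folds=h_folds(overall, fold_corr) if valid else 0,
        z_auc=auc,
        n_epochs=n,
        valid=valid,
        flags=flags,
    )


def _area_over_chance(aucs: np.ndarray) -> float:
    """Mean excess of z-AUC over the 0.5 chance level across the grid."""
    return float(np.nanmean(np.asarray(aucs, dtype=float) - 0.5))


def aauc_snr(
    epochs: EpochSet | np.ndarray,
    z: np.ndarray,
    scheme: CvScheme = CvScheme(),
    rank: int = 0,
    snr_grid_db: tuple[float, ...] = DEFAULT_SNR_GRID_DB,
    reps: int = 3,
    seed: int = 0,
    shrinkage: float = 0.0,
    covs: np.ndarray | None = None,
) -> float:
    """Label-noise stress score (area of the z-AUC vs label-SNR curve).

    At each SNR level white noise with variance ``10**(-SNR/10)`` (the
    standardized target has unit variance) is added to the *training*
    labels; the cross-validated predictions are still scored against the
    clean target.  ``reps`` noisy label sets are averaged per level and
    the returned score is the mean excess over chance across the grid.
    Deterministic given ``seed``.
    """
    if covs is None:
        covs = spoc.epoch_covariances(epochs)
    z = np.asarray(z, dtype=float)
    zs = (z - z.mean()) / z.std(ddof=0)
    rng = np.random.default_rng(seed)
    mean_aucs = []
    for snr_db in snr_grid_db:
        sigma = np.sqrt(10.0 ** (-snr_db / 10.0))
        aucs = []
        for _ in range(reps):
            z_noisy = zs + sigma * rng.standard_normal(len(zs))
            ev = crossval_predict(
                None, z_noisy, scheme, rank, shrinkage=shrinkage, covs=covs,
                z_score_against=zs,
            )
            aucs.append(ev.z_auc)
        mean_aucs.append(np.nanmean(aucs))
    return _area_over_chance(np.asarray(mean_aucs))


# ---------------------------------------------------------------------------
# selection and predictor taxonomy


def select_components(
    evals: list[ComponentEvaluation],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> list[ComponentEvaluation]:
    """Keep components passing all selection criteria in parallel."""
    return [ev for ev in evals if passes_selection(ev, thresholds)]


def passes_selection(
    ev: ComponentEvaluation, thresholds: SelectionThresholds = SelectionThresholds()
) -> bool:
    if not ev.valid:
        return False
    if ev.n_epochs < thresholds.n_e_min:
        return False
    if not np.isfinite(ev.z_auc) or ev.z_auc < thresholds.z_auc_min:
        return False
    if ev.aauc_snr is None or not np.isfinite(ev.aauc_snr) or ev.aauc_snr < thresholds.aauc_min:
        return False
    return ev.h_folds == thresholds.h_folds_min


def classify_predictor(
    ev: ComponentEvaluation,
    r_all_min: float = 0.2,
    folds_ratio: float = 0.5,
) -> str:
    """Label a component ``single_trial``, ``session_trend`` or ``neither``.

    A high overall correlation with a proportionally high, sign-consistent
    mean fold correlation indicates genuine trial-by-trial information;
    high overall but low fold-wise correlation indicates a slow session
    trend shared by predictor and target.
    """
    if not np.isfinite(ev.r_all) or abs(ev.r_all) < r_all_min:
        return "neither"
    sign_ok = np.sign(ev.r_folds) == np.sign(ev.r_all)
    if abs(ev.r_folds) >= folds_ratio * abs(ev.r_all) and sign_ok:
        return "single_trial"
    return "session_trend"
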