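"""Single-trial motor performance scores for isometric force trajectories.

A trial of the sequential visual isometric pinch task (SVIPT) is described
by its force trace ``F(t)`` and three event timestamps: the go-cue
``t_go``, the moment the cursor leaves the start field ``t_T0_exit``, and
the first hit of the target field ``t_hit``.  Five scores summarise how
fast and how smoothly the force was produced:

* **RT** — reaction time, ``t_T0_exit - t_go`` in milliseconds.
* **DUR** — duration from go-cue to first target hit, in seconds.
* **CPL** — cursor path length, the total variation of ``F`` on
  ``[t_go, t_hit]`` (discretely ``sum |F_{k+1} - F_k|``).
* **ISJ** — integrated squared jerk, ``int |F'''(t)|^2 dt`` over the same
  window; jerk is estimated by repeated central finite differences.
* **NJ** — normalized jerk, ``ISJ * DUR^(5/2) / CPL^2`` (the exponent is
  configurable).

Because the task alternates between two target-field sequences, all
metrics except RT are z-scored within each condition before trials are
pooled into a single chronological target vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ForceTrial",
    "TrialMetrics",
    "MetricUndefinedError",
    "compute_rt",
    "compute_dur",
    "compute_cpl",
    "compute_isj",
    "compute_nj",
    "compute_metrics",
    "standardize_and_pool",
]

METRIC_NAMES = ("RT", "DUR", "CPL", "ISJ", "NJ")


class MetricUndefinedError(ValueError):
    """A performance metric cannot be computed for this trial."""


@dataclass
class ForceTrial:
    """One trial's force trace plus event timestamps.

    ``force`` is sampled at ``sampling_rate`` starting at time ``t_start``
    (seconds, same clock as the events).  The trace must cover at least
    ``[t_go, t_hit]``.  ``condition`` identifies the target-field sequence
    (``"seq1"`` / ``"seq2"``).
    """

    force: np.ndarray
    sampling_rate: float
    t_go: float
    t_T0_exit: float
    t_hit: float
    condition: str = "seq1"
    t_start: float = 0.0
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if not (self.t_go < self.t_T0_exit <= self.t_hit):
            raise ValueError("events must satisfy t_go < t_T0_exit <= t_hit")
        t_end = self.t_start + (len(self.force) - 1) / self.sampling_rate
        if self.t_go < self.t_start - 0.5 / self.sampling_rate or self.t_hit > t_end + 0.5 / self.sampling_rate:
            raise ValueError("force trace does not cover [t_go, t_hit]")

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Samples of the trace with timestamps in ``[t0, t1]`` (inclusive)."""
        i0 = int(round((t0 - self.t_start) * self.sampling_rate))
        i1 = int(round((t1 - self.t_start) * self.sampling_rate))
        return self.force[max(i0, 0) : i1 + 1]


@dataclass
class TrialMetrics:
    trial_id: int
    condition: str
    RT: float
    DUR: float
    CPL: float
    ISJ: float
    NJ: float


def compute_rt(trial: ForceTrial) -> float:
    """Reaction time in milliseconds: interval from go-cue to start-field exit."""
    if not np.isfinite(trial.t_T0_exit):
        raise MetricUndefinedError("missing T0-exit event")
    return (trial.t_T0_exit - trial.t_go) * 1000.0


def compute_dur(trial: ForceTrial) -> float:
    """Duration in seconds from the go-cue until the first target hit."""
    if not np.isfinite(trial.t_hit):
        raise MetricUndefinedError("missing first-hit event")
    return trial.t_hit - trial.t_go


def compute_cpl(trial: ForceTrial) -> float:
    """Cursor path length: total variation of the force on [t_go, t_hit]."""
    f = trial.window(trial.t_go, trial.t_hit)
    if len(f) < 2:
        raise MetricUndefinedError("window shorter than 2 samples")
    return float(np.abs(np.diff(f)).sum())


def _third_derivative(f: np.ndarray, dt: float) -> np.ndarray:
    # central third-difference stencil in the interior, one-sided stencils
    # at the two samples on each end; all stencils are exact for cubics
    n = len(f)
    d = np.empty(n)
    h3 = dt**3
    fwd = (f[3:] - 3 * f[2:-1] + 3 * f[1:-2] - f[:-3]) / h3  # stencil over f[k..k+3]
    if n >= 6:
        d[2 : n - 2] = (f[4:] - 2 * f[3 : n - 1] + 2 * f[1 : n - 3] - f[: n - 4]) / (2 * h3)
        d[0], d[1] = fwd[0], fwd[1]
        d[n - 2], d[n - 1] = fwd[n - 5], fwd[n - 4]
    else:
        for k in range(n):
            d[k] = fwd[int(np.clip(k - 1, 0, n - 4))]
    return d


def compute_isj(trial: ForceTrial) -> float:
    """Integrated squared jerk: ``int |F'''|^2 dt`` on [t_go, t_hit]."""
    f = trial.window(trial.t_go, trial.t_hit)
    if len(f) < 4:
        raise MetricUndefinedError("need >= 4 samples for a third derivative")
    dt = 1.0 / trial.sampling_rate
    jerk = _third_derivative(f, dt)
    return float(np.trapezoid(jerk**2, dx=dt))


def compute_nj(isj: float, dur: float, cpl: float, exponent: float = 2.5) -> float:
    """Normalized jerk ``ISJ * DUR**exponent / CPL**2`` (default exponent 5/2)."""
    if cpl <= 0:
        raise MetricUndefinedError("NJ undefined for CPL = 0")
    return isj * dur**exponent / cpl**2


def compute_metrics(trial: ForceTrial, nj_exponent: float = 2.5) -> TrialMetrics:
    """All five scores for one trial."""
    rt = compute_rt(trial)
    dur = compute_dur(trial)
    cpl = compute_cpl(trial)
    isj = compute_isj(trial)
    nj = compute_nj(isj, dur, cpl, exponent=nj_exponent)
    return TrialMetrics(trial.trial_id, trial.condition, rt, dur, cpl, isj, nj)


def standardize_and_pool(
    metrics: pd.DataFrame,
    by: str = "condition",
    skip: tuple[str, ...] = ("RT",),
) -> pd.DataFrame:
    """Z-score each metric within condition, then pool chronologically.

    RT is passed through raw (it is defined on an absolute time scale and
    comparable across conditions); every other metric is standardized to
    zero mean / unit SD (population convention, ``ddof=0``) within each
    condition before pooling.  Rows come back sorted by ``trial_id``.

    Raises ``ValueError`` if a metric is constant within a condition.
    """
    metrics = metrics.copy()
    cols = [c for c in METRIC_NAMES if c in metrics.columns]
    if by not in metrics.columns:
        raise ValueError(f"grouping column {by!r} missing")
    for cond, grp in metrics.groupby(by):
        if len(grp) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 trials")
        for col in cols:
            if col in skip:
                continue
            vals = grp[col].to_numpy(dtype=float)
            sd = vals.std(ddof=0)
            if sd == 0:
                raise ValueError(f"metric {col} has zero variance in condition {cond!r}")
            metrics.loc[grp.index, col] = (vals - vals.mean()) / sd
    if "trial_id" in metrics.columns:
        metrics = metrics.sort_values("trial_id").reset_index(drop=True)
    return metrics
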