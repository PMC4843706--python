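"""Filtering, epoching and outlier-trial rejection.

Continuous multichannel data is Butterworth-filtered (5th order,
zero-phase by default), cut into fixed windows relative to the go-cue,
and cleaned by three rejection rules applied to the 2 s pre-go epochs:

1. **min-max** — reject an epoch whose peak-to-peak amplitude on any
   frontal channel exceeds 60 uV (eye blinks / movements);
2. **variance** — reject an epoch whose per-channel variance is an upper
   outlier relative to the P10/P90 spread of all epoch variances on that
   channel (muscular artifacts);
3. **behavioral** — reject trials whose active performance metric falls
   outside fixed min-max bounds (extreme behavior).

A dataset must retain at least 150 trials to proceed to the
decomposition stage (convergence requirement of the supervised filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .containers import BROADBAND, EpochSet

__all__ = [
    "RejectionReport",
    "bandpass",
    "epoch",
    "reject_minmax",
    "reject_variance",
    "reject_behavioral",
    "enforce_min_trials",
    "apply_report",
    "BEHAVIORAL_THRESHOLDS",
    "DEFAULT_MIN_TRIALS",
]

#: Min-max bounds per metric; RT in raw milliseconds, NJ raw, the other
#: three on standardized (z-scored) values.
BEHAVIORAL_THRESHOLDS: dict[str, tuple[float, float]] = {
    "RT": (150.0, 900.0),
    "ISJ": (-1.5, 1.5),
    "CPL": (-0.6, 0.6),
    "DUR": (-1.5, 2.0),
    "NJ": (0.0, 1300.0),
}

DEFAULT_MIN_TRIALS = 150


@dataclass
class RejectionReport:
    """Partition of trial ids into kept and rejected (with reasons)."""

    kept_ids: np.ndarray
    rejected: dict[int, str] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    @property
    def rejected_ids(self) -> np.ndarray:
        return np.asarray(sorted(self.rejected), dtype=int)

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [(int(i), "kept", "") for i in self.kept_ids]
        rows += [(int(i), "rejected", r) for i, r in self.rejected.items()]
        return pd.DataFrame(rows, columns=["trial_id", "status", "reason"]).sort_values(
            "trial_id", ignore_index=True
        )


def bandpass(
    raw: np.ndarray,
    sampling_rate: float,
    f0: float,
    df: float,
    order: int = 5,
    zero_phase: bool = True,
    axis: int = -1,
) -> np.ndarray:
    """Butterworth bandpass ``[f0, f0 + df]`` Hz.

    Zero-phase (forward-backward) by default, which doubles the effective
    order; set ``zero_phase=False`` for a causal filter (online use).
    """
    nyq = sampling_rate / 2.0
    if not 0 < f0 < f0 + df < nyq:
        raise ValueError(f"band [{f0}, {f0 + df}] Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [f0, f0 + df], btype="bandpass", fs=sampling_rate, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, raw, axis=axis)
    return signal.sosfilt(sos, raw, axis=axis)


def bandpass_epochs(epochs: EpochSet, f0: float, df: float, order: int = 5) -> EpochSet:
    """Zero-phase bandpass applied along the sample axis of each epoch."""
    data = bandpass(epochs.data, epochs.sampling_rate, f0, df, order=order, axis=-1)
    return replace(epochs, data=data, band=(f0, f0 + df))


def epoch(
    raw: np.ndarray,
    sampling_rate: float,
    events: np.ndarray,
    t0: float,
    dt: float,
    channel_names: list[str] | None = None,
    band: tuple[float, float] | str = BROADBAND,
) -> EpochSet:
    """Cut half-open windows ``[event + t0, event + t0 + dt)`` from a
    continuous ``(n_channels, n_samples)`` recording.

    Events whose window falls outside the recording are dropped with a
    warning; the surviving epochs keep their chronological event index as
    trial id.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    n_samples_total = raw.shape[1]
    n_t = int(round(dt * sampling_rate))
    slabs, ids = [], []
    for i, ev in enumerate(np.asarray(events, dtype=float)):
        start = int(round((ev + t0) * sampling_rate))
        if start < 0 or start + n_t > n_samples_total:
            warnings.warn(f"event {i} at {ev:.3f}s: window out of bounds, dropped")
            continue
        slabs.append(raw[:, start : start + n_t])
        ids.append(i)
    if not slabs:
        raise ValueError("no event window fits inside the recording")
    return EpochSet(
        data=np.stack(slabs),
        sampling_rate=sampling_rate,
        channel_names=channel_names or [],
        window=(t0, t0 + dt),
        band=band,
        trial_ids=np.asarray(ids),
    )


def default_frontal(channel_names: list[str]) -> list[str]:
    """Channels whose 10-20 label starts with Fp/AF/F (frontal row)."""
    return [c for c in channel_names if c.startswith(("Fp", "AF", "F"))]


def reject_minmax(
    epochs: EpochSet,
    channels: list[str] | None = None,
    threshold_uv: float = 60.0,
) -> RejectionReport:
    """Reject epochs whose peak-to-peak swing on any frontal channel is
    strictly above ``threshold_uv``."""
    if channels is None:
        channels = default_frontal(epochs.channel_names)
    idx = [epochs.channel_index(c) for c in channels]
    rejected: dict[int, str] = {}
    kept = []
    for e, tid in enumerate(epochs.trial_ids):
        if idx:
            seg = epochs.data[e, idx, :]
            p2p = (seg.max(axis=1) - seg.min(axis=1)).max()
        else:
            p2p = 0.0
        if p2p > threshold_uv:
            rejected[int(tid)] = "minmax"
        else:
            kept.append(tid)
    return RejectionReport(
        kept_ids=np.asarray(kept, dtype=int),
        rejected=rejected,
        thresholds={"minmax_uV": threshold_uv, "channels": channels},
    )


def reject_variance(
    epochs: EpochSet, p_low: float = 10.0, p_up: float = 90.0
) -> RejectionReport:
    """Reject epochs with outlying per-channel variance.

    For each channel the P10/P90 percentiles of epoch variances are
    computed; an epoch is rejected if any channel's variance exceeds
    ``P90 + 2 * (P90 - P10)``.  The rule is scale invariant.
    """
    if epochs.n_epochs < 10:
        raise ValueError("need >= 10 epochs for percentile-based rejection")
    var = epochs.data.var(axis=2, ddof=1)  # (n_epochs, n_channels)
    lo = np.percentile(var, p_low, axis=0)
    hi = np.percentile(var, p_up, axis=0)
    limit = hi + 2.0 * (hi - lo)
    bad = (var > limit[None, :]).any(axis=1)
    rejected = {int(t): "variance" for t in epochs.trial_ids[bad]}
    return RejectionReport(
        kept_ids=np.asarray(epochs.trial_ids[~bad], dtype=int),
        rejected=rejected,
        thresholds={"p_low": p_low, "p_up": p_up},
    )


def reject_behavioral(
    metrics: pd.DataFrame,
    metric: str,
    thresholds: dict[str, tuple[float, float]] | None = None,
) -> RejectionReport:
    """Reject trials whose active metric lies outside its min-max bounds."""
    thresholds = thresholds or BEHAVIORAL_THRESHOLDS
    if metric not in thresholds:
        raise ValueError(f"no thresholds for metric {metric!r}")
    lo, hi = thresholds[metric]
    vals = metrics[metric].to_numpy(dtype=float)
    tids = metrics["trial_id"].to_numpy(dtype=int)
    bad = (vals < lo) | (vals > hi)
    return RejectionReport(
        kept_ids=tids[~bad],
        rejected={int(t): "behavioral" for t in tids[bad]},
        thresholds={metric: (lo, hi)},
    )


def enforce_min_trials(n_kept: int, n_min: int = DEFAULT_MIN_TRIALS) -> bool:
    """Gate: a dataset needs at least ``n_min`` surviving trials."""
    return n_kept >= n_min


def apply_report(epochs: EpochSet, report: RejectionReport) -> EpochSet:
    """Restrict an EpochSet to the trials kept by a rejection report."""
    keep = np.isin(epochs.trial_ids, report.kept_ids)
    return epochs.subset(np.flatnonzero(keep))
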