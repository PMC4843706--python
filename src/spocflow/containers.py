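"""Core in-memory containers shared across the workflow.

The canonical unit of EEG data is the :class:`EpochSet`: a dense
``(n_epochs, n_channels, n_samples)`` array of pre-trial voltage epochs
together with the metadata required to interpret it (sampling rate,
channel labels, epoching window relative to the go-cue, and the frequency
band the data has been filtered to).  Epochs are always stored in
chronological order; ``trial_ids`` are strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["EpochSet", "BROADBAND"]

#: Sentinel band label for data that has not been narrowband-filtered.
BROADBAND = "broadband"


@dataclass
class EpochSet:
    """Epoched multichannel EEG.

    Parameters
    ----------
    data
        Array of shape ``(n_epochs, n_channels, n_samples)`` in microvolts
        (arbitrary units are fine for synthetic data).
    sampling_rate
        Sampling frequency in Hz.
    channel_names
        One label per channel (extended 10-20 names for real recordings).
    window
        ``(t0, t0 + dt)`` in seconds relative to the go-cue.
    band
        ``(f0, f1)`` in Hz, or :data:`BROADBAND` for unfiltered data.
    trial_ids
        Strictly increasing chronological trial identifiers.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    window: tuple[float, float] = (0.0, 0.0)
    band: tuple[float, float] | str = BROADBAND
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_epochs, n_channels, n_samples), got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite values")
        n_e, n_c, _ = self.data.shape
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(n_c)]
        if len(self.channel_names) != n_c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_c} channels"
            )
        if self.trial_ids is None:
            self.trial_ids = np.arange(n_e)
        self.trial_ids = np.asarray(self.trial_ids)
        if len(self.trial_ids) != n_e:
            raise ValueError("trial_ids length mismatch")
        if n_e > 1 and not np.all(np.diff(self.trial_ids) > 0):
            raise ValueError("trial_ids must be strictly increasing (chronological)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx: Sequence[int] | np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to the given epoch indices."""
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx], trial_ids=self.trial_ids[idx])

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None
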