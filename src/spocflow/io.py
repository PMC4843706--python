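"""Reading and writing the canonical epochs container and raw recordings.

The on-disk epochs container is a small HDF5 layout:

* dataset ``epochs`` — ``(n_epochs, n_channels, n_samples)`` float64
* dataset ``z`` — optional per-epoch target variable
* dataset ``trial_ids`` — chronological trial identifiers
* attrs ``sampling_rate``, ``channel_names``, ``window``, ``band``

Continuous recordings (BrainVision ``.vhdr`` or EDF) are read through MNE
when it is installed; this is a thin convenience wrapper, everything
downstream operates on plain arrays / :class:`~spocflow.containers.EpochSet`.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .containers import BROADBAND, EpochSet

__all__ = ["save_epochs", "load_epochs", "read_raw"]


def save_epochs(path: str | Path, epochs: EpochSet, z: np.ndarray | None = None) -> None:
    """Write an :class:`EpochSet` (and optionally its target ``z``) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset("trial_ids", data=np.asarray(epochs.trial_ids))
        if z is not None:
            f.create_dataset("z", data=np.asarray(z, dtype=float))
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]
        f.attrs["window"] = list(epochs.window)
        if isinstance(epochs.band, str):
            f.attrs["band"] = epochs.band
        else:
            f.attrs["band"] = list(epochs.band)


def load_epochs(path: str | Path) -> tuple[EpochSet, np.ndarray | None]:
    """Load an epochs container; returns ``(EpochSet, z or None)``."""
    with h5py.File(path, "r") as f:
        data = f["epochs"][...]
        trial_ids = f["trial_ids"][...] if "trial_ids" in f else None
        z = f["z"][...] if "z" in f else None
        band = f.attrs["band"]
        if isinstance(band, (bytes, str)):
            band = band.decode() if isinstance(band, bytes) else band
            band = band if band == BROADBAND else band
        else:
            band = tuple(float(b) for b in band)
        epochs = EpochSet(
            data=data,
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            window=tuple(f.attrs["window"]),
            band=band,
            trial_ids=trial_ids,
        )
    return epochs, z


def read_raw(path: str | Path):
    """Read a continuous BrainVision (``.vhdr``) or EDF recording via MNE.

    Returns ``(data, sampling_rate, channel_names)`` with ``data`` of shape
    ``(n_channels, n_samples)``.  Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading raw recordings requires mne") from exc
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw format {suffix!r} (expected .vhdr or .edf)")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)
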