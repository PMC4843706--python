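"""Synthetic forward-model EEG scenes and parametric force trials.

The generator instantiates the linear forward model ``x(t) = A s(t)``:
each planted source is a narrowband carrier (Butterworth-filtered white
noise) whose per-epoch amplitude is modulated so that the source's
log-bandpower correlates with a continuous per-trial target variable
``z(e)`` at a prescribed level.  Sources are mixed into the sensor space
through their pattern columns (columns of ``A``) and spatially/temporally
white noise is added, so that the sensor covariance is
``A diag(power) A^T + noise_power I`` — closed-form checkable.

Amplitude modulation law
------------------------
Carriers are normalised to exactly unit sample variance within each
epoch, then scaled by ``sigma(e) = sqrt(baseline_power) * exp(g * d(e))``
where ``g`` is a small fixed log-power gain and the driver ``d`` is an
exact-correlation blend of the (standardized) target and an orthogonal
noise component::

    d = r * z_std + sqrt(1 - r^2) * eps_perp

``eps_perp`` is residualized against ``z_std`` and re-standardized, so the
empirical correlation between per-epoch log-bandpower (``2 g d``) and the
target is *exactly* ``r = comodulation_r`` on every realisation.  Keeping
``g`` small keeps the raw power approximately linear in the target, which
is the regime the covariance-based decomposition exploits.  A source may
alternatively couple to a slow session trend instead of the trial-wise
target (``coupling="trend"``), which is how session-trend scenes for
predictor-discrimination tests are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet
from .forcemetrics import ForceTrial

__all__ = [
    "SourceSpec",
    "SyntheticScene",
    "generate_scene",
    "ForceProfile",
    "generate_force_trial",
    "force_events_frame",
]


@dataclass
class SourceSpec:
    """One planted oscillatory source.

    Parameters
    ----------
    pattern
        Per-channel mixing weights (a column of the forward matrix ``A``).
        ``None`` draws a random unit-norm pattern from the scene RNG.
    center_freq, bandwidth
        Carrier band ``center_freq +/- bandwidth/2`` in Hz.
    comodulation_r
        Target correlation in ``[-1, 1]`` between per-epoch source
        log-bandpower and the target variable (or the session trend for
        ``coupling="trend"``).
    baseline_power
        Mean-log source power level (variance units).
    coupling
        ``"target"`` (default) ties power to the trial-wise target,
        ``"trend"`` ties it to the slow session trend only.
    log_power_gain
        Gain ``g`` of the exponential modulation law; the per-epoch log
        power is ``log(baseline_power) + 2 g d(e)``.
    """

    pattern: np.ndarray | None = None
    center_freq: float = 10.0
    bandwidth: float = 2.0
    comodulation_r: float = 0.9
    baseline_power: float = 1.0
    coupling: str = "target"
    log_power_gain: float = 0.25

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if abs(self.comodulation_r) > 1:
            raise ValueError("|comodulation_r| must be <= 1")
        if self.coupling not in ("target", "trend"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.pattern is not None:
            self.pattern = np.asarray(self.pattern, dtype=float)
            if not np.any(self.pattern):
                raise ValueError("pattern must have at least one nonzero entry")


@dataclass
class SyntheticScene:
    """Study-scale scene defaults: 63 channels, 400 trials, 500 Hz,
    750 ms pre-go epochs."""

    n_channels: int = 63
    n_epochs: int = 400
    sampling_rate: float = 500.0
    epoch_length: float = 0.75
    sources: list[SourceSpec] = field(default_factory=lambda: [SourceSpec()])
    noise_power: float = 0.1
    trend_weight: float = 0.0
    pink_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not 0 <= self.trend_weight <= 1:
            raise ValueError("trend_weight must be in [0, 1]")


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def _orthonormal_noise(base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal draw residualized against ``base`` and re-standardized."""
    eps = rng.standard_normal(len(base))
    eps = eps - base * (eps @ base) / (base @ base)
    return _standardize(eps)


def _exact_corr_blend(base: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance driver with empirical correlation exactly ``r`` to ``base``."""
    base = _standardize(base)
    perp = _orthonormal_noise(base, rng)
    return r * base + np.sqrt(1.0 - r * r) * perp


def _narrowband_carrier(
    n_epochs: int, n_samples: int, fs: float, f_lo: float, f_hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance narrowband noise carriers, one row per epoch."""
    nyq = fs / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(f"carrier band [{f_lo}, {f_hi}] outside (0, {nyq}) Hz")
    sos = signal.butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    stream = signal.sosfiltfilt(sos, rng.standard_normal(n_epochs * n_samples))
    u = stream.reshape(n_epochs, n_samples)
    u = u - u.mean(axis=1, keepdims=True)
    u /= u.std(axis=1, ddof=1, keepdims=True)
    return u


def _pink(shape: tuple[int, ...], fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spectrum * scale, n=shape[-1], axis=-1)
    return pink / pink.std(axis=-1, keepdims=True, ddof=0)


def generate_scene(
    scene: SyntheticScene,
) -> tuple[EpochSet, np.ndarray, np.ndarray]:
    """Generate an epoched sensor scene from the forward model.

    Returns
    -------
    epochs : EpochSet
        ``(n_epochs, n_channels, n_samples)`` sensor data.
    z : ndarray
        Standardized per-epoch target variable.
    true_patterns : ndarray
        ``(n_channels, n_sources)`` — the planted mixing columns of ``A``.

    All randomness flows from ``scene.seed``; the same scene yields the
    same arrays bit for bit.
    """
    rng = np.random.default_rng(scene.seed)
    n_e, n_c = scene.n_epochs, scene.n_channels
    n_t = int(round(scene.epoch_length * scene.sampling_rate))

    # target variable: white component plus optional linear session trend
    eps_z = rng.standard_normal(n_e)
    if scene.trend_weight > 0 and n_e > 1:
        trend = _standardize(np.linspace(-1.0, 1.0, n_e))
        w = scene.trend_weight
        z = _standardize(w * trend + np.sqrt(1 - w * w) * _standardize(eps_z))
    else:
        trend = np.zeros(n_e)
        z = _standardize(eps_z)

    data = np.zeros((n_e, n_c, n_t))
    patterns = np.zeros((n_c, len(scene.sources)))
    for m, src in enumerate(scene.sources):
        if src.pattern is None:
            a = rng.standard_normal(n_c)
            a /= np.linalg.norm(a)
        else:
            a = src.pattern
            if len(a) != n_c:
                raise ValueError(
                    f"source {m}: pattern has {len(a)} entries for {n_c} channels"
                )
        patterns[:, m] = a

        if src.coupling == "trend":
            if scene.trend_weight == 0:
                raise ValueError("trend-coupled source requires trend_weight > 0")
            base = trend
        else:
            base = z
        driver = _exact_corr_blend(base, src.comodulation_r, rng)
        sigma = np.sqrt(src.baseline_power) * np.exp(src.log_power_gain * driver)

        f_lo = src.center_freq - src.bandwidth / 2.0
        f_hi = src.center_freq + src.bandwidth / 2.0
        carrier = _narrowband_carrier(n_e, n_t, scene.sampling_rate, f_lo, f_hi, rng)
        source = sigma[:, None] * carrier  # (n_e, n_t), unit carrier variance
        data += a[None, :, None] * source[:, None, :]

    if scene.noise_power > 0:
        if scene.pink_noise:
            noise = _pink((n_e, n_c, n_t), scene.sampling_rate, rng)
        else:
            noise = rng.standard_normal((n_e, n_c, n_t))
        data += np.sqrt(scene.noise_power) * noise

    epochs = EpochSet(
        data=data,
        sampling_rate=scene.sampling_rate,
        window=(-0.8, -0.8 + scene.epoch_length),
        band="broadband",
    )
    return epochs, z, patterns


# ---------------------------------------------------------------------------
# parametric force trials


@dataclass
class ForceProfile:
    """Piecewise-linear target force profile.

    The trace ramps from 0 to ``(1 + overshoot) * target_force`` over
    ``ramp_time`` seconds, then (if overshooting) settles linearly back to
    ``target_force`` over ``settle_time``.  ``jerk_scale`` adds a smooth
    random perturbation to emulate tremor.
    """

    ramp_time: float = 0.35
    overshoot: float = 0.0
    jerk_scale: float = 0.0
    target_force: float = 1.0
    settle_time: float = 0.3
    pre_time: float = 0.2
    hold_time: float = 0.2

    def __post_init__(self) -> None:
        if self.ramp_time <= 0:
            raise ValueError("ramp_time must be positive")


def generate_force_trial(
    profile: ForceProfile,
    sampling_rate: float = 1000.0,
    seed: int = 0,
    condition: str = "seq1",
    trial_id: int = 0,
) -> ForceTrial:
    """Build one synthetic :class:`ForceTrial` with consistent events.

    The go-cue sits at ``t = 0``; the start-field exit coincides with the
    end of the force ramp and the first target hit with the moment the
    force settles at the target level.
    """
    rng = np.random.default_rng(seed)
    p = profile
    dt = 1.0 / sampling_rate
    peak = p.target_force * (1.0 + p.overshoot)

    t_exit = p.ramp_time
    t_hit = p.ramp_time + (p.settle_time if p.overshoot > 0 else 0.0)
    t_end = t_hit + p.hold_time

    t = np.arange(-p.pre_time, t_end + dt / 2, dt)
    f = np.zeros_like(t)
    ramp = (t >= 0) & (t <= p.ramp_time)
    f[ramp] = peak * t[ramp] / p.ramp_time
    if p.overshoot > 0:
        settle = (t > p.ramp_time) & (t <= t_hit)
        f[settle] = peak - (peak - p.target_force) * (t[settle] - p.ramp_time) / p.settle_time
    f[t > t_hit] = p.target_force

    if p.jerk_scale > 0:
        rough = rng.standard_normal(len(t))
        win = np.hanning(max(int(0.05 * sampling_rate), 5))
        smooth = np.convolve(rough, win / win.sum(), mode="same")
        f = f + p.jerk_scale * smooth

    return ForceTrial(
        force=f,
        sampling_rate=sampling_rate,
        t_go=0.0,
        t_T0_exit=t_exit,
        t_hit=t_hit,
        condition=condition,
        t_start=-p.pre_time,
        trial_id=trial_id,
    )


def force_events_frame(trials: list[ForceTrial]) -> pd.DataFrame:
    """Event table (trial_id, condition, t_go, t_T0_exit, t_hit) for export."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "condition": [t.condition for t in trials],
            "t_go": [t.t_go for t in trials],
            "t_T0_exit": [t.t_T0_exit for t in trials],
            "t_hit": [t.t_hit for t in trials],
        }
    )
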