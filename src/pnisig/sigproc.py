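"""Preprocessing and basic signal metrics shared by acute and chronic analyses.

The conventions here mirror routine extracellular-electrophysiology practice
for multichannel nerve recordings:

* **common-mode subtraction** removes the per-sample across-channel mean,
  cancelling interference shared by all electrodes (movement artifact,
  electromagnetic pickup) while preserving channel-unique neural signal;
* **zero-phase band-pass filtering** (forward-backward IIR) isolates the
  multi-unit band without introducing group delay, so response latencies
  measured downstream are unbiased;
* the **activity envelope** is the squared signal smoothed with a boxcar
  (default 20 ms window advanced in 1 ms steps), a standard proxy for
  multi-unit firing intensity.

All voltages are in microvolts (µV); envelopes are therefore in µV².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps


@dataclass
class Channel:
    """Identity and wiring layer of one electrode channel."""

    id: str
    layer: str = "L1"  # "L1" or "L2" (bi-layer array wiring)


@dataclass
class Recording:
    """A multichannel extracellular voltage trace.

    Attributes
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Voltage in µV.
    fs : float
        Sampling rate in Hz (acute acquisition default is 24 400 Hz).
    channels : list of Channel
        Per-channel metadata; length must match the sample matrix.
    t0 : float
        Session-relative start time in seconds.
    """

    samples: np.ndarray
    fs: float
    channels: list[Channel] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            self.channels = [Channel(id=f"ch{i}") for i in range(self.samples.shape[1])]
        if len(self.channels) != self.samples.shape[1]:
            raise ValueError(
                f"channel metadata ({len(self.channels)}) does not match "
                f"sample matrix ({self.samples.shape[1]} columns)"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Session-relative sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class Envelope:
    """Non-negative per-bin activity envelope (µV²) on a 1 ms time base."""

    values: np.ndarray
    bin_width: float = 1.0  # ms between bin centers
    window: float = 20.0  # ms boxcar used to compute it
    t0: float = 0.0  # session-relative time of first bin center (s)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < -1e-12):
            raise ValueError("envelope values must be non-negative")

    def __len__(self) -> int:
        return self.values.shape[0]


def common_mode_subtract(rec: Recording) -> Recording:
    """Subtract the per-sample across-channel mean from every channel.

    After subtraction the mean across channels is identically zero at every
    sample, which cancels interference common to all electrodes. Requires at
    least two channels (with one channel the operation would zero the data).
    """
    if rec.n_channels < 2:
        raise ValueError("common-mode subtraction requires >= 2 channels")
    cm = rec.samples.mean(axis=1, keepdims=True)
    return replace(rec, samples=rec.samples - cm)


def _design_sos(low: float, high: float, fs: float, family: str, order: int) -> np.ndarray:
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({fs / 2} Hz)"
        )
    ftype = {"butterworth": "butter", "bessel": "bessel"}.get(family)
    if ftype is None:
        raise ValueError(f"unknown filter family {family!r}")
    return sps.iirfilter(
        order, [low, high], btype="bandpass", ftype=ftype, fs=fs, output="sos"
    )


def bandpass_zero_phase(
    rec: Recording,
    low: float,
    high: float,
    family: str = "butterworth",
    order: int = 2,
) -> Recording:
    """Forward-backward band-pass filter (zero net phase shift).

    Parameters follow the acquisition/analysis chains used for nerve data:
    a 1 Hz–10 kHz Bessel filter at acquisition and a 0.3–6 kHz 2-pole
    Butterworth for analysis. Edge transients are suppressed by odd
    reflection padding spanning at least three time constants of the low
    cutoff.
    """
    sos = _design_sos(low, high, rec.fs, family, order)
    # >= 3 time constants of the slowest (low-cutoff) dynamics
    padlen = min(rec.n_samples - 1, int(3 * rec.fs / low))
    out = sps.sosfiltfilt(sos, rec.samples, axis=0, padtype="odd", padlen=padlen)
    return replace(rec, samples=out)


def envelope(rec_or_trace, window: float = 20.0, advance: float = 1.0, fs: float | None = None) -> Envelope:
    """Squared-and-smoothed activity envelope.

    The value at bin k is the boxcar mean of the squared signal centered on
    that bin; bins whose boxcar window would extend past either edge of the
    trace are dropped (edge policy: no partial windows, so correlations
    downstream never see biased edge values). For multichannel input the
    channels are averaged after squaring.

    Parameters
    ----------
    rec_or_trace : Recording or 1-D/2-D array
        Voltage trace (µV). If an array is given, `fs` must be supplied.
    window, advance : float
        Boxcar width and bin spacing, both in ms; `window >= advance`.
    """
    if isinstance(rec_or_trace, Recording):
        x = rec_or_trace.samples
        fs = rec_or_trace.fs
        t0 = rec_or_trace.t0
    else:
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
        x = np.asarray(rec_or_trace, dtype=np.float64)
        if x.ndim == 1:
            x = x[:, None]
        t0 = 0.0
    if window < advance:
        raise ValueError("window must be >= advance")
    win_n = int(round(window * fs / 1000.0))
    hop_n = max(1, int(round(advance * fs / 1000.0)))
    if win_n < 1:
        raise ValueError("window shorter than one sample")
    if x.shape[0] < win_n:
        raise ValueError("trace shorter than one boxcar window")
    sq = (x**2).mean(axis=1)
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    starts = np.arange(0, x.shape[0] - win_n + 1, hop_n)
    vals = (csum[starts + win_n] - csum[starts]) / win_n
    # first bin center sits half a window into the trace
    t0_env = t0 + (win_n / 2) / fs
    vals = np.maximum(vals, 0.0)  # guard tiny negative rounding
    return Envelope(values=vals, bin_width=advance, window=window, t0=t0_env)


def noise_metrics(
    rec: Recording,
    band: tuple[float, float],
    family: str = "butterworth",
    order: int = 2,
    psd_segment_s: float = 1.0,
) -> dict:
    """Baseline-noise summary: band-limited RMS, peak-to-peak, and PSD.

    RMS and Vpp are computed after zero-phase band-pass filtering to `band`;
    the PSD is an averaged modified periodogram (Welch, Hann window,
    `psd_segment_s` segments, 50% overlap) of the unfiltered trace. All
    values are averaged across channels; per-channel values are included.
    """
    if rec.n_samples == 0:
        raise ValueError("empty trace")
    filt = bandpass_zero_phase(rec, band[0], band[1], family=family, order=order)
    # exclude a settling margin at both edges (residual filter transients)
    margin = min(rec.n_samples // 10, int(3 * rec.fs / band[0]))
    core = filt.samples[margin : rec.n_samples - margin] if margin > 0 else filt.samples
    rms_ch = np.sqrt((core**2).mean(axis=0))
    vpp_ch = core.max(axis=0) - core.min(axis=0)
    nper = min(rec.n_samples, int(round(psd_segment_s * rec.fs)))
    freqs, psd = sps.welch(rec.samples, fs=rec.fs, nperseg=nper, axis=0)
    return {
        "rms": float(rms_ch.mean()),
        "vpp": float(vpp_ch.mean()),
        "rms_per_channel": rms_ch,
        "vpp_per_channel": vpp_ch,
        "psd_freqs": freqs,
        "psd": psd.mean(axis=1),
        "psd_per_channel": psd,
    }
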