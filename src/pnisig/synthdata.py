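"""Synthetic nerve-recording generator with known ground truth.

Every analysis stage in this package can be validated without animal data by
generating three kinds of sessions that mimic recordings from a multichannel
cuff-style interface on a small (~150 µm) nerve:

* **baseline noise** — band-limited Gaussian traces whose RMS matches a
  named electrode noise class (pre- vs post-electroplating);
* **acute stimulation sessions** — stimulation trials at commanded currents,
  each containing a biphasic stimulation artifact at t = 0, a compound-
  action-potential-like evoked waveform whose amplitude follows a fiber-
  recruitment sigmoid of current and whose onset latency is conduction
  distance / velocity (velocity drawn per trial), plus additive noise;
* **chronic singing sessions** — stereotyped per-channel multi-unit activity
  envelopes (a shared component mixed with channel-unique components),
  expressed as inhomogeneous-Poisson spike trains, warped in time from
  rendition to rendition by a smooth random monotone map, plus noise.

Ground truth (per-trial evoked amplitude and latency, per-rendition warp,
per-channel true envelopes) is returned alongside every generated session.
A single integer seed expands into independent per-trial substreams via
`numpy.random.SeedSequence`, so identical (scenario, seed) pairs yield
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .evoked import SigmoidParams
from .sigproc import Channel, Recording, bandpass_zero_phase


# ---------------------------------------------------------------------------
# scenario types


@dataclass
class NoisePreset:
    """Target baseline-noise class for generated traces.

    ``rms`` is the per-channel RMS in µV inside the shaping ``band`` (Hz).
    The two named presets bracket the effect of electroplating the
    electrode sites: un-plated electrodes show >60 µV peak-to-peak noise in
    a 0.001–7.5 kHz bandwidth, plated ones <10 µV.
    """

    rms: float
    band: tuple[float, float] = (1.0, 7500.0)
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise ValueError("rms must be non-negative")
        if self.band[0] >= self.band[1]:
            raise ValueError("band low must be < band high")


def pre_plating_noise() -> NoisePreset:
    """High-impedance (un-plated) electrode noise: Vpp well above 60 µV."""
    return NoisePreset(rms=10.0, band=(1.0, 7500.0), name="pre-plating")


def post_plating_noise() -> NoisePreset:
    """Plated low-impedance electrode noise: Vpp below 10 µV."""
    return NoisePreset(rms=1.0, band=(1.0, 7500.0), name="post-plating")


@dataclass
class AcuteScenario:
    """Parameters of a simulated acute stimulation session.

    Currents are signed µA (positive = cathodic-first); evoked amplitude is
    ``block_factor`` × sigmoid(|current|) with the 4PL ground truth in
    ``recruit`` (``block_factor`` 1 = saline control, ~0 = lidocaine nerve
    block), gated to exactly 0 at 0 µA (no pulse, no response). Onset
    latency is ``distance_mm`` / velocity with velocity drawn uniformly from
    ``velocity_range`` per trial. Stimuli are spaced ``isi_s`` apart
    (default 1 s, i.e., 1 Hz delivery).
    """

    currents: list[float]
    trials_per_current: int = 40
    fs: float = 24_400.0
    distance_mm: float = 20.0
    velocity_range: tuple[float, float] = (4.0, 24.0)
    recruit: SigmoidParams = field(
        default_factory=lambda: SigmoidParams(Vmin=0.0, Vmax=100.0, I50=35.0, slope=5.0)
    )
    artifact_amp: float = 200.0  # µV
    block_factor: float = 1.0
    noise: NoisePreset = field(default_factory=post_plating_noise)
    isi_s: float = 1.0
    phase_us: float = 200.0
    command_offset_ms: float = 0.0  # true artifact onset minus commanded time
    n_channels: int = 6

    def __post_init__(self) -> None:
        if self.trials_per_current < 1:
            raise ValueError("trials_per_current must be >= 1")
        if not 0 <= self.block_factor <= 1:
            raise ValueError("block_factor must lie in [0, 1]")
        if self.noise.rms > 0 and self.fs <= 2 * self.noise.band[1]:
            raise ValueError("fs must exceed twice the noise shaping band upper edge")
        if self.velocity_range[0] <= 0 or self.velocity_range[0] > self.velocity_range[1]:
            raise ValueError("invalid velocity range")


@dataclass
class ChronicScenario:
    """Parameters of a simulated chronic singing session.

    Each channel's true per-ms activity envelope is
    ``shared_weight`` × shared + (1 − shared_weight) × unique(channel).
    Renditions are produced by warping a fixed per-(seed, channel)
    inhomogeneous-Poisson multi-unit spike pattern with a piecewise-linear
    monotone time map (knots every ``warp_knot_ms``, segment slopes in
    [1 − warp_jitter, 1 + warp_jitter]) and adding preset noise, so all
    rendition-to-rendition variability comes from the warp and the noise.
    """

    n_channels: int = 6
    motif_len_ms: int = 600
    shared_envelope: np.ndarray | None = None  # per-ms, length motif_len_ms
    unique_envelopes: np.ndarray | None = None  # (n_channels, motif_len_ms)
    shared_weight: float = 0.8
    warp_jitter: float = 0.1
    warp_knot_ms: float = 50.0
    spike_rate: float = 200.0  # mean events/s per channel
    spike_amp_uv: float = 60.0
    noise: NoisePreset = field(default_factory=post_plating_noise)
    renditions_per_day: int = 60
    n_days: int = 14
    fs: float = 24_400.0
    gap_s: float = 0.4  # silence between renditions
    env_seed: int = 0  # used only to synthesize default envelopes

    def __post_init__(self) -> None:
        if not 0 <= self.shared_weight <= 1:
            raise ValueError("shared_weight must lie in [0, 1]")
        if self.warp_jitter < 0:
            raise ValueError("warp_jitter must be >= 0")
        if self.noise.rms > 0 and self.fs <= 2 * self.noise.band[1]:
            raise ValueError("fs must exceed twice the noise shaping band upper edge")
        rng = np.random.default_rng(np.random.SeedSequence([self.env_seed, 917]))
        if self.shared_envelope is None:
            self.shared_envelope = _smooth_envelope(rng, self.motif_len_ms)
        if self.unique_envelopes is None:
            self.unique_envelopes = np.stack(
                [_smooth_envelope(rng, self.motif_len_ms) for _ in range(self.n_channels)]
            )
        self.shared_envelope = np.asarray(self.shared_envelope, dtype=float)
        self.unique_envelopes = np.asarray(self.unique_envelopes, dtype=float)
        if np.any(self.shared_envelope < 0) or np.any(self.unique_envelopes < 0):
            raise ValueError("envelopes must be non-negative")
        # audio amplitude-envelope template for the song itself
        self.audio_template = _smooth_envelope(rng, self.motif_len_ms) + 0.2

    def true_envelope(self, channel: int) -> np.ndarray:
        """Ground-truth per-ms envelope of one channel (template time)."""
        return (
            self.shared_weight * self.shared_envelope
            + (1.0 - self.shared_weight) * self.unique_envelopes[channel]
        )


def _smooth_envelope(rng: np.random.Generator, n_ms: int, smooth_ms: float = 15.0) -> np.ndarray:
    """Non-negative smooth random per-ms envelope with mean ≈ 1."""
    x = gaussian_filter1d(rng.standard_normal(n_ms * 2), smooth_ms)[n_ms // 2 : n_ms // 2 + n_ms]
    x = x - x.min() + 0.05 * x.std()
    return x / x.mean()


@dataclass
class AcuteGroundTruth:
    """Per-trial generative parameters of an acute session."""

    currents: np.ndarray
    amplitudes: np.ndarray  # evoked amplitude A (waveform peak +A, trough −A), µV
    latencies_ms: np.ndarray
    velocities: np.ndarray  # m/s
    onset_times_s: np.ndarray  # true artifact onset (session time)


@dataclass
class ChronicGroundTruth:
    """Per-rendition and per-channel generative parameters of one day."""

    true_envelopes: np.ndarray  # (n_channels, motif_len_ms), template time
    warps_ms: list[np.ndarray]  # per rendition: rendition time (ms) of each template ms
    starts_s: np.ndarray
    durations_s: np.ndarray
    audio_template: np.ndarray  # per-ms amplitude envelope, template time
    audio_features: list[np.ndarray]  # per-rendition per-ms amplitude envelope
    spike_times_ms: list[np.ndarray]  # per channel, template time
    spike_amps: list[np.ndarray]


# ---------------------------------------------------------------------------
# noise


def gen_noise(
    preset: NoisePreset, duration: float, fs: float, n_channels: int = 6, seed: int = 0
) -> Recording:
    """Band-limited Gaussian noise scaled to the preset RMS.

    White Gaussian noise is shaped with a zero-phase 4-pole Butterworth
    band-pass over ``preset.band`` and rescaled per channel to the target
    RMS exactly; a zero-RMS preset yields an all-zero trace. Reproducible
    under a fixed seed.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    n = int(round(duration * fs))
    chans = [Channel(id=f"ch{i}", layer="L1" if i < n_channels / 2 else "L2") for i in range(n_channels)]
    if preset.rms == 0:
        return Recording(samples=np.zeros((n, n_channels)), fs=fs, channels=chans)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    x = rng.standard_normal((n, n_channels))
    rec = Recording(samples=x, fs=fs, channels=chans)
    hi = min(preset.band[1], 0.499 * fs)
    rec = bandpass_zero_phase(rec, preset.band[0], hi, family="butterworth", order=4)
    cur = np.sqrt((rec.samples**2).mean(axis=0))
    rec.samples *= preset.rms / cur[None, :]
    return rec


# ---------------------------------------------------------------------------
# acute sessions


def _evoked_kernel(sigma_ms: float, fs: float) -> np.ndarray:
    """Biphasic Gaussian-derivative compound-action-potential kernel.

    Antisymmetric about its center; normalized so the peak is +1 and the
    trough −1. Support is 6σ starting at the response onset.
    """
    n = max(3, int(round(6 * sigma_ms * fs / 1000.0)))
    t = np.arange(n) / fs * 1000.0  # ms
    c = 3 * sigma_ms
    k = -(t - c) / sigma_ms * np.exp(-((t - c) ** 2) / (2 * sigma_ms**2))
    return k / np.abs(k).max()


def _artifact_kernel(amp: float, fs: float, phase_us: float, tau_ms: float = 0.08) -> np.ndarray:
    """Biphasic square stimulation transient with an exponential tail."""
    ph = max(1, int(round(phase_us * 1e-6 * fs)))
    tail_n = max(1, int(round(5 * tau_ms * fs / 1000.0)))
    t_tail = np.arange(1, tail_n + 1) / fs * 1000.0
    return np.concatenate(
        [np.full(ph, amp), np.full(ph, -amp), -amp * np.exp(-t_tail / tau_ms)]
    )


def gen_acute_session(
    scenario: AcuteScenario, seed: int = 0
) -> tuple[Recording, pd.DataFrame, AcuteGroundTruth]:
    """Generate one acute stimulation session.

    Trials cycle through ``scenario.currents`` (round-robin,
    ``trials_per_current`` passes) with ``isi_s`` spacing. Each stimulation
    event deposits a biphasic artifact at its (possibly offset) onset, an
    evoked waveform with recruitment-sigmoid amplitude and conduction-delay
    latency, and rides on preset noise. Channel waveform shapes differ
    (distinct kernel widths and polarities). Returns the recording, the
    stimulation event table and the per-trial ground truth.
    """
    s = scenario
    if not s.currents:
        raise ValueError("currents list must not be empty")
    fs = s.fs
    n_ev = len(s.currents) * s.trials_per_current
    lead = max(0.03, min(s.isi_s, 0.5))
    times = lead + np.arange(n_ev) * s.isi_s
    total_s = times[-1] + max(0.03, min(s.isi_s, 0.5))
    n = int(round(total_s * fs))

    currents = np.array([s.currents[k % len(s.currents)] for k in range(n_ev)], dtype=float)
    root = np.random.SeedSequence([seed, 211])
    trial_ss = root.spawn(n_ev)

    noise_rec = gen_noise(s.noise, total_s, fs, s.n_channels, seed=seed)
    x = noise_rec.samples[:n]

    sigmas = np.linspace(0.18, 0.32, s.n_channels)
    signs = np.array([1.0 if c % 2 == 0 else -1.0 for c in range(s.n_channels)])
    kernels = [_evoked_kernel(sig, fs) for sig in sigmas]
    art = _artifact_kernel(s.artifact_amp, fs, s.phase_us)

    amps = np.empty(n_ev)
    lats = np.empty(n_ev)
    vels = np.empty(n_ev)
    onsets = times + s.command_offset_ms / 1000.0
    for k in range(n_ev):
        rng = np.random.default_rng(trial_ss[k])
        v = rng.uniform(*s.velocity_range)
        vels[k] = v
        lats[k] = s.distance_mm / v  # mm / (m/s) = ms
        i_abs = abs(currents[k])
        amps[k] = 0.0 if i_abs == 0 else s.block_factor * s.recruit(i_abs)
        i_on = int(round(onsets[k] * fs))
        pol = 1.0 if currents[k] >= 0 else -1.0
        if s.artifact_amp > 0:
            seg = art[: max(0, n - i_on)]
            x[i_on : i_on + seg.size] += pol * seg[:, None]
        if amps[k] > 0:
            i_resp = i_on + int(round(lats[k] * fs / 1000.0))
            for c in range(s.n_channels):
                seg = kernels[c][: max(0, n - i_resp)]
                x[i_resp : i_resp + seg.size, c] += amps[k] * signs[c] * seg

    rec = Recording(
        samples=x.astype(np.float32).astype(np.float64),  # container-exact values
        fs=fs,
        channels=noise_rec.channels,
    )
    events = pd.DataFrame(
        {
            "time_s": times,
            "current_uA": currents,
            "polarity": np.where(currents >= 0, "cathodic-first", "anodic-first"),
        }
    )
    gt = AcuteGroundTruth(
        currents=currents,
        amplitudes=amps,
        latencies_ms=lats,
        velocities=vels,
        onset_times_s=onsets,
    )
    return rec, events, gt


def standard_acute_scenario(**overrides) -> AcuteScenario:
    """The acute stimulation preset: 10–110 µA in 5 µA steps, 40 trials per
    current, 1 Hz biphasic pulses (200 µs/phase), ~20 mm conduction path,
    4–24 m/s fiber velocities, recruitment saturating (95% of max) near
    50 µA."""
    params = dict(
        currents=list(np.arange(10.0, 111.0, 5.0)),
        trials_per_current=40,
    )
    params.update(overrides)
    return AcuteScenario(**params)


# ---------------------------------------------------------------------------
# chronic sessions


def _draw_warp(
    rng: np.random.Generator, motif_len_ms: float, knot_ms: float, jitter: float
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear monotone template→rendition time map.

    Knots every ``knot_ms`` in template time; segment slopes drawn uniformly
    from [1 − jitter, 1 + jitter]. Returns (template knots, rendition knots)
    in ms, both starting at 0.
    """
    n_seg = max(1, int(np.ceil(motif_len_ms / knot_ms)))
    tk = np.minimum(np.arange(n_seg + 1) * knot_ms, motif_len_ms)
    slopes = rng.uniform(1.0 - jitter, 1.0 + jitter, n_seg)
    rk = np.concatenate([[0.0], np.cumsum(slopes * np.diff(tk))])
    return tk, rk


def gen_chronic_session(
    scenario: ChronicScenario, day: int = 0, seed: int = 0, with_audio: bool = True
) -> tuple[Recording, pd.DataFrame, ChronicGroundTruth]:
    """Generate one day of chronic singing-related activity.

    A multi-unit spike pattern is drawn once per (seed, channel) in template
    time as an inhomogeneous Poisson process whose rate follows the
    channel's true envelope; each rendition time-warps that fixed pattern
    with its own random monotone map and adds preset noise. With zero warp
    jitter and zero noise all renditions of a channel are therefore
    sample-identical. Because the spike pattern does not depend on ``day``,
    consecutive days generated from one seed are statistically stationary
    (warp and noise substreams do advance with the day index), which is the
    null condition for day-over-day stability tests. Returns the recording,
    the motif annotation table and the ground truth (true envelopes, warps,
    spike pattern, audio features).
    """
    s = scenario
    fs = s.fs
    ss_spikes = np.random.SeedSequence([seed, 307])
    ss_warp, ss_noise, ss_audio = np.random.SeedSequence([seed, 331, day]).spawn(3)

    # fixed per-(seed, channel) spike pattern in template time
    spike_times: list[np.ndarray] = []
    spike_amps: list[np.ndarray] = []
    ch_ss = ss_spikes.spawn(s.n_channels)
    for c in range(s.n_channels):
        rng = np.random.default_rng(ch_ss[c])
        env = s.true_envelope(c)
        lam = s.spike_rate * env / env.mean() * 1e-3  # events per ms
        counts = rng.poisson(lam)
        t_ms = np.repeat(np.arange(s.motif_len_ms, dtype=float), counts) + rng.uniform(
            0, 1, counts.sum()
        )
        order = np.argsort(t_ms)
        spike_times.append(t_ms[order])
        spike_amps.append(s.spike_amp_uv * rng.uniform(0.6, 1.4, t_ms.size)[order])

    # per-rendition warps and timing
    warp_rngs = [np.random.default_rng(c) for c in ss_warp.spawn(s.renditions_per_day)]
    tmpl_ms = np.arange(s.motif_len_ms, dtype=float)
    warps: list[np.ndarray] = []
    knots: list[tuple[np.ndarray, np.ndarray]] = []
    durs = np.empty(s.renditions_per_day)
    for r in range(s.renditions_per_day):
        tk, rk = _draw_warp(warp_rngs[r], s.motif_len_ms, s.warp_knot_ms, s.warp_jitter)
        knots.append((tk, rk))
        warps.append(np.interp(tmpl_ms, tk, rk))
        durs[r] = rk[-1] / 1000.0
    starts = np.empty(s.renditions_per_day)
    t_cursor = s.gap_s
    for r in range(s.renditions_per_day):
        starts[r] = round(t_cursor * fs) / fs  # sample-aligned rendition onsets
        t_cursor = starts[r] + durs[r] + s.gap_s
    total_s = t_cursor
    n = int(round(total_s * fs))

    noise_rec = gen_noise(s.noise, total_s, fs, s.n_channels, seed=_sub_seed(ss_noise))
    x = noise_rec.samples[:n]

    spike_kernel = _spike_kernel(fs)
    for r in range(s.renditions_per_day):
        tk, rk = knots[r]
        for c in range(s.n_channels):
            t_rend = np.interp(spike_times[c], tk, rk)  # ms in rendition time
            idx = (starts[r] * fs + t_rend * fs / 1000.0).astype(int)
            for i, a in zip(idx, spike_amps[c]):
                seg = spike_kernel[: max(0, n - i)]
                x[i : i + seg.size, c] += a * seg

    # per-rendition audio amplitude envelope (template envelope in rendition time)
    audio_feats: list[np.ndarray] = []
    for r in range(s.renditions_per_day):
        tk, rk = knots[r]
        n_ms = int(np.floor(durs[r] * 1000.0))
        rend_ms = np.arange(n_ms, dtype=float)
        t_tmpl = np.interp(rend_ms, rk, tk)
        audio_feats.append(np.interp(t_tmpl, tmpl_ms, s.audio_template))

    audio = None
    if with_audio:
        rng_a = np.random.default_rng(ss_audio)
        wav = np.zeros(n, dtype=np.float64)
        for r in range(s.renditions_per_day):
            feat = audio_feats[r]
            i0 = int(round(starts[r] * fs))
            n_r = int(round(durs[r] * fs))
            env_fs = np.interp(np.arange(n_r) / fs * 1000.0, np.arange(feat.size, dtype=float), feat)
            wav[i0 : i0 + n_r] += env_fs[: max(0, n - i0)] * rng_a.standard_normal(
                min(n_r, max(0, n - i0))
            )
        audio = (int(fs), (wav / max(1e-9, np.abs(wav).max()) * 0.9).astype(np.float32))

    rec = Recording(
        samples=x.astype(np.float32).astype(np.float64),
        fs=fs,
        channels=noise_rec.channels,
    )
    motifs = pd.DataFrame(
        {
            "start_s": starts,
            "stop_s": starts + durs,
            "duration_unwarped_s": durs,
        }
    )
    gt = ChronicGroundTruth(
        true_envelopes=np.stack([s.true_envelope(c) for c in range(s.n_channels)]),
        warps_ms=warps,
        starts_s=starts,
        durations_s=durs,
        audio_template=s.audio_template,
        audio_features=audio_feats,
        spike_times_ms=spike_times,
        spike_amps=spike_amps,
    )
    gt.audio = audio  # type: ignore[attr-defined]  # (fs, waveform) when generated
    return rec, motifs, gt


def _spike_kernel(fs: float) -> np.ndarray:
    """1 ms biphasic multi-unit spike shape (Hann-windowed sine cycle)."""
    n = max(3, int(round(fs / 1000.0)))
    u = np.arange(n) / n
    k = np.sin(2 * np.pi * u) * np.hanning(n)
    return k / np.abs(k).max()


def _sub_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))
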