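"""End-to-end analysis drivers built from the module operations.

These functions chain the canonical processing order:

* acute:   common-mode subtract → zero-phase band-pass → trial extraction
           (artifact-onset alignment) → artifact blanking → Vpp /
           detection / recruitment fit;
* chronic: common-mode subtract → zero-phase band-pass → per-motif cut →
           squared-and-smoothed envelopes → DTW alignment of the audio
           feature to a template → warp applied to the neural envelopes.

They are what the command-line entry points and the analysis scripts call;
tests exercise them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evoked, songalign, stability
from .sigproc import Recording, bandpass_zero_phase, common_mode_subtract, envelope


@dataclass
class AcuteConfig:
    """Processing parameters for acute sessions."""

    band: tuple[float, float] = (300.0, 6000.0)
    family: str = "butterworth"
    order: int = 2
    pre_ms: float = 5.0
    post_ms: float = 25.0
    window: evoked.ResponseWindow = field(default_factory=evoked.ResponseWindow)
    blank: tuple[float, float] = (-0.1, 0.75)
    bin_width: float = 5.0
    common_mode: bool = True


def preprocess(rec: Recording, band: tuple[float, float], family: str = "butterworth",
               order: int = 2, common_mode: bool = True) -> Recording:
    """Common-mode subtraction followed by zero-phase band-pass filtering."""
    if common_mode and rec.n_channels >= 2:
        rec = common_mode_subtract(rec)
    return bandpass_zero_phase(rec, band[0], band[1], family=family, order=order)


def acute_trials(
    rec: Recording, events: pd.DataFrame, cfg: AcuteConfig | None = None
) -> tuple[list[evoked.StimTrial], int]:
    """Preprocess a session and return blanked, aligned stimulation trials."""
    cfg = cfg or AcuteConfig()
    pre = preprocess(rec, cfg.band, cfg.family, cfg.order, cfg.common_mode)
    trials, skipped = evoked.extract_trials(pre, events, pre_ms=cfg.pre_ms, post_ms=cfg.post_ms)
    trials = [evoked.blank_artifact(t, cfg.blank, cfg.window) for t in trials]
    return trials, skipped


def acute_recruitment(
    rec: Recording, events: pd.DataFrame, cfg: AcuteConfig | None = None
) -> evoked.RecruitmentCurve:
    """Full acute chain ending in a fitted recruitment curve."""
    cfg = cfg or AcuteConfig()
    trials, _ = acute_trials(rec, events, cfg)
    curve = evoked.recruitment_curve(trials, bin_width=cfg.bin_width, window=cfg.window)
    curve.fit = evoked.fit_recruitment(curve)
    return curve


def channel_envelopes(rec: Recording, window: float = 20.0, advance: float = 1.0) -> np.ndarray:
    """Per-channel squared-and-smoothed envelopes, (n_channels, n_bins)."""
    return np.stack(
        [envelope(rec.samples[:, c], window=window, advance=advance, fs=rec.fs).values
         for c in range(rec.n_channels)]
    )


def chronic_aligned_envelopes(
    rec: Recording,
    motifs: pd.DataFrame,
    features: list[np.ndarray],
    band: tuple[float, float] = (300.0, 6000.0),
    template: songalign.Template | None = None,
    template_n: int = 25,
    dtw_band: float = 0.2,
    env_window_ms: float = 20.0,
) -> tuple[np.ndarray, songalign.Template]:
    """Motif-aligned neural envelopes for one chronic session.

    ``features`` supplies one per-ms audio feature sequence per rendition
    (from :func:`pnisig.songalign.audio_feature` or from the simulator).
    Each rendition's neural segment (padded by half the envelope window so
    envelope bins cover the motif span exactly) is enveloped per channel,
    the audio feature is DTW-aligned to the template, and the warp is
    applied to the neural envelopes.

    Returns (aligned, template) where ``aligned`` has shape
    (n_renditions, n_channels, template_len).
    """
    pre = preprocess(rec, band)
    if template is None:
        template = songalign.build_template(features, n=template_n)
    tlen = template.feature.size
    pad_s = env_window_ms / 2000.0
    aligned = []
    for r, (_, row) in enumerate(motifs.iterrows()):
        i0 = max(0, int(round((row["start_s"] - pad_s - pre.t0) * pre.fs)))
        i1 = min(pre.n_samples, int(round((row["stop_s"] + pad_s - pre.t0) * pre.fs)))
        seg = Recording(samples=pre.samples[i0:i1], fs=pre.fs, channels=pre.channels)
        envs = channel_envelopes(seg, window=env_window_ms)
        feat = np.asarray(features[r], dtype=float)
        L = min(feat.size, envs.shape[1])
        path = songalign.dtw_align(feat[:L], template, band=dtw_band)
        aligned.append(songalign.apply_warp(envs[:, :L], path, tlen))
    return np.stack(aligned), template


def daily_channel_metrics(
    aligned: np.ndarray,
    filt_rec: Recording,
    motifs: pd.DataFrame,
    reference: np.ndarray,
    exclude: set[int] | None = None,
) -> dict[str, np.ndarray]:
    """Per-channel daily stability metrics from one session's aligned envelopes.

    ``reference`` is the day-1 mean envelope per channel, (n_channels, T);
    rendition indices in ``exclude`` (e.g., the block the reference was
    built from, on day 1 itself) are left out of the correlation average so
    the reference day is not compared against its own reference block.
    Returns arrays keyed "correlation", "vpp", "event_rate".
    """
    stab = stability
    exclude = exclude or set()
    n_rend, n_ch, _ = aligned.shape
    use = [r for r in range(n_rend) if r not in exclude]
    corr = np.array([
        np.mean([stab.envelope_corr(reference[c], aligned[r, c]) for r in use])
        for c in range(n_ch)
    ])
    vpp = np.mean(
        [stab.motif_vpp(filt_rec, (row["start_s"], row["stop_s"]))
         for _, row in motifs.iterrows()],
        axis=0,
    )
    rate = np.array([
        np.mean([
            stab.event_rate(aligned[r, c], motifs["duration_unwarped_s"].iloc[r])
            for r in range(n_rend)
        ])
        for c in range(n_ch)
    ])
    return {"correlation": corr, "vpp": vpp, "event_rate": rate}
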