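"""Chronic recording stability metrics.

Multi-week nerve recordings are judged stable when (i) song-aligned
activity envelopes keep correlating with the day-1 reference, (ii) signal
amplitude (per-motif peak-to-peak voltage) holds steady, and (iii) the
envelope event rate holds steady. A complementary spatial check is that
envelopes recorded on the *same* electrode correlate more strongly across
renditions than envelopes recorded on *different* electrodes — evidence
that each electrode samples a distinct subcomponent of nerve activity
rather than one common signal.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .sigproc import Envelope, Recording


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (zero variance input)."""


def _values(env) -> np.ndarray:
    return env.values if isinstance(env, Envelope) else np.asarray(env, dtype=float)


def envelope_corr(a, b) -> float:
    """Pearson correlation between two equal-length activity envelopes."""
    x, y = _values(a), _values(b)
    if x.size != y.size:
        raise ValueError("envelopes must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 bins")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero-variance envelope")
    return float(np.corrcoef(x, y)[0, 1])


def envelope_corr_matrix(env_sets: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise correlation matrix over all renditions of all channels.

    ``env_sets[c]`` is an (n_renditions, n_bins) array for channel ``c``.
    Returns (matrix, channel_labels) where the matrix rows/columns run over
    renditions grouped by channel.
    """
    stackd = np.vstack([np.atleast_2d(e) for e in env_sets])
    labels = np.concatenate(
        [np.full(np.atleast_2d(e).shape[0], c) for c, e in enumerate(env_sets)]
    )
    sd = stackd.std(axis=1)
    if np.any(sd == 0):
        raise UndefinedCorrelationError("zero-variance envelope in set")
    return np.corrcoef(stackd), labels


def _within_across_means(env_sets: list[np.ndarray]) -> tuple[float, float]:
    mat, labels = envelope_corr_matrix(env_sets)
    iu = np.triu_indices_from(mat, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = mat[iu]
    if not same.any() or same.all():
        raise ValueError("need both within- and across-channel rendition pairs")
    return float(vals[same].mean()), float(vals[~same].mean())


def within_across_summary(subjects) -> dict:
    """Same-electrode vs different-electrode envelope correlation.

    ``subjects`` is a list (one entry per subject/bird) of per-channel
    rendition sets: each entry is a list where element ``c`` is an
    (n_renditions, n_bins) array of channel ``c`` envelopes. A single
    subject's set may be passed directly. All rendition pairs contribute
    (same-channel pairs → within, different-channel pairs → across); the
    per-subject within/across means are compared with a two-tailed paired
    t-test when ≥2 subjects are available.
    """
    if subjects and isinstance(subjects[0], np.ndarray):
        subjects = [subjects]
    per_within, per_across = [], []
    for env_sets in subjects:
        if len(env_sets) < 2:
            raise ValueError("need >= 2 channels per subject")
        w, a = _within_across_means(env_sets)
        per_within.append(w)
        per_across.append(a)
    per_within = np.array(per_within)
    per_across = np.array(per_across)
    t = p = float("nan")
    if len(subjects) >= 2:
        if np.allclose(per_within, per_across):
            t, p = 0.0, 1.0
        else:
            t, p = (float(v) for v in stats.ttest_rel(per_within, per_across))
    return {
        "within_mean": float(per_within.mean()),
        "across_mean": float(per_across.mean()),
        "per_subject_within": per_within,
        "per_subject_across": per_across,
        "t": t,
        "p": p,
    }


def running_stability(
    renditions: np.ndarray,
    ref_block: int = 25,
    window: int = 25,
    advance: int = 1,
) -> dict:
    """Sliding correlation of aligned envelopes to the day-1 reference.

    The reference is the mean envelope of the first ``ref_block``
    renditions; series value k is the Pearson correlation between the
    reference and the mean envelope of the ``window`` renditions starting
    at k. The day-1 self-consistency point is the correlation between the
    means of the first two consecutive ``ref_block``-rendition blocks.
    """
    renditions = np.atleast_2d(np.asarray(renditions, dtype=float))
    n = renditions.shape[0]
    if n < ref_block + window:
        raise ValueError(f"need >= {ref_block + window} renditions, got {n}")
    ref = renditions[:ref_block].mean(axis=0)
    positions = np.arange(0, n - window + 1, advance)
    series = np.array(
        [envelope_corr(ref, renditions[k : k + window].mean(axis=0)) for k in positions]
    )
    day1_self = (
        envelope_corr(ref, renditions[ref_block : 2 * ref_block].mean(axis=0))
        if n >= 2 * ref_block
        else float("nan")
    )
    return {"positions": positions, "series": series, "day1_self": day1_self}


def motif_vpp(rec: Recording, bounds: tuple[float, float]) -> np.ndarray:
    """Per-channel peak-to-peak voltage (µV) within one motif interval (s)."""
    i0 = int(round((bounds[0] - rec.t0) * rec.fs))
    i1 = int(round((bounds[1] - rec.t0) * rec.fs))
    i0, i1 = max(i0, 0), min(i1, rec.n_samples)
    if i1 <= i0:
        raise ValueError("empty motif interval")
    seg = rec.samples[i0:i1]
    return seg.max(axis=0) - seg.min(axis=0)


def event_rate(env, duration_unwarped: float, k_sd: float = 5.0) -> float:
    """Envelope threshold-crossing rate in Hz.

    The threshold is unique to the motif: mean + ``k_sd`` × SD of its own
    envelope. Upward crossings (value rises from below to at-or-above the
    threshold) are counted and divided by the *unwarped* motif duration, so
    rates are in real time regardless of alignment. A flat envelope has no
    upward crossing and yields 0 Hz.
    """
    x = _values(env)
    if x.size == 0:
        raise ValueError("zero-length envelope")
    if duration_unwarped <= 0:
        raise ValueError("duration must be positive")
    thr = x.mean() + k_sd * x.std()
    above = x >= thr
    n_cross = int(np.count_nonzero(~above[:-1] & above[1:]))
    return n_cross / duration_unwarped


def first_last_compare(day1: dict[str, np.ndarray], last: dict[str, np.ndarray]) -> dict:
    """Two-tailed paired t-test per metric between day 1 and the last day.

    ``day1`` and ``last`` map metric name (e.g. "correlation", "vpp",
    "event_rate") to per-channel daily means; channels must match across
    days.
    """
    if set(day1) != set(last):
        raise ValueError("metric sets differ between days")
    out = {}
    for name in day1:
        a = np.asarray(day1[name], dtype=float)
        b = np.asarray(last[name], dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"channel mismatch for metric {name!r}")
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = (float(v) for v in stats.ttest_rel(a, b))
        out[name] = {"t": t, "p": p, "mean_day1": float(a.mean()), "mean_last": float(b.mean())}
    return out
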