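"""Dynamic-time-warping alignment of song-motif renditions to a template.

Songbird motifs are highly stereotyped but vary a few percent in tempo from
rendition to rendition. To compare neural activity across renditions (and
across days), each rendition's audio amplitude-envelope feature is aligned
to a common template by dynamic time warping (DTW), and the resulting warp
path is applied to the simultaneously recorded neural activity envelopes —
with no premotor time-shifting, i.e., neural time is mapped exactly as song
time.

The DTW here uses squared local cost on per-sequence z-scored features, the
step set {(1,0), (0,1), (1,1)}, and a Sakoe-Chiba band that confines the
path to a corridor around the (length-scaled) diagonal. Ties are broken
deterministically: diagonal first, then the rendition-advancing step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sigproc import Envelope


class InfeasibleBandError(ValueError):
    """The Sakoe-Chiba band is too narrow to admit any warp path."""


@dataclass
class MotifRendition:
    """One motif rendition: audio feature + simultaneous neural envelopes.

    ``feature`` is the per-ms audio amplitude-envelope sequence; ``neural``
    holds per-channel activity envelopes (n_channels, n_ms) on the same
    1 ms time base; ``bounds`` are session-relative start/stop in seconds.
    """

    feature: np.ndarray
    neural: np.ndarray | None = None
    bounds: tuple[float, float] | None = None
    duration_unwarped: float | None = None

    def __post_init__(self) -> None:
        self.feature = np.asarray(self.feature, dtype=float)
        if self.neural is not None:
            self.neural = np.atleast_2d(np.asarray(self.neural, dtype=float))
            if self.neural.shape[1] != self.feature.shape[0]:
                raise ValueError("feature and neural must share the 1 ms time base")


@dataclass
class Template:
    """Reference feature timeline that renditions are warped onto."""

    feature: np.ndarray
    n_source: int = 0

    def __post_init__(self) -> None:
        self.feature = np.asarray(self.feature, dtype=float)
        if self.feature.size == 0:
            raise ValueError("template must be non-empty")


@dataclass
class WarpPath:
    """Monotone (rendition index, template index) correspondence."""

    pairs: np.ndarray  # (K, 2) ints
    cost: float = np.nan

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be (K, 2)")
        d = np.diff(self.pairs, axis=0)
        if np.any(d < 0) or np.any(d > 1) or np.any(d.sum(axis=1) == 0):
            raise ValueError("path steps must be in {(1,0),(0,1),(1,1)}")
        if tuple(self.pairs[0]) != (0, 0):
            raise ValueError("path must start at (0, 0)")


def audio_feature(wav: np.ndarray, fs: float, smooth_ms: float = 5.0) -> np.ndarray:
    """Smoothed log amplitude envelope of an audio segment, at 1 ms resolution."""
    x = np.abs(np.asarray(wav, dtype=float))
    win = max(1, int(round(smooth_ms * fs / 1000.0)))
    csum = np.concatenate(([0.0], np.cumsum(x)))
    hop = fs / 1000.0
    starts = (np.arange(int((x.size - win) / hop) + 1) * hop).astype(int)
    sm = (csum[starts + win] - csum[starts]) / win
    return np.log(sm + 1e-6)


def build_template(renditions: list, n: int = 25) -> Template:
    """Average the first ``n`` renditions into a template.

    Each rendition's feature is linearly resampled to the median rendition
    length before element-wise averaging (convention: the template
    represents the day-1 block of consecutive motifs).
    """
    if not renditions:
        raise ValueError("need at least one rendition")
    feats = [
        np.asarray(r.feature if isinstance(r, MotifRendition) else r, dtype=float)
        for r in renditions[:n]
    ]
    target = int(np.median([f.size for f in feats]))
    grid = np.linspace(0.0, 1.0, target)
    resampled = [np.interp(grid, np.linspace(0.0, 1.0, f.size), f) for f in feats]
    return Template(feature=np.mean(resampled, axis=0), n_source=len(feats))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def band_width(m: int, n: int, band: float) -> float:
    """Sakoe-Chiba corridor half-width in template-index units."""
    return band * max(m, n)


def in_band(i: int, j: int, m: int, n: int, w: float) -> bool:
    """Whether cell (i, j) lies inside the corridor around the scaled diagonal."""
    diag = i * (n - 1) / (m - 1) if m > 1 else 0.0
    return abs(j - diag) <= w


def dtw_align(feature: np.ndarray, template: Template | np.ndarray, band: float = 0.2) -> WarpPath:
    """Align a rendition feature to the template by banded DTW.

    Minimizes the summed squared difference of per-sequence z-scored
    features over monotone paths from (0, 0) to (m−1, n−1) with steps
    {(1,0), (0,1), (1,1)}, restricted to a Sakoe-Chiba corridor of
    half-width ``band`` × max(m, n). Identical sequences map to the
    diagonal with zero cost. Raises :class:`InfeasibleBandError` if the
    corridor admits no path.
    """
    x = _zscore(np.asarray(feature, dtype=float))
    t = template.feature if isinstance(template, Template) else np.asarray(template, dtype=float)
    y = _zscore(t)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("sequences must be non-empty")
    w = band_width(m, n, band)

    inf = np.inf
    dp = np.full((m, n), inf)
    cost = (x[:, None] - y[None, :]) ** 2
    mask = np.zeros((m, n), dtype=bool)
    rows_j0 = np.empty(m, dtype=int)
    rows_j1 = np.empty(m, dtype=int)
    for i in range(m):
        diag = i * (n - 1) / (m - 1) if m > 1 else 0.0
        lo = max(0, int(np.ceil(diag - w)))
        hi = min(n - 1, int(np.floor(diag + w)))
        if hi < lo:
            rows_j0[i], rows_j1[i] = 0, -1
            continue
        rows_j0[i], rows_j1[i] = lo, hi
        mask[i, lo : hi + 1] = True
    if not (mask[0, 0] and mask[m - 1, n - 1]):
        raise InfeasibleBandError("band excludes a path endpoint")

    for i in range(m):
        lo, hi = rows_j0[i], rows_j1[i]
        row = cost[i]
        for j in range(lo, hi + 1):
            if i == 0 and j == 0:
                dp[0, 0] = row[0]
                continue
            best = inf
            if i > 0 and j > 0:
                best = dp[i - 1, j - 1]
            if i > 0 and dp[i - 1, j] < best:
                best = dp[i - 1, j]
            if j > 0 and dp[i, j - 1] < best:
                best = dp[i, j - 1]
            if best < inf:
                dp[i, j] = row[j] + best
    if not np.isfinite(dp[m - 1, n - 1]):
        raise InfeasibleBandError("band too narrow to connect the endpoints")

    # backtrack with deterministic tie-break: diagonal, then rendition step
    path = [(m - 1, n - 1)]
    i, j = m - 1, n - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((dp[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            candidates.append((dp[i - 1, j], (i - 1, j)))
        if j > 0:
            candidates.append((dp[i, j - 1], (i, j - 1)))
        best_cost = min(c for c, _ in candidates)
        # candidates are ordered diagonal → (1,0) → (0,1); take first at the min
        i, j = next(cell for c, cell in candidates if c == best_cost)
        path.append((i, j))
    path.reverse()
    return WarpPath(pairs=np.array(path), cost=float(dp[m - 1, n - 1]))


def apply_warp(env, path: WarpPath, template_len: int):
    """Carry an envelope from rendition time onto the template timeline.

    Each template bin receives the mean of the rendition bins mapped to it
    by the warp path; no temporal offset is applied. Accepts an
    :class:`~pnisig.sigproc.Envelope` (returned as one) or a bare 1-D/2-D
    array with time as the last axis.
    """
    is_env = isinstance(env, Envelope)
    vals = env.values if is_env else np.asarray(env, dtype=float)
    vals2 = np.atleast_2d(vals)
    m = int(path.pairs[:, 0].max()) + 1
    if vals2.shape[-1] != m:
        raise ValueError(
            f"envelope length {vals2.shape[-1]} does not match the warp path extent {m}"
        )
    out = np.zeros(vals2.shape[:-1] + (template_len,))
    counts = np.zeros(template_len)
    np.add.at(counts, path.pairs[:, 1], 1.0)
    for k in range(vals2.shape[0]):
        acc = np.zeros(template_len)
        np.add.at(acc, path.pairs[:, 1], vals2[k, path.pairs[:, 0]])
        out[k] = acc / np.maximum(counts, 1.0)
    out = out if vals.ndim > 1 else out[0]
    if is_env:
        return Envelope(values=out, bin_width=env.bin_width, window=env.window, t0=env.t0)
    return out
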