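"""Acute evoked-response analysis.

Workflow for stimulation experiments on a small nerve: extract stimulation-
aligned trial snippets from a continuous recording, blank the stimulation
artifact, quantify the compound-action-potential response as peak-to-peak
voltage (Vpp) inside a conduction-delay window (default 0.75–4 ms after
stimulation onset, the latency range for 4–6 µm myelinated fibers conducting
at 4–24 m/s over ~20 mm), decide detection against a bootstrap null built
from pre-stimulus noise, bin trials by stimulation current into a
recruitment curve, and fit a 4-parameter logistic to recover the fiber-
recruitment sigmoid and its saturation (plateau) current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sigproc import Recording


class FitError(RuntimeError):
    """Sigmoid fit failed to converge or the data are degenerate."""


class DegenerateInputError(ValueError):
    """Input renders the statistic undefined (e.g., zero noise RMS)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ResponseWindow:
    """Post-stimulus latency window (ms) in which the evoked component lies."""

    start: float = 0.75
    stop: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.start < self.stop <= 25):
            raise ValueError(f"require 0 < start < stop <= 25 ms, got ({self.start}, {self.stop})")

    @property
    def length(self) -> float:
        return self.stop - self.start


@dataclass
class StimTrial:
    """One stimulation-aligned snippet, −pre…+post ms around stimulation onset."""

    snippet: np.ndarray  # (n_samples, n_channels) µV
    current: float  # commanded amplitude, µA (signed; + = cathodic-first)
    fs: float
    pre_ms: float = 5.0

    def __post_init__(self) -> None:
        self.snippet = np.atleast_2d(np.asarray(self.snippet, dtype=np.float64))
        if self.snippet.shape[0] == 1 and self.snippet.shape[1] > 1:
            self.snippet = self.snippet.T

    @property
    def onset_index(self) -> int:
        """Sample index of stimulation onset within the snippet."""
        return int(round(self.pre_ms * self.fs / 1000.0))

    def window_slice(self, start_ms: float, stop_ms: float) -> slice:
        """Slice of snippet samples covering [start_ms, stop_ms) after onset."""
        i0 = self.onset_index + int(round(start_ms * self.fs / 1000.0))
        i1 = self.onset_index + int(round(stop_ms * self.fs / 1000.0))
        return slice(max(i0, 0), min(i1, self.snippet.shape[0]))


@dataclass
class DetectionResult:
    """Outcome of the bootstrap evoked-response test."""

    snr: float
    ci: tuple[float, float]
    detected: bool
    n_boot: int
    level: float
    meta: dict = field(default_factory=dict)


@dataclass
class SigmoidParams:
    """4-parameter logistic describing fiber recruitment,
    V(I) = Vmin + (Vmax − Vmin) / (1 + exp(−(I − I50)/slope))."""

    Vmin: float
    Vmax: float
    I50: float
    slope: float

    def __post_init__(self) -> None:
        if self.Vmax < self.Vmin:
            raise ValueError("Vmax must be >= Vmin")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    @property
    def plateau_current(self) -> float:
        """Current at which the curve reaches Vmin + 0.95 (Vmax − Vmin)."""
        return self.I50 + self.slope * math.log(19.0)

    def __call__(self, current: float | np.ndarray) -> float | np.ndarray:
        return four_pl(current, self.Vmin, self.Vmax, self.I50, self.slope)


def four_pl(
    current: float | np.ndarray, vmin: float, vmax: float, i50: float, slope: float
) -> float | np.ndarray:
    """Evaluate the 4-parameter logistic recruitment curve."""
    z = np.clip(-(np.asarray(current, dtype=float) - i50) / slope, -500, 500)
    out = vmin + (vmax - vmin) / (1.0 + np.exp(z))
    return float(out) if np.isscalar(current) else out


@dataclass
class RecruitmentCurve:
    """Binned stimulation current → trial-mean response Vpp."""

    bins: np.ndarray  # bin centers, µA
    mean_vpp: np.ndarray  # µV
    n_trials: np.ndarray
    bin_width: float = 5.0
    fit: SigmoidParams | None = None


# ---------------------------------------------------------------------------
# trial extraction and artifact handling


def extract_trials(
    rec: Recording,
    events: pd.DataFrame,
    pre_ms: float = 5.0,
    post_ms: float = 25.0,
    detect_k: float = 8.0,
    search_ms: float = 1.0,
) -> tuple[list[StimTrial], int]:
    """Cut stimulation-aligned snippets out of a continuous recording.

    The artifact onset is re-detected as the first sample, within
    ±``search_ms`` of the commanded time, where any channel exceeds
    ``detect_k`` × its pre-stimulus SD; if nothing crosses (e.g., no
    artifact) the commanded time is used. Events whose window would run past
    either edge of the trace are skipped; the skip count is returned.
    """
    fs = rec.fs
    x = rec.samples
    n = rec.n_samples
    pre_n = int(round(pre_ms * fs / 1000.0))
    post_n = int(round(post_ms * fs / 1000.0))
    search_n = int(round(search_ms * fs / 1000.0))
    trials: list[StimTrial] = []
    skipped = 0
    for _, ev in events.iterrows():
        ic = int(round((float(ev["time_s"]) - rec.t0) * fs))
        # pre-stimulus SD estimated clear of the search region
        sd_lo, sd_hi = ic - pre_n, ic - search_n
        onset = ic
        if sd_lo >= 0 and sd_hi > sd_lo:
            sd = x[sd_lo:sd_hi].std(axis=0)
            sd = np.where(sd > 0, sd, np.inf)
            seg = np.abs(x[max(ic - search_n, 0) : ic + search_n + 1])
            hits = np.nonzero((seg > detect_k * sd[None, :]).any(axis=1))[0]
            if hits.size:
                onset = max(ic - search_n, 0) + int(hits[0])
        if onset - pre_n < 0 or onset + post_n > n:
            skipped += 1
            continue
        trials.append(
            StimTrial(
                snippet=x[onset - pre_n : onset + post_n].copy(),
                current=float(ev["current_uA"]),
                fs=fs,
                pre_ms=pre_ms,
            )
        )
    return trials, skipped


def blank_artifact(
    trial: StimTrial,
    blank: tuple[float, float] = (-0.1, 0.75),
    window: ResponseWindow | None = None,
) -> StimTrial:
    """Replace the stimulation-artifact span by linear interpolation.

    Samples strictly inside the blank window (ms relative to onset) are
    replaced by the line joining the values at the window endpoints; all
    other samples are bit-identical, so the response window is untouched.
    """
    w = window or ResponseWindow()
    if blank[1] > w.start:
        raise ValueError(
            f"blank window {blank} overlaps the response window starting at {w.start} ms"
        )
    fs = trial.fs
    i0 = trial.onset_index + int(round(blank[0] * fs / 1000.0))
    i1 = trial.onset_index + int(round(blank[1] * fs / 1000.0))
    if i0 < 0 or i1 >= trial.snippet.shape[0]:
        raise ValueError("blank window extends outside the snippet")
    out = trial.snippet.copy()
    span = i1 - i0
    if span > 1:
        frac = (np.arange(1, span) / span)[:, None]
        out[i0 + 1 : i1] = out[i0][None, :] * (1 - frac) + out[i1][None, :] * frac
    return replace(trial, snippet=out)


def response_vpp(
    trial: StimTrial,
    window: ResponseWindow | None = None,
    channel: int | None = None,
) -> float:
    """Peak-to-peak voltage (max − min, µV) inside the response window.

    Computed per channel and averaged across channels, or for a single
    ``channel`` index if given.
    """
    w = window or ResponseWindow()
    sl = trial.window_slice(w.start, w.stop)
    seg = trial.snippet[sl]
    if seg.shape[0] == 0:
        raise ValueError("response window contains no samples")
    vpp = seg.max(axis=0) - seg.min(axis=0)
    return float(vpp[channel]) if channel is not None else float(vpp.mean())


# ---------------------------------------------------------------------------
# bootstrap detection


def _rms(a: np.ndarray, axis=None) -> np.ndarray:
    return np.sqrt(np.mean(a**2, axis=axis))


def detect_response(
    trials: list[StimTrial],
    window: ResponseWindow | None = None,
    n_boot: int = 10_000,
    level: float = 90.0,
    seed: int = 0,
    guard_ms: float = 1.0,
    single_trial: bool = False,
    trial_resampling: str = "subsample",
) -> DetectionResult:
    """Bootstrap test for the presence of an evoked response.

    The statistic is SNR = RMS(response window) / RMS(pre-stimulus noise
    window) on the trial-averaged trace (or on the single supplied trial if
    ``single_trial``); the noise window is the whole pre-stimulus interval,
    ending ``guard_ms`` before stimulation onset (the default 1 ms keeps
    the window clear of the stimulation artifact's backward smear under
    zero-phase filtering). The null distribution is
    built from ``n_boot`` resamples in which the "signal" segment is a
    contiguous block of response-window length drawn with replacement from
    the pre-stimulus interval of each resampled trial, and the "noise"
    segment is the resampled trials' pre-stimulus interval itself. A
    response is detected when the observed SNR exceeds the upper bound of
    the central ``level``% interval of the null (one-sided exceedance:
    responses only increase SNR).

    ``trial_resampling`` controls how trials enter each null "signal"
    average:

    * ``"subsample"`` (default) — half the trials drawn without
      replacement, the averaged block rescaled by √(m/n) so its variance
      matches an n-trial average; the subset draw restores across-trial
      resampling variance without forcing overlapping blocks, and gives
      nominal null coverage;
    * ``"permute"`` — every trial contributes exactly one randomly placed
      block (slightly narrow null: only block offsets vary);
    * ``"replace"`` — trial indices drawn with replacement; with a short
      pre-stimulus interval, repeated trials contribute overlapping blocks
      which widens the null (conservative detection).
    """
    if not trials:
        raise ValueError("no trials")
    w = window or ResponseWindow()
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    fs = trials[0].fs
    onset = trials[0].onset_index
    L = int(round(w.length * fs / 1000.0))
    guard_n = int(round(guard_ms * fs / 1000.0))
    pre_len = onset - guard_n  # pre-stimulus pool, clear of the artifact onset
    if pre_len < L:
        raise ValueError("pre-stimulus interval shorter than the response window")

    stackd = np.stack([t.snippet for t in trials])  # (n, T, C)
    n = 1 if single_trial else stackd.shape[0]
    avg = stackd[:1, :, :].mean(axis=0) if single_trial else stackd.mean(axis=0)

    resp_sl = trials[0].window_slice(w.start, w.stop)
    snr_num = _rms(avg[resp_sl])
    noise_sl = slice(0, pre_len)
    snr_den = _rms(avg[noise_sl])
    if snr_den == 0:
        raise DegenerateInputError("pre-stimulus noise RMS is zero")
    snr_obs = float(snr_num / snr_den)

    if trial_resampling not in ("subsample", "permute", "replace"):
        raise ValueError("trial_resampling must be 'subsample', 'permute' or 'replace'")
    pool = stackd[:, :pre_len, :]  # (n, P, C)
    n_tr = pool.shape[0]
    rng = np.random.default_rng(seed)
    max_off = pre_len - L + 1
    null = np.empty(n_boot)
    arangeL = np.arange(L)
    chunk = max(1, int(2_000_000 / max(1, n * L * pool.shape[2])))
    for b0 in range(0, n_boot, chunk):
        b1 = min(n_boot, b0 + chunk)
        nb = b1 - b0
        # "signal" part: one response-length block per resampled trial
        scale = 1.0
        if trial_resampling == "permute":
            idx = rng.permuted(np.tile(np.arange(n_tr), (nb, 1)), axis=1)[:, :n]
        elif trial_resampling == "replace":
            idx = rng.integers(0, n_tr, size=(nb, n))
        else:  # subsample: m of n without replacement, variance-matched
            m = max(2, n // 2) if n > 2 else n
            idx = rng.permuted(np.tile(np.arange(n_tr), (nb, 1)), axis=1)[:, :m]
            scale = np.sqrt(m / n)
        off = rng.integers(0, max_off, size=idx.shape)
        blocks = pool[idx[:, :, None], (off[:, :, None] + arangeL)[:, :, :], :]
        num = _rms(scale * blocks.mean(axis=1), axis=(1, 2))
        # "noise" part: the resampled trials' full pre-stimulus interval
        if trial_resampling == "replace":
            idx_n = rng.integers(0, n_tr, size=(nb, n))
            den = _rms(pool[idx_n].mean(axis=1), axis=(1, 2))
        else:
            # all trials contribute once: the average is draw-invariant
            den = np.full(nb, float(_rms(pool.mean(axis=0))))
        null[b0:b1] = num / den
    alpha = (100.0 - level) / 2.0
    ci = (float(np.percentile(null, alpha)), float(np.percentile(null, 100.0 - alpha)))
    return DetectionResult(
        snr=snr_obs,
        ci=ci,
        detected=snr_obs > ci[1],
        n_boot=n_boot,
        level=level,
        meta={
            "sidedness": "one-sided exceedance of the upper bound of the central interval",
            "statistic": "single-trial" if single_trial else "trial-averaged",
            "trial_resampling": trial_resampling,
            "n_trials": n_tr,
        },
    )


# ---------------------------------------------------------------------------
# recruitment curves


def recruitment_curve(
    trials: list[StimTrial],
    bin_width: float = 5.0,
    window: ResponseWindow | None = None,
    vpps: np.ndarray | None = None,
) -> RecruitmentCurve:
    """Group trials into half-open |current| bins [k·w, (k+1)·w) and average Vpp.

    Polarity is discarded for binning (bins are formed on current magnitude);
    empty bins are omitted. ``vpps`` may supply precomputed per-trial Vpp
    values, otherwise they are measured in the response window.
    """
    if not trials:
        raise ValueError("no trials")
    if vpps is None:
        vpps = np.array([response_vpp(t, window) for t in trials])
    cur = np.abs(np.array([t.current for t in trials]))
    k = np.floor(cur / bin_width).astype(int)
    uniq = np.unique(k)
    centers = (uniq + 0.5) * bin_width
    means = np.array([vpps[k == u].mean() for u in uniq])
    counts = np.array([(k == u).sum() for u in uniq])
    return RecruitmentCurve(bins=centers, mean_vpp=means, n_trials=counts, bin_width=bin_width)


def fit_recruitment(
    curve: RecruitmentCurve, n_starts: int = 5, min_bins: int = 5
) -> SigmoidParams:
    """Least-squares 4-parameter-logistic fit of a recruitment curve.

    Multistart initialization: I50 is started at ``n_starts`` evenly spaced
    quantiles of the bin centers (slope at 1/10 of the current range), and
    the best converged solution is kept. Bounds: Vmin ≥ 0, I50 within the
    observed current range, slope > 0. Flat data (no dynamic range) or
    failure of every start raises :class:`FitError`.
    """
    x = np.asarray(curve.bins, dtype=float)
    y = np.asarray(curve.mean_vpp, dtype=float)
    if x.size < min_bins:
        raise ValueError(f"need >= {min_bins} distinct bins, got {x.size}")
    y_range = y.max() - y.min()
    if y_range <= 1e-12 * max(1.0, abs(y.max())):
        raise FitError("flat recruitment data: no dynamic range to fit")

    def resid(p):
        return four_pl(x, *p) - y

    lo = [0.0, 0.0, x.min(), 1e-6]
    hi = [np.inf, np.inf, x.max(), (x.max() - x.min()) * 10 + 1e-6]
    best = None
    for q in np.linspace(0.1, 0.9, n_starts):
        p0 = [
            max(y.min(), 0.0),
            y.max(),
            float(np.quantile(x, q)),
            (x.max() - x.min()) / 10.0,
        ]
        try:
            sol = optimize.least_squares(
                resid, p0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("4PL fit failed to converge from every start")
    vmin, vmax, i50, slope = best.x
    if vmax < vmin:  # decreasing fit means no recruitment signal
        raise FitError("fit converged to a non-increasing curve")
    return SigmoidParams(Vmin=vmin, Vmax=vmax, I50=i50, slope=slope)


# ---------------------------------------------------------------------------
# condition comparisons (e.g., saline / lidocaine / washout)


def compare_conditions(
    vpp_by_condition: dict[str, np.ndarray],
    control: str = "control",
    alpha: float = 0.05,
) -> dict:
    """Repeated-measures comparison of per-subject mean Vpp across conditions.

    ``vpp_by_condition`` maps condition name → per-subject means, with
    subjects in the same order in every condition (complete blocks). Returns
    the repeated-measures one-way ANOVA omnibus result and control-
    referenced Dunnett post-hoc decisions at ``alpha``.
    """
    names = list(vpp_by_condition)
    if control not in names:
        raise ValueError(f"control condition {control!r} not present")
    arrays = {k: np.asarray(v, dtype=float) for k, v in vpp_by_condition.items()}
    n_sub = {k: v.size for k, v in arrays.items()}
    if len(set(n_sub.values())) != 1:
        raise ValueError(f"unbalanced blocks: subjects per condition {n_sub}")
    n = next(iter(n_sub.values()))
    if n < 2 or len(names) < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")

    mat = np.column_stack([arrays[k] for k in names])  # (subjects, conditions)
    if np.allclose(mat, mat[:, :1]):
        # identical conditions within every subject: no effect by construction
        posthoc = {k: {"p": 1.0, "reject": False} for k in names if k != control}
        return {"omnibus": {"F": 0.0, "p": 1.0}, "posthoc": posthoc, "alpha": alpha}

    from statsmodels.stats.anova import AnovaRM

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), len(names)),
            "condition": names * n,
            "vpp": mat.ravel(),
        }
    )
    res = AnovaRM(long, depvar="vpp", subject="subject", within=["condition"]).fit()
    f_val = float(res.anova_table["F Value"].iloc[0])
    p_val = float(res.anova_table["Pr > F"].iloc[0])

    treatments = [k for k in names if k != control]
    dres = stats.dunnett(*[arrays[k] for k in treatments], control=arrays[control])
    posthoc = {
        k: {"p": float(p), "reject": bool(p < alpha)}
        for k, p in zip(treatments, np.atleast_1d(dres.pvalue))
    }
    return {"omnibus": {"F": f_val, "p": p_val}, "posthoc": posthoc, "alpha": alpha}
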