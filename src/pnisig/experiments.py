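"""Canned simulation experiments at the study conditions.

Each function generates synthetic sessions with the generator presets,
runs the corresponding analysis chain end to end, and returns summary
numbers. They are the computational core of the numbered analysis scripts
and of the acceptance checks.
"""

from __future__ import annotations

import numpy as np

from . import evoked, pipeline, songalign, stability, synthdata as sd


def bootstrap_null_coverage(
    n_sessions: int = 500,
    n_trials: int = 16,
    n_boot: int = 2000,
    level: float = 90.0,
    seed: int = 1,
) -> dict:
    """Empirical coverage of the bootstrap detector on null recordings.

    Generates ``n_sessions`` independent noise-only acute sessions (no
    evoked component, no artifact), runs the full acute chain and the
    bootstrap detector on each, and reports the fraction of sessions whose
    observed SNR falls inside the central ``level``% null interval, plus
    the one-sided detection (false-positive) fraction.
    """
    root = np.random.SeedSequence([seed, 11])
    session_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(2 * n_sessions)]
    inside = 0
    detected = 0
    for k in range(n_sessions):
        sc = sd.AcuteScenario(
            currents=[0.0],
            trials_per_current=n_trials,
            isi_s=0.05,
            artifact_amp=0.0,
            noise=sd.post_plating_noise(),
        )
        rec, events, _ = sd.gen_acute_session(sc, seed=session_seeds[k])
        trials, _ = pipeline.acute_trials(rec, events)
        res = evoked.detect_response(
            trials, n_boot=n_boot, level=level, seed=session_seeds[n_sessions + k]
        )
        inside += res.ci[0] <= res.snr <= res.ci[1]
        detected += res.detected
    return {
        "coverage": inside / n_sessions,
        "coverage_pct": 100.0 * inside / n_sessions,
        "false_positive_rate": detected / n_sessions,
        "n_sessions": n_sessions,
        "n_boot": n_boot,
        "level": level,
    }


def recruitment_plateau_recovery(n_seeds: int = 20, seed: int = 1) -> dict:
    """Saturation-current recovery from simulated graded-stimulation sessions.

    Generates acute sessions with the standard preset (10–110 µA in 5 µA
    steps, 40 trials per current, moderate noise), runs the full chain
    (preprocess → extract → blank → bin → 4PL fit), and reports the median
    fitted 95%-of-max plateau current across seeds together with the
    generator's ground-truth plateau.
    """
    root = np.random.SeedSequence([seed, 23])
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(n_seeds)]
    plateaus = []
    i50s = []
    for sseed in seeds:
        sc = sd.standard_acute_scenario(isi_s=0.05)
        rec, events, _ = sd.gen_acute_session(sc, seed=sseed)
        curve = pipeline.acute_recruitment(rec, events)
        plateaus.append(curve.fit.plateau_current)
        i50s.append(curve.fit.I50)
    sc = sd.standard_acute_scenario()
    return {
        "plateau_median_uA": float(np.median(plateaus)),
        "plateau_per_seed": plateaus,
        "i50_median_uA": float(np.median(i50s)),
        "true_plateau_uA": sc.recruit.plateau_current,
        "true_i50_uA": sc.recruit.I50,
        "n_seeds": n_seeds,
    }


def _calibration_chronic_scenario(env_seed: int, **kw) -> sd.ChronicScenario:
    """Down-scaled chronic scenario used for the Monte-Carlo experiments."""
    params = dict(
        n_channels=4,
        motif_len_ms=300,
        renditions_per_day=8,
        fs=8000.0,
        noise=sd.NoisePreset(rms=1.0, band=(1.0, 3000.0)),
        spike_rate=300.0,
        gap_s=0.15,
        env_seed=env_seed,
    )
    params.update(kw)
    return sd.ChronicScenario(**params)


_CHRONIC_BAND = (300.0, 3000.0)


def within_across_fraction(n_runs: int = 50, shared_weight: float = 0.8, seed: int = 1) -> dict:
    """Fraction of seeded runs where same-electrode envelope correlation
    exceeds different-electrode correlation, through the full chronic chain
    (generation → preprocessing → DTW alignment → correlation partition)."""
    hits = 0
    for k in range(n_runs):
        sc = _calibration_chronic_scenario(env_seed=seed * 1000 + k, shared_weight=shared_weight)
        rec, motifs, gt = sd.gen_chronic_session(sc, seed=seed * 1000 + k, with_audio=False)
        aligned, _ = pipeline.chronic_aligned_envelopes(
            rec, motifs, gt.audio_features, band=_CHRONIC_BAND
        )
        env_sets = [aligned[:, c, :] for c in range(sc.n_channels)]
        res = stability.within_across_summary(env_sets)
        hits += res["within_mean"] > res["across_mean"]
    return {"fraction": hits / n_runs, "n_runs": n_runs, "shared_weight": shared_weight}


def first_last_rejection_rate(n_seeds: int = 40, alpha: float = 0.05, seed: int = 1) -> dict:
    """Type-I error of the day-1 vs last-day paired tests on stationary data.

    Two consecutive stationary days are generated per seed (shared spike
    pattern, zero warp jitter so channel metrics carry independent errors);
    per-channel daily correlation / Vpp / event-rate metrics are compared
    with two-tailed paired t-tests and the pooled rejection fraction at
    ``alpha`` is returned.
    """
    rejections = []
    for k in range(n_seeds):
        sc = _calibration_chronic_scenario(
            env_seed=seed * 100 + k,
            n_channels=6,
            renditions_per_day=20,
            warp_jitter=0.0,
            noise=sd.NoisePreset(rms=2.0, band=(1.0, 3000.0)),
        )
        metrics = {}
        template = None
        ref = None
        for day in (0, 1):
            rec, motifs, gt = sd.gen_chronic_session(sc, day=day, seed=seed * 100 + k,
                                                     with_audio=False)
            if template is None:
                # template strictly from the day-1 reference block
                template = songalign.build_template(gt.audio_features[:10], n=10)
            aligned, _ = pipeline.chronic_aligned_envelopes(
                rec, motifs, gt.audio_features, band=_CHRONIC_BAND, template=template
            )
            filt = pipeline.preprocess(rec, _CHRONIC_BAND)
            if ref is None:
                ref = aligned[:10].mean(axis=0)
                m = pipeline.daily_channel_metrics(
                    aligned, filt, motifs, ref, exclude=set(range(10))
                )
            else:
                m = pipeline.daily_channel_metrics(aligned, filt, motifs, ref)
            metrics[day] = m
        res = stability.first_last_compare(metrics[0], metrics[1])
        for r in res.values():
            rejections.append(r["p"] < alpha)
    return {
        "rejection_rate": float(np.mean(rejections)),
        "n_tests": len(rejections),
        "alpha": alpha,
    }


def running_corr_trend(n_seeds: int = 5, n_days: int = 3, seed: int = 1) -> dict:
    """Slope of the running day-1-referenced correlation under stationarity.

    Concatenates several stationary simulated days per seed, computes the
    sliding correlation to the day-1 reference on disjoint windows, and
    fits a linear trend; reports how many seeds show a significant slope.
    """
    from scipy.stats import linregress

    n_sig = 0
    slopes = []
    for k in range(n_seeds):
        sc = _calibration_chronic_scenario(
            env_seed=seed * 10 + k, n_channels=2, renditions_per_day=40, warp_jitter=0.0
        )
        days = []
        template = None
        for day in range(n_days):
            rec, motifs, gt = sd.gen_chronic_session(
                sc, day=day, seed=seed * 10 + k, with_audio=False
            )
            aligned, template = pipeline.chronic_aligned_envelopes(
                rec, motifs, gt.audio_features, band=_CHRONIC_BAND, template=template
            )
            days.append(aligned[:, 0, :])
        rend = np.vstack(days)
        res = stability.running_stability(rend, ref_block=25, window=25, advance=25)
        fit = linregress(res["positions"], res["series"])
        slopes.append(fit.slope)
        n_sig += fit.pvalue < 0.05
    return {"n_significant": n_sig, "n_seeds": n_seeds, "slopes": slopes}
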