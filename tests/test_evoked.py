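"""Acute analysis: trial handling, Vpp, bootstrap detection, recruitment."""

import numpy as np
import pandas as pd
import pytest

from pnisig import evoked, pipeline, synthdata as sd
from pnisig.evoked import (
    FitError,
    RecruitmentCurve,
    ResponseWindow,
    SigmoidParams,
    StimTrial,
    four_pl,
)
from pnisig.sigproc import Recording

from conftest import null_acute_scenario

FS = 24_400.0


def _mk_trial(snippet, current=50.0, fs=FS, pre_ms=5.0):
    return StimTrial(snippet=snippet, current=current, fs=fs, pre_ms=pre_ms)


def _kernel_trial(amp, lat_ms=2.0, n_ch=2, pre_ms=5.0, post_ms=25.0):
    """Noiseless trial with an antisymmetric evoked deflection of peak ±amp."""
    n = int(round((pre_ms + post_ms) * FS / 1000))
    x = np.zeros((n, n_ch))
    k = sd._evoked_kernel(0.25, FS)
    i0 = int(round(pre_ms * FS / 1000)) + int(round(lat_ms * FS / 1000))
    x[i0 : i0 + k.size] = amp * k[:, None]
    return _mk_trial(x)


class TestExtractTrials:
    def test_counts_and_lengths(self):
        sc = null_acute_scenario(trials_per_current=10, artifact_amp=200.0)
        rec, events, _ = sd.gen_acute_session(sc, seed=0)
        trials, skipped = evoked.extract_trials(rec, events)
        assert len(trials) == 10 and skipped == 0
        lengths = {t.snippet.shape[0] for t in trials}
        assert len(lengths) == 1

    def test_alignment_recovers_command_offset(self):
        # artifact placed 0.3 ms after the commanded time: re-detection must
        # land on the true artifact onset within one sample
        sc = null_acute_scenario(trials_per_current=6, artifact_amp=300.0,
                                 command_offset_ms=0.3)
        rec, events, gt = sd.gen_acute_session(sc, seed=1)
        trials, _ = evoked.extract_trials(rec, events)
        for t in trials:
            at_onset = np.abs(t.snippet[t.onset_index : t.onset_index + 2]).max()
            before = np.abs(t.snippet[t.onset_index - 4 : t.onset_index - 1]).max()
            assert at_onset > 200.0  # on the 300 µV artifact
            assert before < 50.0  # still baseline one sample earlier

    def test_edge_event_skipped(self):
        rec = Recording(samples=np.zeros((int(FS), 2)), fs=FS)
        events = pd.DataFrame({"time_s": [0.001, 0.5], "current_uA": [10.0, 10.0]})
        trials, skipped = evoked.extract_trials(rec, events)
        assert len(trials) == 1 and skipped == 1


class TestBlankArtifact:
    def test_blank_is_linear_segment(self):
        t = _kernel_trial(0.0)
        art = sd._artifact_kernel(100.0, FS, 200.0)
        x = t.snippet.copy()
        x[t.onset_index : t.onset_index + art.size] += art[:, None]
        t2 = evoked.blank_artifact(_mk_trial(x))
        i0 = t2.onset_index + int(round(-0.1 * FS / 1000))
        i1 = t2.onset_index + int(round(0.75 * FS / 1000))
        seg = t2.snippet[i0 : i1 + 1, 0]
        assert np.allclose(np.diff(seg, 2), 0.0, atol=1e-9)

    def test_response_window_untouched(self):
        t = _kernel_trial(40.0, lat_ms=2.0)
        before = evoked.response_vpp(t)
        after = evoked.response_vpp(evoked.blank_artifact(t))
        assert before == after
        # samples outside the blank are bit-identical
        t2 = evoked.blank_artifact(t)
        i1 = t.onset_index + int(round(0.75 * FS / 1000))
        assert np.array_equal(t.snippet[i1 + 1 :], t2.snippet[i1 + 1 :])

    def test_overlapping_blank_rejected(self):
        with pytest.raises(ValueError):
            evoked.blank_artifact(_kernel_trial(1.0), blank=(-0.1, 2.0))


class TestResponseVpp:
    def test_antisymmetric_kernel_gives_twice_amplitude(self):
        # deflection with exact peak +A and trough −A inside the window
        n = int(round(30 * FS / 1000))
        x = np.zeros((n, 2))
        i_peak = int(round((5 + 1.5) * FS / 1000))
        x[i_peak] = 30.0
        x[i_peak + 8] = -30.0
        assert evoked.response_vpp(_mk_trial(x)) == pytest.approx(60.0, rel=1e-9)

    def test_zero_trace(self):
        assert evoked.response_vpp(_kernel_trial(0.0)) == 0.0

    def test_common_offset_invariance(self):
        t = _kernel_trial(30.0, lat_ms=1.5)
        shifted = _mk_trial(t.snippet + 123.4)
        assert evoked.response_vpp(shifted) == pytest.approx(evoked.response_vpp(t))

    def test_monte_carlo_mean_near_twice_ground_truth(self):
        recruit = SigmoidParams(Vmin=0.0, Vmax=100.0, I50=35.0, slope=5.0)
        sc = sd.AcuteScenario(
            currents=[100.0], trials_per_current=100, isi_s=0.05, recruit=recruit,
            velocity_range=(8.0, 24.0), noise=sd.post_plating_noise(),
        )
        rec, events, gt = sd.gen_acute_session(sc, seed=3)
        # measure on raw aligned trials (generator contract, before any
        # amplitude-altering filtering)
        trials, _ = evoked.extract_trials(rec, events)
        trials = [evoked.blank_artifact(t) for t in trials]
        vpp_mean = np.mean([evoked.response_vpp(t) for t in trials])
        assert vpp_mean == pytest.approx(2 * gt.amplitudes.mean(), rel=0.10)


class TestDetectResponse:
    def test_reproducible_under_seed(self):
        sc = null_acute_scenario(trials_per_current=8)
        rec, events, _ = sd.gen_acute_session(sc, seed=4)
        trials, _ = pipeline.acute_trials(rec, events)
        a = evoked.detect_response(trials, n_boot=300, seed=42)
        b = evoked.detect_response(trials, n_boot=300, seed=42)
        assert a.ci == b.ci and a.snr == b.snr

    def test_strong_response_always_detected(self):
        hits = 0
        for s in range(5):
            sc = sd.AcuteScenario(currents=[100.0], trials_per_current=10, isi_s=0.05,
                                  noise=sd.post_plating_noise())
            rec, events, _ = sd.gen_acute_session(sc, seed=100 + s)
            trials, _ = pipeline.acute_trials(rec, events)
            hits += evoked.detect_response(trials, n_boot=400, seed=s).detected
        assert hits == 5

    def test_null_detection_rate_near_five_percent(self):
        det = 0
        n_runs = 120
        for s in range(n_runs):
            sc = null_acute_scenario()
            rec, events, _ = sd.gen_acute_session(sc, seed=s)
            trials, _ = pipeline.acute_trials(rec, events)
            det += evoked.detect_response(trials, n_boot=400, seed=5000 + s).detected
        # one-sided 5% nominal; binomial 99.7% band for n=120
        frac = det / n_runs
        assert 0.0 <= frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_power_monotone_in_amplitude(self):
        recruit = SigmoidParams(Vmin=0.0, Vmax=100.0, I50=35.0, slope=5.0)
        amps = [0.0, 1.0, 2.0, 4.0, 8.0]
        power = []
        for a in amps:
            det = 0
            for s in range(20):
                sc = sd.AcuteScenario(
                    currents=[60.0], trials_per_current=8, isi_s=0.05,
                    recruit=SigmoidParams(Vmin=0.0, Vmax=a, I50=35.0, slope=5.0),
                    velocity_range=(8.0, 24.0), noise=sd.post_plating_noise(),
                )
                rec, events, _ = sd.gen_acute_session(sc, seed=300 + s)
                trials, _ = pipeline.acute_trials(rec, events)
                det += evoked.detect_response(trials, n_boot=300, seed=s).detected
            power.append(det / 20)
        # allow small Monte-Carlo wiggle while requiring an increasing trend
        assert power[-1] > power[0]
        assert all(power[i + 1] >= power[i] - 0.15 for i in range(len(power) - 1))

    def test_zero_noise_is_degenerate(self):
        t = _kernel_trial(0.0)
        with pytest.raises(evoked.DegenerateInputError):
            evoked.detect_response([t], n_boot=100)


class TestRecruitmentCurve:
    def test_binning_convention_21_bins(self):
        trials = [_kernel_trial(1.0) for _ in range(21)]
        for t, cur in zip(trials, np.arange(10.0, 111.0, 5.0)):
            t.current = cur
        curve = evoked.recruitment_curve(trials, vpps=np.ones(21))
        assert len(curve.bins) == 21
        assert np.all(curve.n_trials == 1)
        assert curve.bins[0] == 12.5

    def test_single_bin_mean(self):
        trials = [_kernel_trial(1.0, lat_ms=1.0) for _ in range(4)]
        vpps = np.array([1.0, 2.0, 3.0, 4.0])
        curve = evoked.recruitment_curve(trials, vpps=vpps)
        assert len(curve.bins) == 1
        assert curve.mean_vpp[0] == 2.5

    def test_permutation_invariance(self, rng):
        trials = [_kernel_trial(1.0) for _ in range(12)]
        currents = rng.uniform(10, 110, 12)
        vpps = rng.uniform(1, 100, 12)
        for t, c in zip(trials, currents):
            t.current = c
        a = evoked.recruitment_curve(trials, vpps=vpps)
        perm = rng.permutation(12)
        b = evoked.recruitment_curve([trials[i] for i in perm], vpps=vpps[perm])
        assert np.allclose(a.bins, b.bins) and np.allclose(a.mean_vpp, b.mean_vpp)

    def test_polarity_binned_on_magnitude(self):
        trials = [_kernel_trial(1.0), _kernel_trial(1.0)]
        trials[0].current, trials[1].current = 50.0, -50.0
        curve = evoked.recruitment_curve(trials, vpps=np.array([1.0, 3.0]))
        assert len(curve.bins) == 1 and curve.mean_vpp[0] == 2.0


class TestFitRecruitment:
    def test_exact_recovery_on_noiseless_4pl(self):
        true = SigmoidParams(Vmin=10.0, Vmax=200.0, I50=35.0, slope=6.0)
        x = np.arange(12.5, 113.0, 5.0)
        curve = RecruitmentCurve(bins=x, mean_vpp=true(x), n_trials=np.ones_like(x))
        fit = evoked.fit_recruitment(curve)
        for name in ("Vmin", "Vmax", "I50", "slope"):
            assert getattr(fit, name) == pytest.approx(getattr(true, name), rel=1e-6)

    def test_plateau_current_closed_form(self):
        p = SigmoidParams(Vmin=0.0, Vmax=100.0, I50=35.0, slope=5.0)
        assert p(p.plateau_current) == pytest.approx(95.0, rel=1e-9)

    def test_flat_data_raises(self):
        x = np.arange(10.0, 60.0, 5.0)
        curve = RecruitmentCurve(bins=x, mean_vpp=np.full_like(x, 7.0), n_trials=np.ones_like(x))
        with pytest.raises(FitError):
            evoked.fit_recruitment(curve)

    def test_too_few_bins_rejected(self):
        curve = RecruitmentCurve(
            bins=np.array([10.0, 20.0]), mean_vpp=np.array([1.0, 2.0]),
            n_trials=np.array([1, 1]),
        )
        with pytest.raises(ValueError):
            evoked.fit_recruitment(curve)


class TestCompareConditions:
    def test_identical_conditions_no_effect(self):
        v = np.array([10.0, 20.0, 30.0, 40.0])
        res = evoked.compare_conditions(
            {"control": v, "treatment": v, "washout": v}
        )
        assert res["omnibus"]["p"] == 1.0
        assert not any(d["reject"] for d in res["posthoc"].values())

    def test_two_condition_f_equals_hand_worked_value(self):
        # paired design: F = t² with t = mean(d)/(sd(d)/√n); d = [1,3,−1,3]
        control = np.array([10.0, 12.0, 14.0, 16.0])
        treat = np.array([11.0, 15.0, 13.0, 19.0])
        res = evoked.compare_conditions({"control": control, "treatment": treat})
        assert res["omnibus"]["F"] == pytest.approx(27.0 / 11.0, rel=1e-9)

    def test_unbalanced_blocks_rejected(self):
        with pytest.raises(ValueError):
            evoked.compare_conditions(
                {"control": np.arange(4.0), "treatment": np.arange(3.0)}
            )

    def test_lidocaine_block_flagged_washout_not(self):
        # per-subject mean Vpp from simulated saline / lidocaine / washout runs
        flags = []
        recruit = SigmoidParams(Vmin=0.0, Vmax=100.0, I50=35.0, slope=5.0)
        for run in range(15):
            conds = {}
            for name, bf in (("control", 1.0), ("lidocaine", 0.02), ("washout", 1.0)):
                subj_means = []
                for subj in range(4):
                    sc = sd.AcuteScenario(
                        currents=[64.0], trials_per_current=8, isi_s=0.05,
                        recruit=recruit, block_factor=bf,
                        velocity_range=(8.0, 24.0), noise=sd.post_plating_noise(),
                    )
                    rec, events, _ = sd.gen_acute_session(sc, seed=10_000 + 100 * run + 10 * subj + int(bf * 7))
                    trials, _ = pipeline.acute_trials(rec, events)
                    subj_means.append(np.mean([evoked.response_vpp(t) for t in trials]))
                conds[name] = np.array(subj_means)
            res = evoked.compare_conditions(conds)
            flags.append(
                res["posthoc"]["lidocaine"]["reject"] and not res["posthoc"]["washout"]["reject"]
            )
        assert np.mean(flags) >= 0.9


def test_four_pl_monotone_increasing():
    x = np.linspace(0, 120, 200)
    y = four_pl(x, 5.0, 150.0, 40.0, 6.0)
    assert np.all(np.diff(y) > 0)
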