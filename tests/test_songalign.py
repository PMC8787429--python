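"""DTW alignment: brute-force oracle, warp recovery, warp application."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pnisig import songalign as sa
from pnisig import synthdata as sd, pipeline
from pnisig.sigproc import Envelope

from conftest import CHRONIC_BAND, small_chronic_scenario


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of admissible warp paths


def brute_force_cost(x, y, band=0.2):
    """Minimum path cost by enumerating every monotone step path."""
    x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    y = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    m, n = len(x), len(y)
    w = sa.band_width(m, n, band)
    best = [np.inf]

    def rec(i, j, acc):
        if acc >= best[0]:
            return
        if (i, j) == (m - 1, n - 1):
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ii, jj = i + di, j + dj
            if ii < m and jj < n and sa.in_band(ii, jj, m, n, w):
                rec(ii, jj, acc + (x[ii] - y[jj]) ** 2)

    if not sa.in_band(0, 0, m, n, w):
        return np.inf
    rec(0, 0, (x[0] - y[0]) ** 2)
    return best[0]


class TestDtwOracle:
    def test_identity_alignment_is_diagonal_with_zero_cost(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        path = sa.dtw_align(x, x)
        assert path.cost == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(path.pairs, np.column_stack([np.arange(4), np.arange(4)]))

    @pytest.mark.parametrize("m,n", list(itertools.product(range(2, 7), range(2, 7))))
    def test_matches_exhaustive_enumeration(self, m, n):
        rng = np.random.default_rng(97 * m + n)
        for _ in range(4):
            x = rng.normal(size=m)
            y = rng.normal(size=n)
            path = sa.dtw_align(x, y, band=0.5)
            assert path.cost == pytest.approx(brute_force_cost(x, y, band=0.5), rel=1e-9)

    def test_cost_symmetric_under_swap(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=14), rng.normal(size=12)
        assert sa.dtw_align(x, y, band=0.5).cost == pytest.approx(
            sa.dtw_align(y, x, band=0.5).cost, rel=1e-9
        )

    def test_zero_cost_iff_identical(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        assert sa.dtw_align(x, x.copy()).cost == pytest.approx(0.0, abs=1e-12)
        y = x.copy()
        y[10] += 2.0
        assert sa.dtw_align(x, y).cost > 1e-6

    def test_infeasible_band_raises(self):
        # zero band on strongly different-length sequences leaves no corridor
        with pytest.raises(sa.InfeasibleBandError):
            sa.dtw_align(np.arange(50.0), np.arange(5.0), band=0.0)


class TestWarpRecovery:
    def test_simulator_warp_recovered_within_3ms(self):
        sc = small_chronic_scenario(warp_jitter=0.1, renditions_per_day=6)
        _, _, gt = sd.gen_chronic_session(sc, seed=21, with_audio=False)
        errs = []
        template = sa.Template(feature=gt.audio_template)
        for r in range(6):
            feat = gt.audio_features[r]
            path = sa.dtw_align(feat, template)
            # recovered rendition index per template index vs true warp
            recov = np.full(len(template.feature), np.nan)
            for i, j in path.pairs:
                recov[j] = i
            true = gt.warps_ms[r][: len(template.feature)]
            errs.append(np.nanmedian(np.abs(recov - true)))
        assert np.median(errs) <= 3.0

    def test_alignment_improves_envelope_correlation(self):
        sc = small_chronic_scenario(warp_jitter=0.12, renditions_per_day=8)
        rec, motifs, gt = sd.gen_chronic_session(sc, seed=22, with_audio=False)
        aligned, _ = pipeline.chronic_aligned_envelopes(
            rec, motifs, gt.audio_features, band=CHRONIC_BAND
        )
        pre = pipeline.preprocess(rec, CHRONIC_BAND)
        L = min(int(d * 1000) for d in motifs["duration_unwarped_s"]) - 25
        raw = []
        for _, row in motifs.iterrows():
            i0 = int(round(row["start_s"] * pre.fs))
            i1 = int(round(row["stop_s"] * pre.fs))
            from pnisig.sigproc import Recording

            envs = pipeline.channel_envelopes(
                Recording(samples=pre.samples[i0:i1], fs=pre.fs, channels=pre.channels)
            )
            raw.append(envs[:, :L])
        raw = np.stack(raw)

        def mean_pairwise(env_stack):
            n = env_stack.shape[0]
            cs = []
            for c in range(env_stack.shape[1]):
                for a in range(n):
                    for b in range(a + 1, n):
                        cs.append(np.corrcoef(env_stack[a, c], env_stack[b, c])[0, 1])
            return np.mean(cs)

        assert mean_pairwise(aligned) > mean_pairwise(raw)


class TestBuildTemplate:
    def test_identical_renditions_give_that_rendition(self):
        f = np.array([1.0, 2.0, 4.0, 1.0])
        tpl = sa.build_template([f, f.copy(), f.copy()])
        assert np.allclose(tpl.feature, f)

    def test_two_equal_length_renditions_average(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([3.0, 4.0, 5.0])
        tpl = sa.build_template([a, b])
        assert np.allclose(tpl.feature, [2.0, 3.0, 4.0])

    def test_template_closer_to_truth_than_single_rendition(self):
        sc = small_chronic_scenario(warp_jitter=0.1, renditions_per_day=12)
        _, _, gt = sd.gen_chronic_session(sc, seed=23, with_audio=False)
        tpl = sa.build_template(gt.audio_features, n=12)
        truth = gt.audio_template
        L = min(len(tpl.feature), len(truth))

        def corr_to_truth(f):
            LL = min(len(f), len(truth))
            g = np.interp(np.linspace(0, 1, L), np.linspace(0, 1, LL), f[:LL])
            return np.corrcoef(g, truth[:L])[0, 1]

        tpl_corr = np.corrcoef(
            np.interp(np.linspace(0, 1, L), np.linspace(0, 1, len(tpl.feature)), tpl.feature),
            truth[:L],
        )[0, 1]
        singles = [corr_to_truth(f) for f in gt.audio_features]
        assert tpl_corr > np.mean(singles)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sa.build_template([])


class TestApplyWarp:
    def test_identity_path_is_identity(self):
        env = Envelope(values=np.array([1.0, 4.0, 9.0]))
        path = sa.WarpPath(pairs=np.column_stack([np.arange(3), np.arange(3)]))
        out = sa.apply_warp(env, path, 3)
        assert np.allclose(out.values, env.values)

    def test_many_to_one_bins_average(self):
        # rendition bins 1 and 2 both map to template bin 1
        path = sa.WarpPath(pairs=np.array([[0, 0], [1, 1], [2, 1], [3, 2]]))
        out = sa.apply_warp(np.array([10.0, 2.0, 4.0, 7.0]), path, 3)
        assert np.allclose(out, [10.0, 3.0, 7.0])

    def test_length_mismatch_rejected(self):
        path = sa.WarpPath(pairs=np.array([[0, 0], [1, 1]]))
        with pytest.raises(ValueError):
            sa.apply_warp(np.arange(5.0), path, 2)

    def test_noiseless_roundtrip_correlation(self):
        # warp a smooth envelope, align it back with DTW, compare to original
        rng = np.random.default_rng(8)
        from scipy.ndimage import gaussian_filter1d

        truth = gaussian_filter1d(rng.normal(size=400), 12)
        tk = np.arange(0, 401, 50.0)
        slopes = rng.uniform(0.9, 1.1, 8)
        rk = np.concatenate([[0], np.cumsum(slopes * np.diff(tk))])
        rend_ms = np.arange(int(rk[-1]))
        warped = np.interp(np.interp(rend_ms, rk, tk), np.arange(400.0), truth)
        path = sa.dtw_align(warped, sa.Template(feature=truth))
        back = sa.apply_warp(warped, path, 400)
        assert np.corrcoef(back, truth)[0, 1] >= 0.99


@given(st.integers(min_value=0, max_value=500))
def test_path_structure_invariants(seed):
    rng = np.random.default_rng(seed)
    m, n = rng.integers(3, 20, 2)
    path = sa.dtw_align(rng.normal(size=m), rng.normal(size=n), band=0.6)
    assert tuple(path.pairs[0]) == (0, 0)
    assert tuple(path.pairs[-1]) == (m - 1, n - 1)
    steps = np.diff(path.pairs, axis=0)
    assert set(map(tuple, steps)) <= {(1, 0), (0, 1), (1, 1)}
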