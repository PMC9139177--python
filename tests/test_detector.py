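"""Permutation-based effect-size detector."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from resperm.detector import (DISQUALIFIED, ChangepointResult, RespermConfig,
                              RespermDetector, _permutation_index_matrix,
                              _smallest_argmax, adjusted_cohens_d, detect,
                              permutation_slope_sds, pooled_sigma_beta)
from resperm.series import Series, fit_segment_pair
from resperm.simulate import SimulationSpec, generate_series

from conftest import naive_permutation_slope_sds


class TestPermutationSlopeSds:
    def test_zero_residuals_give_zero_sds(self):
        x = np.arange(1.0, 31.0)
        y = np.where(x <= 15, 2.0, 2.0 + (x - 15))  # exact broken line
        sd1, sd2 = permutation_slope_sds(Series(x, y), 15, 50, seed=0)
        assert sd1 == 0.0 and sd2 == 0.0

    def test_single_permutation_rejected(self, noisy_series):
        with pytest.raises(ValueError, match="sample SD"):
            permutation_slope_sds(noisy_series, 15, 1, seed=0)

    def test_matches_naive_double_loop_oracle(self, noisy_series):
        rng = np.random.default_rng(77)
        idx = _permutation_index_matrix(rng, 50, noisy_series.n)
        fast = permutation_slope_sds(noisy_series, 15, 50, perm_index=idx)
        slow = naive_permutation_slope_sds(noisy_series, 15, idx)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_series_reversal_swaps_regime_sds(self, noisy_series):
        """Mirroring the series exchanges the two regimes' slope SDs."""
        n, k = noisy_series.n, 12
        rng = np.random.default_rng(5)
        idx = _permutation_index_matrix(rng, 200, n)
        sd1, sd2 = permutation_slope_sds(noisy_series, k, 200,
                                         perm_index=idx)
        x_rev = (noisy_series.x[0] + noisy_series.x[-1]
                 - noisy_series.x)[::-1]
        rev = Series(x_rev, noisy_series.y[::-1].copy())
        # mirror the permutation stream so each position receives the
        # mirrored residual of the original stream
        idx_rev = (n - 1 - idx)[:, ::-1]
        sd1_r, sd2_r = permutation_slope_sds(rev, n - k, 200,
                                             perm_index=idx_rev)
        assert sd1_r == pytest.approx(sd2, rel=1e-9)
        assert sd2_r == pytest.approx(sd1, rel=1e-9)

    def test_permuted_residuals_alone_give_same_sds(self, noisy_series):
        """Refitting on permuted residuals as the response has the same
        slope spread as refitting on fitted + permuted residuals: the
        design is fixed, so the two differ by a constant slope."""
        k, n_perm = 15, 100
        pair = fit_segment_pair(noisy_series, k)
        idx = _permutation_index_matrix(np.random.default_rng(3), n_perm,
                                        noisy_series.n)
        with_fitted = permutation_slope_sds(noisy_series, k, n_perm,
                                            perm_index=idx)
        slopes1, slopes2 = [], []
        for row in idx:
            pr = pair.residuals[row]
            slopes1.append(np.polyfit(noisy_series.x[:k], pr[:k], 1)[0])
            slopes2.append(np.polyfit(noisy_series.x[k:], pr[k:], 1)[0])
        assert with_fitted[0] == pytest.approx(np.std(slopes1, ddof=1),
                                               rel=1e-8)
        assert with_fitted[1] == pytest.approx(np.std(slopes2, ddof=1),
                                               rel=1e-8)


class TestCriterion:
    def test_pooled_sigma_beta_formula(self):
        # equal components collapse to the common value
        assert pooled_sigma_beta(2.5, 2.5, 13, 40) == pytest.approx(2.5)
        # one-term case
        assert pooled_sigma_beta(3.0, 0.0, 2, 100) == \
            pytest.approx(math.sqrt(9 / 98))
        # midpoint split against direct evaluation
        sd1, sd2, n = 1.3, 0.4, 60
        k = n // 2
        expect = math.sqrt(((k - 1) * sd1**2 + (n - k - 1) * sd2**2)
                           / (n - 2))
        assert pooled_sigma_beta(sd1, sd2, k, n) == pytest.approx(expect)

    def test_adjusted_cohens_d(self):
        assert adjusted_cohens_d(0.7, 0.7, 2.0) == 0.0
        assert adjusted_cohens_d(0.0, 1.0, 0.5) == pytest.approx(2.0)
        # antisymmetry
        assert adjusted_cohens_d(0.2, 1.1, 0.3) == \
            pytest.approx(-adjusted_cohens_d(1.1, 0.2, 0.3))
        # zero spread: equal slopes -> 0, unequal -> disqualified
        assert adjusted_cohens_d(1.0, 1.0, 0.0) == 0.0
        assert adjusted_cohens_d(0.0, 1.0, 0.0) == DISQUALIFIED

    def test_tie_break_takes_smallest_candidate(self):
        ds = np.array([0.1, 3.0, 2.0, 3.0, -1.0])
        assert _smallest_argmax(ds) == 1


class TestDetect:
    def test_near_noise_free_recovery(self):
        # the kink observation lies on both branches of the generator,
        # so splits at 49 and 50 are equally exact; recovery is to the
        # kink up to that intrinsic ambiguity
        for seed in range(5):
            ser = generate_series(SimulationSpec(p=0.01, seed=seed))
            res = detect(ser, RespermConfig(n_perm=200, seed=seed))
            assert res.k_star in (49, 50)
            assert res.chp_x == float(res.k_star)

    def test_trace_covers_grid_and_optimum(self, noisy_series):
        cfg = RespermConfig(s=5, n_perm=100, seed=1)
        res = detect(noisy_series, cfg)
        ks = res.trace[:, 0]
        np.testing.assert_array_equal(
            ks, np.arange(5, noisy_series.n - 5 + 1))
        assert res.d_star == res.trace[:, 1].max()
        assert res.k_star == int(ks[np.argmax(res.trace[:, 1])])

    def test_seed_reproducibility(self, noisy_series):
        cfg = RespermConfig(s=5, n_perm=100, seed=42)
        a = detect(noisy_series, cfg)
        b = detect(noisy_series, cfg)
        assert a.k_star == b.k_star
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_shift_invariance(self, noisy_series):
        cfg = RespermConfig(s=5, n_perm=100, seed=9)
        a = detect(noisy_series, cfg)
        b = detect(Series(noisy_series.x, noisy_series.y + 100.0), cfg)
        assert a.k_star == b.k_star
        np.testing.assert_allclose(a.trace, b.trace, rtol=1e-8)

    def test_scale_invariance(self, noisy_series):
        cfg = RespermConfig(s=5, n_perm=100, seed=9)
        a = detect(noisy_series, cfg)
        b = detect(Series(noisy_series.x, 3.7 * noisy_series.y), cfg)
        assert a.k_star == b.k_star
        np.testing.assert_allclose(a.trace, b.trace, rtol=1e-8)

    def test_short_series_rejected(self):
        s = Series(np.arange(1.0, 11.0), np.arange(1.0, 11.0) ** 1.5)
        with pytest.raises(ValueError, match="2s"):
            detect(s, RespermConfig(s=10))

    def test_exact_line_is_degenerate(self):
        x = np.arange(1.0, 41.0)
        with pytest.raises(ValueError, match="degenerate"):
            detect(Series(x, 2 * x + 1), RespermConfig(s=5, n_perm=20,
                                                       seed=0))

    def test_labels_are_carried_through(self):
        ser = generate_series(SimulationSpec(p=0.01, seed=0))
        labelled = Series(ser.x, ser.y,
                          labels=np.arange(1000, 1000 + ser.n))
        res = detect(labelled, RespermConfig(n_perm=100, seed=0))
        assert res.chp_label == 1000 + res.k_star - 1


class TestEstimatorApi:
    def test_fit_sets_attributes_and_clone_roundtrips(self):
        ser = generate_series(SimulationSpec(p=0.01, seed=2))
        det = RespermDetector(n_perm=150, random_state=0)
        cloned = clone(det)
        assert cloned.get_params() == det.get_params()
        det.fit(ser.x.reshape(-1, 1), ser.y)
        assert det.k_star_ in (49, 50)
        assert isinstance(det.result_, ChangepointResult)
        assert det.trace_.shape[1] == 2

    def test_predict_follows_two_lines(self):
        ser = generate_series(SimulationSpec(p=0.01, seed=2))
        det = RespermDetector(n_perm=150, random_state=0).fit(ser.x, ser.y)
        pred = det.predict(ser.x)
        # near noise-free data: predictions track the generating trend
        assert np.max(np.abs(pred - ser.y)) < 0.2
        with pytest.raises(AttributeError):
            RespermDetector().predict(ser.x)
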