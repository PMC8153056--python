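import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from cardioaudio.behavior_sdt import (ConfusionCounts, fit_meta_d,
                                      interoceptive_indices, median_split,
                                      type1_sdt)


def counts_from_rates(hr, far, n_signal=100, n_noise=100):
    c = np.zeros((2, 2, 4))
    c[1, 1, 0] = round(hr * n_signal)
    c[1, 0, 0] = n_signal - c[1, 1, 0]
    c[0, 1, 0] = round(far * n_noise)
    c[0, 0, 0] = n_noise - c[0, 1, 0]
    return ConfusionCounts(c)


def sdt_trials(rng, n, d, meta_sd=0.0, thresholds=(0.5, 1.0, 1.5)):
    stim = rng.random(n) < 0.5
    x = rng.normal(np.where(stim, d / 2, -d / 2), 1.0)
    resp = x > 0
    x2 = x + (rng.normal(0, meta_sd, n) if meta_sd else 0.0)
    conf = 1 + (np.abs(x2)[:, None] > np.asarray(thresholds)).sum(axis=1)
    return stim, resp, conf


class TestType1:
    def test_equal_rates_give_zero_dprime(self):
        d, c = type1_sdt(counts_from_rates(0.4, 0.4))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_probit_formula(self):
        # d' = z(0.69) - z(0.31) = 2 z(0.69), from a high-precision oracle
        d, c = type1_sdt(counts_from_rates(0.69, 0.31))
        assert d == pytest.approx(2 * norm.ppf(0.69), abs=1e-9)
        assert c == pytest.approx(0.0, abs=1e-9)

    def test_extreme_rate_correction(self):
        # HR = 1 with 28 signal trials is replaced by 1 - 1/56
        cc = counts_from_rates(1.0, 0.5, n_signal=28, n_noise=28)
        d, _ = type1_sdt(cc)
        assert d == pytest.approx(norm.ppf(1 - 1 / 56) - norm.ppf(0.5), abs=1e-9)

    def test_antisymmetric_under_class_swap(self, rng):
        c = rng.integers(1, 40, size=(2, 2, 4)).astype(float)
        d1, _ = type1_sdt(ConfusionCounts(c))
        swapped = c[::-1]                      # swap signal/noise
        d2, _ = type1_sdt(ConfusionCounts(swapped))
        assert d1 == pytest.approx(-d2, abs=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 50), min_size=16, max_size=16),
           st.integers(1, 100), st.integers(1, 100))
    def test_antisymmetry_and_rate_bounds_hold_generally(self, cells, a, b):
        """For any confusion table with both stimulus classes populated,
        swapping the class labels negates d', and both indices stay finite
        thanks to the extreme-rate correction."""
        c = np.asarray(cells, dtype=float).reshape(2, 2, 4)
        c[0, 0, 0] += a          # ensure nonzero trials in both classes
        c[1, 0, 0] += b
        d1, c1 = type1_sdt(ConfusionCounts(c))
        d2, c2 = type1_sdt(ConfusionCounts(c[::-1]))
        assert d1 == pytest.approx(-d2, abs=1e-9)
        assert np.isfinite(d1) and np.isfinite(c1)

    def test_zero_trials_error(self):
        c = np.zeros((2, 2, 4))
        c[1, 1, 0] = 10
        with pytest.raises(ValueError):
            type1_sdt(ConfusionCounts(c))


class TestMetaD:
    def test_ideal_observer_mratio_near_one(self, rng):
        stim, resp, conf = sdt_trials(rng, 10_000, d=1.0, meta_sd=0.0)
        fit = fit_meta_d(ConfusionCounts.from_trials(stim, resp, conf))
        assert 0.95 <= fit.m_ratio <= 1.05

    def test_shuffled_confidence_kills_meta_d(self, rng):
        stim, resp, conf = sdt_trials(rng, 10_000, d=1.5)
        conf = rng.permutation(conf)
        fit = fit_meta_d(ConfusionCounts.from_trials(stim, resp, conf))
        assert abs(fit.meta_d) <= 0.1

    def test_optimum_beats_grid_search(self, rng):
        """Profile likelihood at the fitted meta-d' must be at least the
        best of a 41-point brute-force grid over meta-d' in [-2, 4]."""
        from scipy.optimize import minimize

        from cardioaudio.behavior_sdt import _meta_cell_logprobs

        stim, resp, conf = sdt_trials(rng, 2_000, d=1.0, meta_sd=0.5)
        cc = ConfusionCounts.from_trials(stim, resp, conf)
        fit = fit_meta_d(cc)
        d1, c1 = type1_sdt(cc)
        c_rel = c1 / d1
        obs = cc.counts + 1.0 / 16.0

        def profile_ll(meta_d):
            def nll(theta):
                lp = _meta_cell_logprobs(meta_d, c_rel, theta[:3], theta[3:])
                pr = np.log(np.exp(lp).sum(axis=2, keepdims=True))
                return -float(np.sum(obs * (lp - pr)))
            best = np.inf
            for s in (0.3, 0.7):
                r = minimize(nll, np.full(6, np.log(np.expm1(s))),
                             method="L-BFGS-B")
                best = min(best, r.fun)
            return -best

        grid_best = max(profile_ll(m) for m in np.linspace(-2, 4, 41))
        assert fit.log_likelihood >= grid_best - 1e-3

    @pytest.mark.parametrize("meta_sd", [0.0, 0.5, 1.0])
    def test_recovers_generating_meta_d(self, meta_sd, rng):
        """Fits to finite samples land within 0.15 of the population-level
        (expected-count) fit at each metacognitive noise level."""
        from scipy.stats import multivariate_normal

        d, ths = 1.2, np.array([0.5, 1.0, 1.5])
        bounds = np.concatenate([[-np.inf], -ths[::-1], [0.0], ths, [np.inf]])
        cells = np.zeros((2, 2, 4))
        cov = np.array([[1.0, 1.0], [1.0, 1.0 + meta_sd ** 2]])

        def orthant(lo_x, hi_x, lo_y, hi_y, mu):
            mvn = multivariate_normal(mean=[mu, mu], cov=cov, allow_singular=True)
            big = 30.0
            a = mvn.cdf([min(hi_x, big), min(hi_y, big)])
            b = mvn.cdf([max(lo_x, -big), min(hi_y, big)])
            c = mvn.cdf([min(hi_x, big), max(lo_y, -big)])
            dd = mvn.cdf([max(lo_x, -big), max(lo_y, -big)])
            return a - b - c + dd

        for s, mu in ((0, -d / 2), (1, d / 2)):
            for r, (lo_x, hi_x) in ((0, (-np.inf, 0.0)), (1, (0.0, np.inf))):
                for k in range(4):
                    if r == 1:
                        lo_y, hi_y = bounds[4 + k], bounds[5 + k]
                    else:
                        lo_y, hi_y = bounds[3 - k], bounds[4 - k]
                    cells[s, r, k] = orthant(lo_x, hi_x, lo_y, hi_y, mu)
        cells /= cells.sum()

        pop_fit = fit_meta_d(ConfusionCounts(cells * 1e4))
        sample = rng.multinomial(10_000, cells.ravel()).reshape(2, 2, 4)
        fit = fit_meta_d(ConfusionCounts(sample.astype(float)))
        assert abs(fit.meta_d - pop_fit.meta_d) <= 0.15


class TestIndices:
    def make_behavior(self, rng, n=200):
        rows = []
        for i in range(n):
            att = "internal" if i % 2 == 0 else "external"
            dly = "short" if (i // 2) % 2 == 0 else "long"
            om = (i // 4) % 2 == 0
            rows.append({"trial": i, "attention": att, "delay": dly,
                         "omission_trial": int(om),
                         "response": "yes" if rng.random() < 0.5 else "no",
                         "confidence": int(rng.integers(1, 5))})
        return pd.DataFrame(rows)

    def test_sensibility_is_median_confidence(self, rng):
        beh = self.make_behavior(rng)
        internal = beh["attention"] == "internal"
        beh.loc[internal, "confidence"] = \
            ([1, 2, 2, 3] * 100)[:internal.sum()]
        idx = interoceptive_indices(beh)
        assert idx.sensibility == 2

    def test_bpq_subscales_are_item_sums(self, rng):
        idx = interoceptive_indices(self.make_behavior(rng),
                                    bpq_awareness_items=[1, 2, 3],
                                    bpq_autonomic_items=[4, 4])
        assert idx.bpq_awareness == 6
        assert idx.bpq_autonomic == 8

    def test_missing_confidence_rejected(self, rng):
        beh = self.make_behavior(rng)
        beh.loc[0, "confidence"] = np.nan
        with pytest.raises(ValueError):
            interoceptive_indices(beh)

    def test_median_split_ties_go_low(self):
        labels = median_split([1.0, 2.0, 2.0, 3.0])
        assert labels == ["low", "low", "low", "high"]

    def test_indices_invariant_to_trial_order(self, rng):
        beh = self.make_behavior(rng)
        a = interoceptive_indices(beh)
        b = interoceptive_indices(beh.sample(frac=1.0, random_state=1))
        assert a.d_internal == pytest.approx(b.d_internal)
        assert a.d_external == pytest.approx(b.d_external)
        assert a.sensibility == b.sensibility
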