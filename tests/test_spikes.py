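"""Spike-train synchrony, ISI motifs, Granger coupling, effective correlation."""

import numpy as np
import pytest

from striodm.exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from striodm.spikes import (
    EXC,
    INH,
    TIE,
    MotifCounts,
    SpikeTrain,
    activity_cross_correlation,
    bin_spike_counts,
    count_functional_motifs,
    effective_correlation,
    generate_coupled_trains,
    granger_coupling,
    isi_classify,
)


def ar1_pair(n, rng, rho=0.5):
    e = rng.standard_normal((2, n + 50))
    x = np.zeros((2, n + 50))
    for t in range(1, n + 50):
        x[:, t] = rho * x[:, t - 1] + e[:, t]
    return x[0, 50:], x[1, 50:]


class TestGenerator:
    def test_spike_count_poisson(self):
        pairs = generate_coupled_trains(1, base_rate=5.0, duration=60.0, seed=0)
        n = pairs[0][0].n_spikes
        assert abs(n - 300) < 3 * np.sqrt(300)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            generate_coupled_trains(1, base_rate=0.0)
        with pytest.raises(InvalidParameterError):
            generate_coupled_trains(1, coupling_strength=1.5)

    def test_strictly_increasing_times_enforced(self):
        with pytest.raises(InvalidParameterError):
            SpikeTrain(0, "sSPN", np.array([0.1, 0.1, 0.2]), 1.0)
        with pytest.raises(InvalidParameterError):
            SpikeTrain(0, "sSPN", np.array([0.1, 2.0]), 1.0)

    def test_full_coupling_peak_at_lag(self):
        pairs = generate_coupled_trains(
            5, base_rate=8.0, coupling_strength=1.0, lag=0.1, duration=120.0, seed=1
        )
        for s, m in pairs:
            xc = activity_cross_correlation(s, m, bin_width=0.05, max_lag=0.3)
            assert abs(xc["peak_lag"] - 0.1) <= 0.05

    def test_zero_coupling_uncorrelated(self):
        pairs = generate_coupled_trains(
            40, base_rate=5.0, coupling_strength=0.0, duration=60.0, seed=2
        )
        flagged = sum(
            activity_cross_correlation(s, m)["correlated"] for s, m in pairs
        )
        assert flagged <= 2  # r^2 > 0.4 virtually never under independence


class TestCrossCorrelation:
    def test_identical_trains_peak_at_zero(self):
        (s, _), = generate_coupled_trains(1, base_rate=5.0, duration=30.0, seed=3)
        xc = activity_cross_correlation(s, s)
        assert xc["peak_lag"] == 0.0 and xc["peak_r"] == pytest.approx(1.0)

    def test_shift_moves_peak_one_bin(self):
        (s, _), = generate_coupled_trains(1, base_rate=10.0, duration=30.0, seed=4)
        shifted = SpikeTrain(
            1, "mSPN", s.times[s.times < 30.0 - 0.05] + 0.05, 30.0
        )
        xc = activity_cross_correlation(s, shifted, bin_width=0.05)
        assert xc["peak_lag"] == pytest.approx(0.05)

    def test_matches_textbook_pearson(self):
        a = SpikeTrain(0, "sSPN", np.array([0.01, 0.12, 0.13, 0.33, 0.41, 0.55]), 0.6)
        b = SpikeTrain(1, "mSPN", np.array([0.02, 0.11, 0.31, 0.32, 0.56]), 0.6)
        ca, cb = bin_spike_counts(a, 0.1), bin_spike_counts(b, 0.1)
        expected = np.corrcoef(ca, cb)[0, 1]
        xc = activity_cross_correlation(a, b, bin_width=0.1, max_lag=0.0)
        assert xc["table"].r.iloc[0] == pytest.approx(expected)

    def test_empty_train_rejected(self):
        a = SpikeTrain(0, "sSPN", np.array([]), 1.0)
        b = SpikeTrain(1, "mSPN", np.array([0.5]), 1.0)
        with pytest.raises(UndefinedStatisticError):
            activity_cross_correlation(a, b)


class TestIsiClassification:
    def test_definition_with_tie(self):
        tr = SpikeTrain(0, "sSPN", np.array([0.0, 1.0, 3.0, 6.0]), 10.0)
        out = isi_classify(tr)  # ISIs 1, 2, 3; median 2
        assert out["labels"].tolist() == [EXC, TIE, INH]
        assert not out["degenerate"]

    def test_constant_isis_degenerate(self):
        tr = SpikeTrain(0, "sSPN", np.arange(10) * 0.5, 10.0)
        out = isi_classify(tr)
        assert out["degenerate"] and np.all(out["labels"] == TIE)

    def test_poisson_train_balanced(self):
        (s, _), = generate_coupled_trains(1, base_rate=20.0, duration=50.0, seed=5)
        out = isi_classify(s)
        frac_e = (out["labels"] == EXC).mean()
        assert abs(frac_e - 0.5) < 0.05

    def test_too_few_spikes(self):
        with pytest.raises(InsufficientDataError):
            isi_classify(SpikeTrain(0, "sSPN", np.array([0.1, 0.5]), 1.0))


class TestMotifCounting:
    def toy_classified(self, end_times, labels):
        return {"end_times": np.asarray(end_times, float),
                "labels": np.asarray(labels, int)}

    def test_hand_counted_toy_example(self):
        s = self.toy_classified([1.0, 2.0, 3.0], [EXC, INH, EXC])
        m = self.toy_classified([1.05, 2.08, 3.5], [EXC, EXC, INH])
        mc = count_functional_motifs(s, m, window=0.1, n_shuffles=10, seed=0)
        # pairs within 0.1: (1.0 E -> 1.05 E), (2.0 I -> 2.08 E)
        assert mc.counts == {"EE": 1, "EI": 0, "IE": 1, "II": 0}

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        ends_s = np.sort(rng.uniform(0, 30, 50))
        ends_m = np.sort(rng.uniform(0, 30, 60))
        lab_s = rng.integers(0, 2, 50)
        lab_m = rng.integers(0, 2, 60)
        a = count_functional_motifs(
            self.toy_classified(ends_s, lab_s), self.toy_classified(ends_m, lab_m),
            window=0.2, n_shuffles=10, seed=1,
        )
        b = count_functional_motifs(
            self.toy_classified(ends_s + 5.0, lab_s),
            self.toy_classified(ends_m + 5.0, lab_m),
            window=0.2, n_shuffles=10, seed=1,
        )
        assert a.counts == b.counts

    def test_window_larger_than_recording_rejected(self):
        s = self.toy_classified([1.0, 2.0, 3.0], [EXC, INH, EXC])
        with pytest.raises(InvalidParameterError):
            count_functional_motifs(s, s, window=10.0)

    def test_null_calibration(self):
        """Independent trains stay within the 3-SD shuffle band."""
        pairs = generate_coupled_trains(
            100, base_rate=5.0, coupling_strength=0.0, duration=60.0, seed=7
        )
        exceed = 0
        for s, m in pairs:
            mc = count_functional_motifs(
                isi_classify(s), isi_classify(m), n_shuffles=300, seed=8
            )
            exceed += any(mc.z_score(k) > 3 for k in ("EE", "EI", "IE", "II"))
        assert exceed <= 5  # >= 95% of pairs inside the band

    def test_excitatory_coupling_inflates_ee(self):
        pairs = generate_coupled_trains(
            30, base_rate=5.0, coupling_strength=0.8, duration=60.0, seed=9
        )
        above = sum(
            count_functional_motifs(
                isi_classify(s), isi_classify(m), n_shuffles=200, seed=10
            ).z_score("EE") > 3
            for s, m in pairs
        )
        assert above > 15  # majority of pairs


class TestGranger:
    def test_directed_coupling_detected(self):
        rng = np.random.default_rng(11)
        n = 600
        a = rng.standard_normal(n)
        b = np.zeros(n)
        for t in range(2, n):
            b[t] = 0.3 * b[t - 1] + 0.6 * a[t - 1] + 0.5 * rng.standard_normal()
        res = granger_coupling(a, b, max_order=4)
        assert res["a_to_b"]["p"] < 1e-6
        assert res["b_to_a"]["p"] > 0.001

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_sim = 150
        for _ in range(n_sim):
            a, b = ar1_pair(400, rng)
            res = granger_coupling(a, b, max_order=4)
            rejections += res["a_to_b"]["p"] < 0.05
        assert 0.01 <= rejections / n_sim <= 0.10

    def test_constant_series_flagged(self):
        assert granger_coupling(np.ones(200), np.arange(200.0))["degenerate"]

    def test_matches_statsmodels_f_test(self):
        """Cross-check the in-package lag-OLS F test against statsmodels."""
        from statsmodels.tsa.stattools import grangercausalitytests

        rng = np.random.default_rng(13)
        a, b = ar1_pair(300, rng)
        order = 3
        from striodm.spikes import _granger_direction

        f_ours, p_ours = _granger_direction(a, b, order)
        res = grangercausalitytests(np.column_stack([b, a]), maxlag=[order])
        f_sm, p_sm, *_ = res[order][0]["ssr_ftest"]
        assert f_ours == pytest.approx(f_sm, rel=1e-6)
        assert p_ours == pytest.approx(p_sm, rel=1e-6)

    def test_short_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            granger_coupling(np.ones(30), np.ones(30), max_order=5)


class TestEffectiveCorrelation:
    def test_identical_neurons(self):
        x = np.tile(np.sin(np.linspace(0, 10, 200))[:, None], (1, 5))
        assert effective_correlation(x) == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        t = np.linspace(0, 10, 100)
        x = np.column_stack([np.sin(t), -np.sin(t)])
        assert effective_correlation(x) == pytest.approx(1.0)

    def test_independent_noise_near_null_level(self):
        rng = np.random.default_rng(14)
        T = 1000
        x = rng.standard_normal((T, 30))
        expected = np.sqrt(2 / (np.pi * T))  # E|r| under the null
        val = effective_correlation(x)
        n_pairs = 30 * 29 / 2
        se = 3 * expected / np.sqrt(n_pairs)
        assert abs(val - expected) < 5 * se

    def test_zero_variance_neuron_excluded(self):
        rng = np.random.default_rng(15)
        x = np.column_stack([rng.standard_normal(50), np.ones(50), rng.standard_normal(50)])
        with pytest.warns(RuntimeWarning):
            val = effective_correlation(x)
        assert 0 <= val <= 1
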