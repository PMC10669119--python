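"""Multitaper spectrogram, surrogates, distances and the stationarity test."""

import math

import numpy as np
import pytest

from gradpuff import tfstat
from gradpuff.errors import DegenerateInputError, LengthError, ParameterError
from gradpuff.tfstat import (
    EPS_FLOOR,
    hermite_bank,
    local_global_distances,
    make_surrogates,
    mt_spectrogram,
    spectral_distance,
    theta_statistic,
)

# alias: pytest must not collect the library function as a test
tf_test = tfstat.test_stationarity


def brute_force_distance(G, H):
    """Loop-level evaluation of k(G,H) = kKL(G~,H~)*(1+kLSD(G,H))."""
    Gf = [max(g, EPS_FLOOR * max(G)) for g in G]
    Hf = [max(h, EPS_FLOOR * max(H)) for h in H]
    Gn = [g / sum(Gf) for g in Gf]
    Hn = [h / sum(Hf) for h in Hf]
    kl = sum((g - h) * math.log(g / h) for g, h in zip(Gn, Hn))
    lsd = sum(abs(math.log(g / h)) for g, h in zip(Gf, Hf))
    return kl * (1 + lsd)


class TestHermiteBank:
    @pytest.mark.parametrize("Nh", [129, 257, 513])
    def test_orthonormal_k5(self, Nh):
        bank = hermite_bank(5, Nh)
        assert np.abs(bank.gram() - np.eye(5)).max() < 1e-8

    def test_k1_is_unit_norm_gaussian_like(self):
        bank = hermite_bank(1, 65)
        w = bank.windows[0]
        assert np.linalg.norm(w) == pytest.approx(1.0, rel=1e-12)
        assert np.argmax(w) == 32  # peaked at the center
        assert np.all(w > -1e-10)  # no sign change

    def test_window_k_has_k_minus_1_sign_changes(self):
        bank = hermite_bank(5, 257)
        for k, w in enumerate(bank.windows, start=1):
            sig = np.sign(w[np.abs(w) > 1e-8])
            changes = int(np.sum(np.diff(sig) != 0))
            assert changes == k - 1

    @pytest.mark.parametrize("K,Nh", [(0, 31), (5, 20), (5, 19), (5, 128)])
    def test_invalid_parameters_rejected(self, K, Nh):
        with pytest.raises(ParameterError):
            hermite_bank(K, Nh)


class TestSpectrogram:
    def test_zero_signal_gives_zero_spectrogram(self):
        bank = hermite_bank(3, 33)
        spec = mt_spectrogram(np.zeros(500), bank)
        assert np.all(spec.S == 0)

    def test_k1_equals_single_window_spectrogram(self, rng):
        x = rng.standard_normal(400)
        bank1 = hermite_bank(1, 41)
        spec = mt_spectrogram(x, bank1, stride=20)
        h = bank1.windows[0]
        half = 20
        for i, t in enumerate(spec.tn):
            seg = x[t - half : t + half + 1] * h
            ref = np.abs(np.fft.rfft(seg)) ** 2
            assert np.allclose(spec.S[i], ref, rtol=1e-12, atol=1e-12)

    def test_too_short_signal_rejected(self):
        bank = hermite_bank(5, 101)
        with pytest.raises(LengthError):
            mt_spectrogram(np.zeros(50), bank)

    def test_white_noise_marginal_flat(self, rng):
        """Time-marginalized multitaper spectrum of white noise is flat
        across frequency within averaged-periodogram variability."""
        x = rng.standard_normal(20000)
        bank = hermite_bank(5, 201)
        spec = mt_spectrogram(x, bank)
        marginal = spec.S.mean(axis=0)[1:-1]  # skip DC/Nyquist halves
        rel_dev = marginal / marginal.mean() - 1
        # ~K*N averaged periodograms -> relative SD ~ 1/sqrt(K*N)
        n_avg = bank.K * spec.S.shape[0]
        assert np.std(rel_dev) < 4.0 / np.sqrt(n_avg)


class TestSurrogates:
    def test_modulus_preserved_exactly(self, rng):
        for n in (256, 257, 1000):
            x = rng.standard_normal(n)
            s = make_surrogates(x, 8, seed=0)
            X = np.abs(np.fft.rfft(x))
            S = np.abs(np.fft.rfft(s, axis=1))
            assert np.max(np.abs(S - X)) < 1e-9 * X.max()

    def test_variance_preserved_via_parseval(self, rng):
        x = rng.standard_normal(1024)
        s = make_surrogates(x, 16, seed=1)
        assert np.allclose(np.sum(s * s, axis=1), np.sum(x * x), rtol=1e-9)

    def test_output_is_real_and_reproducible(self, rng):
        x = rng.standard_normal(333)
        a = make_surrogates(x, 4, seed=42)
        b = make_surrogates(x, 4, seed=42)
        assert a.dtype.kind == "f"
        assert np.array_equal(a, b)


class TestSpectralDistance:
    def test_identity_is_zero(self, rng):
        G = rng.uniform(0.1, 1, 32)
        assert spectral_distance(G, G) == pytest.approx(0.0, abs=1e-12)

    def test_four_bin_hand_oracle(self):
        G = np.array([1.0, 1.0, 1.0, 1.0]) / 4
        H = np.array([2.0, 1.0, 1.0, 0.0]) / 4
        assert spectral_distance(G, H) == pytest.approx(brute_force_distance(G, H), rel=1e-10)

    def test_symmetry(self, rng):
        for _ in range(20):
            G = rng.uniform(0, 1, 16)
            H = rng.uniform(0, 1, 16)
            assert spectral_distance(G, H) == pytest.approx(
                spectral_distance(H, G), rel=1e-10)

    def test_random_spectra_match_brute_force(self, rng):
        for _ in range(100):
            nf = int(rng.integers(4, 40))
            G = rng.uniform(0, 2, nf)
            H = rng.uniform(0, 2, nf)
            assert spectral_distance(G, H) == pytest.approx(
                brute_force_distance(G, H), rel=1e-10)

    def test_zero_mass_rejected(self):
        with pytest.raises(DegenerateInputError):
            spectral_distance(np.zeros(8), np.ones(8))


class TestLocalGlobal:
    def _spec(self, S):
        return tfstat.MultitaperSpectrogram(
            tn=np.arange(S.shape[0]), freqs=np.arange(S.shape[1], dtype=float),
            S=S, K=1, Nh=3)

    def test_time_constant_spectrogram_gives_zero(self):
        S = np.tile(np.linspace(1, 2, 8), (5, 1))
        c = local_global_distances(self._spec(S))
        assert np.allclose(c, 0.0, atol=1e-12)

    def test_two_bin_matches_hand_evaluation(self, rng):
        S = rng.uniform(0.2, 1.0, (2, 6))
        c = local_global_distances(self._spec(S))
        Gbar = S.mean(axis=0)
        for i in range(2):
            assert c[i] == pytest.approx(brute_force_distance(S[i], Gbar), rel=1e-10)

    def test_permutation_invariance_of_multiset(self, rng):
        S = rng.uniform(0.1, 1.0, (7, 10))
        c1 = local_global_distances(self._spec(S))
        perm = rng.permutation(7)
        c2 = local_global_distances(self._spec(S[perm]))
        assert np.allclose(np.sort(c1), np.sort(c2), rtol=1e-12)

    def test_single_time_rejected(self, rng):
        with pytest.raises(LengthError):
            local_global_distances(self._spec(rng.uniform(0.5, 1, (1, 6))))


class TestTheta:
    def test_constant_divergences_give_zero(self):
        assert theta_statistic(np.full(10, 0.7)) == 0.0

    def test_hand_value(self):
        assert theta_statistic(np.array([0.0, 2.0])) == pytest.approx(1.0)

    def test_quadratic_homogeneity(self, rng):
        c = rng.uniform(0, 1, 25)
        for a in (0.5, 2.0, 10.0):
            assert theta_statistic(a * c) == pytest.approx(
                a * a * theta_statistic(c), rel=1e-10)

    def test_matches_loop_variance(self, rng):
        for _ in range(100):
            c = rng.uniform(0, 3, int(rng.integers(2, 30)))
            m = sum(c) / len(c)
            expected = sum((v - m) ** 2 for v in c) / len(c)
            assert theta_statistic(c) == pytest.approx(expected, rel=1e-10, abs=1e-15)


class TestStationarityTest:
    def test_deterministic_given_seed(self, white_noise_2000):
        r1 = tf_test(white_noise_2000, J=20, seed=5)
        r2 = tf_test(white_noise_2000, J=20, seed=5)
        assert r1.theta1 == r2.theta1
        assert np.array_equal(r1.theta0, r2.theta0)
        assert r1.decision == r2.decision

    def test_am_noise_flagged_nonstationary(self, rng):
        t = np.arange(2000) / 2000
        x = np.sin(2 * np.pi * 3 * t) * rng.standard_normal(2000)
        res = tf_test(x, K=5, win_frac=0.05, J=50, seed=0)
        assert res.decision == "non-stationary"
        assert res.INS > res.INS_threshold

    def test_decision_stable_in_surrogate_count(self, rng):
        """Few vs many surrogates agree on clear cases."""
        w = rng.standard_normal(2000)
        t = np.arange(2000) / 2000
        am = np.sin(2 * np.pi * 3 * t) * rng.standard_normal(2000)
        for x, expected in [(w, "stationary"), (am, "non-stationary")]:
            d_small = tf_test(x, J=50, seed=3).decision
            d_large = tf_test(x, J=400, seed=3).decision
            assert d_small == d_large == expected

    def test_theta0_mean_stable_across_seeds(self, rng):
        x = rng.standard_normal(1500)
        m = [tf_test(x, J=2000, seed=s).theta0_mean for s in (1, 2)]
        assert abs(m[0] - m[1]) / m[0] < 0.05

    def test_gamma_threshold_close_to_empirical_quantile(self, rng):
        x = rng.standard_normal(1500)
        res = tf_test(x, J=2000, seed=4)
        emp = np.quantile(res.theta0, 1 - res.alpha)
        assert res.threshold == pytest.approx(emp, rel=0.10)

    def test_surrogate_pvalue_uniform(self, rng):
        """A surrogate analyzed as 'the signal' is exchangeable with the null
        sample: its empirical p-value is ~uniform over repeated runs."""
        x = rng.standard_normal(512)
        pvals = []
        for run in range(200):
            s = make_surrogates(x, 1, seed=10_000 + run)[0]
            res = tf_test(s, K=5, win_frac=0.1, J=32, seed=run)
            pvals.append((1 + np.sum(res.theta0 >= res.theta1)) / (1 + res.J))
        pvals = np.sort(pvals)
        grid = (np.arange(1, 201)) / 200
        ks = np.max(np.abs(pvals - grid))
        assert ks < 0.15

    def test_ins_consistency_with_decision(self, white_noise_2000):
        res = tf_test(white_noise_2000, J=100, seed=8)
        # sqrt convention: INS > threshold iff theta1 > gamma
        assert (res.INS > res.INS_threshold) == (res.theta1 > res.threshold)
        ratio = tf_test(white_noise_2000, J=100, seed=8,
                                  ins_convention="ratio")
        assert ratio.INS == pytest.approx(res.INS ** 2, rel=1e-10)

    def test_too_short_signal_raises_length_error(self):
        with pytest.raises((LengthError, ParameterError)):
            tf_test(np.zeros(40), K=5, win_frac=0.2, J=5)

    def test_summary_and_diagnostic_plot(self, white_noise_2000):
        import matplotlib
        matplotlib.use("Agg")
        res = tfstat.TimeFrequencyStationarityTest(
            white_noise_2000, J=50).fit(seed=0)
        assert "theta1" in res.summary()
        ax = res.plot_diagnostic()
        assert ax is not None


def test_ins_curve_shapes(rng):
    x = rng.standard_normal(1200)
    out = tfstat.ins_curve(x, win_frac_list=[0.05, 0.075], J=20, seed=0)
    assert [wf for wf, _, _ in out] == [0.05, 0.075]
    assert tfstat.ins_curve(x, win_frac_list=[], J=20, seed=0) == []


def test_ins_curve_stationary_below_threshold(rng):
    """On stationary noise the INS stays below its threshold across the
    window-size sweep."""
    x = rng.standard_normal(3000)
    out = tfstat.ins_curve(x, win_frac_list=[0.03, 0.05, 0.075], J=50, seed=1)
    for _, ins, thr in out:
        assert ins < thr
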