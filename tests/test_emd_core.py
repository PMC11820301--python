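import numpy as np
import pytest

from vagpipe import Recording, SiftConfig, emd, envelopes, find_extrema, is_imf
from vagpipe.emd_core import NotSiftableError, count_zero_crossings
from vagpipe.signal_model import InvalidInputError


class TestFindExtrema:
    def test_simple_alternation(self):
        maxima, minima = find_extrema([0, 1, 0, -1, 0])
        assert maxima.tolist() == [1]
        assert minima.tolist() == [3]

    def test_monotone_has_no_extrema(self):
        maxima, minima = find_extrema(np.arange(50.0))
        assert maxima.size == 0 and minima.size == 0

    def test_sine_extrema_near_analytic_positions(self):
        t = np.arange(1000) / 1000.0
        maxima, minima = find_extrema(np.sin(2 * np.pi * t))
        assert maxima.size == 1 and minima.size == 1
        assert abs(maxima[0] - 250) <= 2
        assert abs(minima[0] - 750) <= 2

    def test_plateau_reports_midpoint_once(self):
        maxima, minima = find_extrema([0, 1, 1, 1, 0, -1, 0])
        assert maxima.tolist() == [2]
        assert minima.tolist() == [5]

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            find_extrema([1.0, 2.0])


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ([1, -1, 1, -1], 3),
            ([1, 0, -1], 1),  # exact zero counts once
            ([1, 0, 1], 1),  # touching zero counts once
            ([1, 2, 3], 0),
        ],
    )
    def test_counting_rules(self, x, expected):
        assert count_zero_crossings(np.asarray(x, dtype=float)) == expected


class TestEnvelopes:
    def test_sine_envelopes_near_unit(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 5 * t)
        maxima, minima = find_extrema(x)
        upper, lower, mean = envelopes(x, maxima, minima)
        interior = slice(200, 1800)
        assert np.all(np.abs(upper[interior] - 1.0) < 0.05)
        assert np.all(np.abs(lower[interior] + 1.0) < 0.05)
        assert np.all(np.abs(mean[interior]) < 0.05)

    def test_offset_sine_mean_envelope_at_offset(self):
        t = np.arange(2000) / 1000.0
        x = 2.0 + np.sin(2 * np.pi * 5 * t)
        maxima, minima = find_extrema(x)
        _, _, mean = envelopes(x, maxima, minima)
        assert np.all(np.abs(mean[200:1800] - 2.0) < 0.05)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        maxima, minima = find_extrema(x)
        u1, l1, _ = envelopes(x, maxima, minima)
        maxima2, minima2 = find_extrema(-x)
        u2, l2, _ = envelopes(-x, maxima2, minima2)
        np.testing.assert_allclose(u2, -l1, atol=1e-10)
        np.testing.assert_allclose(l2, -u1, atol=1e-10)


class TestIsIMF:
    def test_pure_sine_is_imf(self):
        t = np.arange(2000) / 1000.0
        assert is_imf(np.sin(2 * np.pi * 5 * t))

    def test_monotone_ramp_is_not(self):
        assert not is_imf(np.linspace(-1, 1, 100))

    def test_offset_sine_fails_mean_condition(self):
        t = np.arange(2000) / 1000.0
        assert not is_imf(np.sin(2 * np.pi * 5 * t) + 0.5, tol_mean=0.05)


class TestEMD:
    def test_monotone_input_gives_zero_imfs(self):
        s = emd(np.linspace(0, 1, 100) ** 2 + np.linspace(0, 1, 100))
        assert s.n_imfs == 0
        np.testing.assert_allclose(s.residual, np.linspace(0, 1, 100) ** 2 + np.linspace(0, 1, 100))

    def test_constant_input_rejected(self):
        with pytest.raises(NotSiftableError):
            emd(np.full(100, 3.14))

    def test_two_tone_separation(self, two_tone_probe):
        t = np.arange(two_tone_probe.size) / 1000.0
        s = emd(two_tone_probe)
        assert s.n_imfs >= 2
        fast = np.sin(2 * np.pi * 10 * t)
        slow = np.sin(2 * np.pi * 1 * t)
        assert np.corrcoef(s.imfs[0], fast)[0, 1] > 0.95
        assert np.corrcoef(s.imfs[1], slow)[0, 1] > 0.95

    @pytest.mark.parametrize("seed", range(5))
    def test_completeness_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(3000)
        s = emd(x)
        err = np.abs(x - s.reconstruct()).max()
        assert err <= 1e-8 * x.std()

    def test_accepted_imfs_satisfy_count_condition(self, two_tone_probe):
        s = emd(two_tone_probe)
        for imf in s.imfs:
            maxima, minima = find_extrema(imf)
            n_ext = maxima.size + minima.size
            n_zc = count_zero_crossings(imf)
            assert abs(n_ext - n_zc) <= 1

    def test_mode_ordering_by_zero_crossing_rate(self):
        """Modes come out frequency-ordered: zero-crossing rate non-increasing."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.arange(5000) / 1000.0
            x = np.sin(2 * np.pi * 1 * t) + np.sin(2 * np.pi * 10 * t) + 0.1 * rng.standard_normal(t.size)
            s = emd(x)
            rates = [count_zero_crossings(c) for c in s.imfs]
            if all(rates[i] >= rates[i + 1] - 1 for i in range(len(rates) - 1)):
                ok += 1
        assert ok >= 18

    def test_recording_input_accepted(self, noise_recording):
        s = emd(noise_recording)
        assert s.source_length == noise_recording.samples.size

    def test_max_imfs_budget_respected(self, two_tone_probe):
        s = emd(two_tone_probe, SiftConfig(max_imfs=2))
        assert s.n_imfs <= 2
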