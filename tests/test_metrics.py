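"""Tests for PSD-based IMF quality metrics (alignment, mixing, counts)."""

import numpy as np
import pytest

from memdkit import (
    BandSummary,
    PsdEstimate,
    PsdParams,
    band_summary,
    channel_mode_mixing,
    estimate_psd,
    filter_low_frequency_imfs,
    imf_count_table,
    mode_alignment,
    mode_mixing_pair,
    normalize_imf,
)
from memdkit._exceptions import DegenerateImfError, UndefinedMetricError


class TestNormalize:
    def test_unit_std(self):
        out = normalize_imf([1.0, -1.0, 1.0, -1.0])
        assert np.isclose(out.std(), 1.0)

    def test_scale_invariance(self):
        x = np.random.default_rng(0).normal(size=100)
        assert np.allclose(normalize_imf(x), normalize_imf(7 * x))

    def test_constant_rejected(self):
        with pytest.raises(DegenerateImfError):
            normalize_imf(np.full(50, 3.0))


class TestPsd:
    def test_tone_peak_at_tone_frequency(self, fs):
        t = np.arange(int(2 * fs)) / fs
        psd = estimate_psd(np.sin(2 * np.pi * 50 * t), fs)
        assert abs(psd.frequencies[np.argmax(psd.density)] - 50.0) <= fs / 1024

    def test_white_noise_roughly_flat(self, fs):
        # average 10 seeds, then compare low/high halves of the band
        acc = None
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=4096)
            psd = estimate_psd(x, fs)
            acc = psd.density if acc is None else acc + psd.density
        f = psd.frequencies
        lo = acc[(f > 10) & (f < 250)].mean()
        hi = acc[(f > 250) & (f < 490)].mean()
        assert max(lo, hi) / min(lo, hi) < 3

    @pytest.mark.parametrize("kind", ["tone", "noise"])
    def test_parseval_within_ten_percent(self, fs, kind):
        t = np.arange(4096) / fs
        x = (
            np.sin(2 * np.pi * 50 * t)
            if kind == "tone"
            else np.random.default_rng(1).normal(size=t.size)
        )
        psd = estimate_psd(x, fs)
        assert abs(psd.total_energy - x.var()) < 0.1 * x.var()


class TestBandSummary:
    def test_flat_density_analytic_edges(self):
        f = np.linspace(0, 100, 1001)
        psd = PsdEstimate(frequencies=f, density=np.ones_like(f))
        b = band_summary(psd)
        assert np.isclose(b.f2, 20.0, atol=0.2)
        assert np.isclose(b.f8, 80.0, atol=0.2)
        assert np.isclose(b.width, 60.0, atol=0.4)
        assert np.isclose(b.central_frequency, 50.0, atol=0.2)

    def test_single_bin_spike(self):
        f = np.linspace(0, 100, 101)
        d = np.zeros_like(f)
        d[40] = 5.0
        b = band_summary(PsdEstimate(frequencies=f, density=d))
        assert abs(b.f2 - 40.0) < 1.0 and abs(b.f8 - 40.0) < 1.0
        assert b.width < 1.0

    def test_quantile_monotonicity(self):
        rng = np.random.default_rng(2)
        f = np.linspace(0, 500, 513)
        d = rng.uniform(0, 1, f.size)
        b = band_summary(PsdEstimate(frequencies=f, density=d))
        assert b.f2 <= b.f8


class TestModeMixing:
    @pytest.mark.parametrize(
        "bi, bj, expected",
        [
            ((10, 30), (40, 60), 0.0),  # disjoint
            ((10, 30), (10, 30), 1.0),  # identical
            ((10, 30), (20, 40), 0.5),  # half overlap over the narrower width
            ((10, 50), (20, 30), 1.0),  # nested band
        ],
    )
    def test_worked_cases(self, bi, bj, expected):
        a = BandSummary(f2=bi[0], f8=bi[1], central_frequency=np.mean(bi))
        b = BandSummary(f2=bj[0], f8=bj[1], central_frequency=np.mean(bj))
        assert mode_mixing_pair(a, b) == pytest.approx(expected)
        assert mode_mixing_pair(b, a) == pytest.approx(expected)

    def test_both_zero_width_is_zero_with_warning(self):
        a = BandSummary(f2=10, f8=10, central_frequency=10)
        with pytest.warns(UserWarning):
            assert mode_mixing_pair(a, a) == 0.0

    def test_channel_aggregate_rules(self):
        bands = [
            BandSummary(10, 30, 20),
            BandSummary(10, 30, 20),
            BandSummary(10, 30, 20),
        ]
        assert channel_mode_mixing(bands, "mean").aggregate == pytest.approx(1.0)
        assert channel_mode_mixing(bands, "sum").aggregate == pytest.approx(2.0)

    def test_disjoint_chain_is_zero(self):
        bands = [BandSummary(10, 20, 15), BandSummary(30, 40, 35), BandSummary(50, 60, 55)]
        assert channel_mode_mixing(bands).aggregate == 0.0

    def test_single_imf_undefined(self):
        with pytest.raises(UndefinedMetricError):
            channel_mode_mixing([BandSummary(10, 20, 15)])


class TestModeAlignment:
    def test_identical_channels_align_perfectly(self, fs):
        t = np.arange(2048) / fs
        stack = np.vstack([np.sin(2 * np.pi * 80 * t), np.sin(2 * np.pi * 20 * t)])
        result = mode_alignment([stack, stack.copy(), stack.copy()], fs)
        assert np.allclose(result.values, 1.0, atol=1e-9)
        assert result.scalar_summary == pytest.approx(1.0, abs=1e-9)

    def test_shared_tone_row_aligns(self, fs):
        rng = np.random.default_rng(5)
        t = np.arange(2048) / fs
        tone = np.sin(2 * np.pi * 120 * t)
        stacks = [
            np.vstack([tone + 0.2 * rng.normal(size=t.size)]) for _ in range(4)
        ]
        result = mode_alignment(stacks, fs)
        assert result.row_means[0] >= 0.9

    def test_independent_noise_aligns_worse_than_shared_mode(self, fs):
        t = np.arange(2048) / fs
        shared_scores, indep_scores = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tone = np.sin(2 * np.pi * 120 * t)
            shared = [
                np.vstack([tone + 0.3 * rng.normal(size=t.size)]) for _ in range(4)
            ]
            # narrowband but independent content per channel
            indep = [
                np.vstack(
                    [np.sin(2 * np.pi * rng.uniform(30, 400) * t + rng.uniform(0, 6))
                     + 0.3 * rng.normal(size=t.size)]
                )
                for _ in range(4)
            ]
            shared_scores.append(mode_alignment(shared, fs).scalar_summary)
            indep_scores.append(mode_alignment(indep, fs).scalar_summary)
        assert np.mean(indep_scores) < np.mean(shared_scores)

    def test_amplitude_scale_invariance(self, fs):
        rng = np.random.default_rng(8)
        stacks = [rng.normal(size=(3, 1024)) for _ in range(3)]
        base = mode_alignment(stacks, fs)
        scaled = mode_alignment([7.5 * s for s in stacks], fs)
        assert np.allclose(base.values, scaled.values, atol=1e-12)


class TestLowFrequencyFilter:
    def _tone_stack(self, freqs, fs, n=4096):
        t = np.arange(n) / fs
        return np.vstack([np.sin(2 * np.pi * f * t) for f in freqs])

    def test_centroid_based_exclusion(self, fs):
        freqs = [250, 90, 30, 8, 2]
        stack = self._tone_stack(freqs, fs)
        retained, remainder = filter_low_frequency_imfs(stack, fs, cutoff=20.0)
        assert retained == [0, 1, 2]
        assert np.allclose(remainder, stack[3] + stack[4])

    def test_zero_cutoff_retains_all(self, fs):
        stack = self._tone_stack([100, 40], fs)
        retained, remainder = filter_low_frequency_imfs(stack, fs, cutoff=0.0)
        assert retained == [0, 1]
        assert np.allclose(remainder, 0.0)

    def test_regrouped_reconstruction(self, fs, surrogate_segment):
        from memdkit import emd

        x = surrogate_segment.samples[:, 0]
        d = emd(x)
        retained, remainder = filter_low_frequency_imfs(d.imfs, fs)
        regroup = d.imfs[retained].sum(axis=0) + remainder + d.residual
        assert np.max(np.abs(regroup - x)) <= 1e-8 * x.std()


class TestImfCountTable:
    def test_mean_and_sample_std(self):
        table = imf_count_table({"EEMD": {"BF": [3, 3, 3], "VM": [2, 4]}})
        assert table.loc["EEMD", "BF"] == "3.00 ± 0.00"
        assert table.loc["EEMD", "VM"] == "3.00 ± 1.41"
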