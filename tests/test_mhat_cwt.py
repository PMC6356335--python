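"""Mexican-hat CWT: closed-form values, quadrature oracle, physics checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from conftest import pure_tone, random_profile
from scaffoldscope import spectral
from scaffoldscope.mhat_cwt import (
    FOURIER_FACTOR_L1,
    FOURIER_FACTOR_L2,
    ScaleRangeError,
    Waveletgram,
    cwt,
    fourier_factor,
    load_waveletgram,
    mhat,
    period_to_scale,
    save_waveletgram,
    scale_to_period,
)


def cwt_quadrature(profile, periods_um, normalization="L1", padding="reflect"):
    """Direct-sum oracle: same definition, no convolution machinery."""
    dx = profile.sampling_um
    f = profile.values
    n = f.size
    p = 1.0 if normalization == "L1" else 0.5
    out = np.empty((len(periods_um), n))
    for i, period in enumerate(periods_um):
        a = period / fourier_factor(normalization)
        k = int(np.ceil(6.0 * a / dx))
        mode = "reflect" if padding == "reflect" else "constant"
        fpad = np.pad(f, k, mode=mode)
        w = np.array([mhat(m * dx / a) for m in range(-k, k + 1)])
        w -= w.mean()  # sampled-wavelet zero-sum, as the transform defines
        for j in range(n):
            acc = 0.0
            for m in range(-k, k + 1):
                acc += fpad[j + k + m] * w[m + k]
            out[i, j] = acc * dx / a**p
    return out


class TestWaveletFunction:
    def test_zeros_at_unit_argument(self):
        assert mhat(1.0) == pytest.approx(0.0, abs=1e-15)
        assert mhat(-1.0) == pytest.approx(0.0, abs=1e-15)

    def test_peak_value_closed_form(self):
        # 2/(sqrt(3)·pi^(1/4)) evaluated independently
        assert mhat(0.0) == pytest.approx(0.86733, abs=5e-6)

    def test_zero_mean_by_quadrature(self):
        integral, _ = quad(mhat, -8, 8)
        assert abs(integral) < 1e-10

    def test_unit_energy(self):
        energy, _ = quad(lambda t: mhat(t) ** 2, -8, 8)
        assert energy == pytest.approx(1.0, abs=1e-10)


class TestScalePeriodMapping:
    def test_l2_factor_value(self):
        assert scale_to_period(1.0) == pytest.approx(3.9738, abs=5e-5)

    @pytest.mark.parametrize("norm", ["L1", "L2"])
    def test_round_trip(self, norm):
        a = 7.3
        assert period_to_scale(scale_to_period(a, norm), norm) == pytest.approx(a)

    @pytest.mark.parametrize("norm,expected", [("L1", FOURIER_FACTOR_L1), ("L2", FOURIER_FACTOR_L2)])
    def test_factor_matches_response_curve_maximum(self, norm, expected):
        """Numerically maximize the tone response over scale and invert.

        Response is the interior coefficient amplitude (max |W| over a
        central window) so edge and partial-cycle effects stay out.
        """
        lam = 50.0
        prof = pure_tone(lam, length_um=2000.0, sampling_um=0.5)
        scales = np.geomspace(8.0, 16.0, 201)
        wg = cwt(prof, scales_um=scales, normalization=norm)
        n = wg.coeffs.shape[1]
        amp = np.abs(wg.coeffs[:, n // 2 - 200: n // 2 + 200]).max(axis=1)
        a_star = scales[np.argmax(amp)]
        assert lam / a_star == pytest.approx(expected, rel=0.01)


class TestCwtAgainstOracle:
    @pytest.mark.parametrize("norm", ["L1", "L2"])
    @pytest.mark.parametrize("padding", ["reflect", "zero"])
    def test_fast_equals_quadrature(self, norm, padding):
        prof = random_profile(256, seed=7)
        periods = np.geomspace(4.0, 64.0, 8)
        fast = cwt(prof, periods_um=periods, normalization=norm, padding=padding).coeffs
        slow = cwt_quadrature(prof, periods, norm, padding)
        scale = np.abs(slow).max()
        assert np.max(np.abs(fast - slow)) / scale < 1e-8

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=24, max_value=96),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        period=st.floats(min_value=3.0, max_value=20.0),
    )
    def test_fast_equals_quadrature_property(self, n, seed, period):
        prof = random_profile(n, seed=seed)
        if period > n:  # scale bound: period ≤ profile length
            period = float(n)
        fast = cwt(prof, periods_um=[period]).coeffs
        slow = cwt_quadrature(prof, [period])
        scale = max(np.abs(slow).max(), 1e-30)
        assert np.max(np.abs(fast - slow)) / scale < 1e-8


class TestCwtPhysics:
    def test_constant_profile_maps_to_zero(self):
        prof = random_profile(128, seed=0)
        const = type(prof)(prof.positions_um, np.full(prof.n, 42.0), prof.sampling_um)
        wg = cwt(const, periods_um=np.geomspace(4, 32, 6))
        assert np.max(np.abs(wg.coeffs)) < 1e-9 * 42.0

    def test_linearity(self):
        f = random_profile(128, seed=1)
        g = random_profile(128, seed=2)
        combo = type(f)(f.positions_um, 2.5 * f.values - 1.5 * g.values, f.sampling_um)
        periods = np.geomspace(4, 32, 6)
        lhs = cwt(combo, periods_um=periods).coeffs
        rhs = 2.5 * cwt(f, periods_um=periods).coeffs - 1.5 * cwt(g, periods_um=periods).coeffs
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_translation_covariance_inside_coi(self):
        lam, dx, n = 40.0, 1.0, 600
        k = 17
        base = pure_tone(lam, length_um=n * dx, sampling_um=dx)
        shifted = pure_tone(lam, length_um=n * dx, sampling_um=dx,
                            phase=-2 * np.pi * k * dx / lam)
        periods = np.geomspace(8, 120, 12)
        wg_a = cwt(base, periods_um=periods)
        wg_b = cwt(shifted, periods_um=periods)
        # profile shifted right by k samples ⇒ coefficient columns shift right.
        # Exact equality holds where the truncated kernel support (±6a) never
        # touches the padding, a stricter region than the e-folding COI.
        pos = wg_a.positions_um
        support = 6.0 * wg_a.scales_um[:, None]
        strict = (pos[None, :] - pos[0] >= support) & (pos[-1] - pos[None, :] >= support)
        inside = strict[:, k:] & strict[:, :-k]
        diff = np.abs(wg_b.coeffs[:, k:] - wg_a.coeffs[:, :-k])[inside]
        assert diff.max() < 1e-9 * np.abs(wg_a.coeffs).max()

    def test_matched_tone_response_position_independent(self):
        lam = 60.0
        prof = pure_tone(lam, length_um=1200.0, sampling_um=1.0)
        wg = cwt(prof, periods_um=[lam])
        inside = np.abs(wg.coeffs[0])[wg.coi_mask[0]]
        # envelope of |cos| oscillates; compare cycle-maxima spread
        per_cycle = np.array_split(inside, max(1, inside.size // 60))
        peaks = np.array([c.max() for c in per_cycle if c.size])
        assert peaks.std() / peaks.mean() < 0.05

    def test_l1_tone_amplitude_scale_independent(self):
        """Unit-tone matched response flat across a decade of periods (L1)."""
        amps = []
        for lam in (20.0, 60.0, 200.0):
            prof = pure_tone(lam, length_um=12 * lam, sampling_um=lam / 40)
            wg = cwt(prof, periods_um=[lam], normalization="L1")
            amps.append(np.abs(wg.coeffs[0])[wg.coi_mask[0]].max())
        amps = np.array(amps)
        assert amps.max() / amps.min() - 1 < 0.02

    def test_coi_shrinks_with_period(self, three_tone_waveletgram):
        counts = three_tone_waveletgram.coi_mask.sum(axis=1)
        assert np.all(np.diff(counts) <= 0)

    @pytest.mark.parametrize("periods,msg", [([1.0], "Nyquist"), ([5000.0], "length")])
    def test_scale_bounds_named_in_error(self, periods, msg):
        prof = random_profile(64, seed=0)
        with pytest.raises(ScaleRangeError, match=msg):
            cwt(prof, periods_um=periods)


class TestCrossCheckPyWavelets:
    def test_row_shapes_match_reference_cwt(self):
        """Independent implementation check against PyWavelets' mexh CWT."""
        pywt = pytest.importorskip("pywt")
        rng = np.random.default_rng(5)
        n, dx = 400, 1.0
        values = np.cumsum(rng.normal(size=n))  # smooth-ish random walk
        values -= np.polyval(np.polyfit(np.arange(n), values, 1), np.arange(n))
        prof = random_profile(n, seed=0)
        prof = type(prof)(prof.positions_um, values, dx)
        scales_samples = np.array([8.0, 16.0, 32.0])
        ours = cwt(prof, scales_um=scales_samples * dx, normalization="L2").coeffs
        theirs, _ = pywt.cwt(values, scales_samples, "mexh")
        for i, a in enumerate(scales_samples):
            lo, hi = int(6 * a), n - int(6 * a)
            r = np.corrcoef(ours[i, lo:hi], theirs[i, lo:hi])[0, 1]
            assert r > 0.99


class TestSerialization:
    def test_npz_round_trip(self, three_tone_waveletgram, tmp_path):
        path = tmp_path / "wg.npz"
        save_waveletgram(three_tone_waveletgram, path)
        back = load_waveletgram(path)
        assert np.array_equal(back.coeffs, three_tone_waveletgram.coeffs)
        assert np.array_equal(back.coi_mask, three_tone_waveletgram.coi_mask)
        assert back.normalization == three_tone_waveletgram.normalization

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dims"):
            Waveletgram(
                periods_um=np.array([4.0, 8.0]),
                positions_um=np.arange(5.0),
                coeffs=np.zeros((3, 5)),
                coi_mask=np.ones((3, 5), dtype=bool),
                normalization="L1",
                sampling_um=1.0,
            )
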