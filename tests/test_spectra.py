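"""2D power spectra and radial averaging against brute-force oracles."""

import numpy as np
import pytest

import memfluct as mf
from memfluct.spectra import parseval_mismatch


def dft_power_oracle(values, box_lengths):
    """O(N^2) direct Fourier sum under the package convention."""
    nx, ny = values.shape
    lx, ly = box_lengths
    area = lx * ly
    v = values - values.mean()
    power = np.zeros((nx, ny))
    for kx in range(nx):
        for ky in range(ny):
            acc = 0.0 + 0.0j
            for ix in range(nx):
                for iy in range(ny):
                    phase = -2j * np.pi * (kx * ix / nx + ky * iy / ny)
                    acc += v[ix, iy] * np.exp(phase)
            acc /= nx * ny
            power[kx, ky] = area * abs(acc) ** 2
    power[0, 0] = 0.0
    return power


class TestPowerSpectrum2D:
    def test_constant_field_has_zero_power(self):
        f = mf.GridField(np.full((8, 8), 3.7), (4.0, 4.0))
        s = mf.power_spectrum_2d(f)
        np.testing.assert_allclose(s.power, 0.0, atol=1e-25)

    def test_single_cosine_concentrates_in_one_mode_pair(self):
        L, nx, a = 16.0, 32, 0.8
        x = np.arange(nx) * (L / nx)
        f = mf.GridField(
            a * np.cos(2 * np.pi * x / L)[:, None] * np.ones((1, nx)), (L, L)
        )
        s = mf.power_spectrum_2d(f)
        expected = np.zeros((nx, nx))
        expected[1, 0] = expected[-1, 0] = L * L * a**2 / 4
        np.testing.assert_allclose(s.power, expected, atol=1e-12)

    def test_matches_direct_fourier_sum_oracle(self):
        gen = np.random.Generator(np.random.PCG64(42))
        values = gen.standard_normal((8, 8))
        f = mf.GridField(values, (4.0, 4.0))
        s = mf.power_spectrum_2d(f)
        oracle = dft_power_oracle(values, (4.0, 4.0))
        np.testing.assert_allclose(s.power, oracle, rtol=1e-10, atol=1e-18)

    def test_nonfinite_field_rejected(self):
        with pytest.raises(mf.ParameterError):
            mf.GridField(np.full((8, 8), np.nan), (4.0, 4.0))

    @pytest.mark.parametrize("shape,box", [((16, 16), (8.0, 8.0)),
                                           ((12, 20), (6.0, 10.0))])
    def test_parseval_identity(self, shape, box):
        gen = np.random.Generator(np.random.PCG64(3))
        f = mf.GridField(gen.standard_normal(shape), box)
        assert parseval_mismatch(f) < 1e-10

    def test_batched_ensemble_path_equals_per_frame_path(self):
        gen = np.random.Generator(np.random.PCG64(9))
        stack = gen.standard_normal((5, 16, 16))
        box = (8.0, 8.0)
        batched = mf.mean_spectrum_2d(stack, box)
        manual = np.mean(
            [mf.power_spectrum_2d(mf.GridField(s, box)).power for s in stack], axis=0
        )
        np.testing.assert_allclose(batched.power, manual, rtol=1e-12, atol=1e-20)
        assert batched.n_frames == 5


class TestRadialAverage:
    def test_isotropic_power_gives_flat_shells(self):
        nx, box = 16, (8.0, 8.0)
        power = np.full((nx, nx), 2.5)
        power[0, 0] = 0.0
        ps = mf.radial_average(mf.Spectrum2D(power, box))
        np.testing.assert_allclose(ps.intensity, 2.5, rtol=1e-12)

    def test_shell_means_match_hand_enumeration_4x4(self):
        box = (4.0, 4.0)
        gen = np.random.Generator(np.random.PCG64(17))
        power = gen.uniform(1.0, 2.0, (4, 4))
        power[0, 0] = 0.0
        dq = 2 * np.pi / 4.0
        ps = mf.radial_average(mf.Spectrum2D(power, box), shell_width=dq)

        # independent enumeration over the 16 modes
        shells: dict[int, list] = {}
        for i in range(4):
            for j in range(4):
                ci, cj = (-i) % 4, (-j) % 4
                if (i, j) == (0, 0) or (i, j) > (ci, cj):
                    continue  # conjugate partner already counted
                nx_i = i if i <= 2 else i - 4
                ny_j = j if j <= 2 else j - 4
                q = dq * np.hypot(nx_i, ny_j)
                if q > np.pi / 1.0 * (1 + 1e-12):  # Nyquist pi/spacing, spacing=1
                    continue
                shells.setdefault(int(q / dq), []).append((q, power[i, j]))
        expected = {
            k: (np.mean([q for q, _ in v]), np.mean([p for _, p in v]), len(v))
            for k, v in sorted(shells.items())
        }
        assert len(ps) == len(expected)
        for (qc, inten, cnt), k in zip(zip(ps.q, ps.intensity, ps.counts), expected):
            eq, ei, ec = expected[k]
            assert qc == pytest.approx(eq, rel=1e-12)
            assert inten == pytest.approx(ei, rel=1e-12)
            assert cnt == ec

    def test_transpose_invariance_square_box(self):
        gen = np.random.Generator(np.random.PCG64(5))
        v = gen.standard_normal((16, 16))
        a = mf.radial_average(mf.power_spectrum_2d(mf.GridField(v, (8.0, 8.0))))
        b = mf.radial_average(mf.power_spectrum_2d(mf.GridField(v.T, (8.0, 8.0))))
        np.testing.assert_allclose(a.q, b.q, rtol=1e-12)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_axis_flip_invariance(self):
        gen = np.random.Generator(np.random.PCG64(6))
        v = gen.standard_normal((16, 16))
        a = mf.radial_average(mf.power_spectrum_2d(mf.GridField(v, (8.0, 8.0))))
        b = mf.radial_average(
            mf.power_spectrum_2d(mf.GridField(v[::-1], (8.0, 8.0)))
        )
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_single_giant_shell_rejected(self):
        gen = np.random.Generator(np.random.PCG64(1))
        s = mf.power_spectrum_2d(mf.GridField(gen.standard_normal((8, 8)), (4.0, 4.0)))
        with pytest.raises(mf.ConfigurationError):
            mf.radial_average(s, shell_width=1e3)


class TestAverageOverFrames:
    def test_repeated_frame_equals_single_frame(self):
        gen = np.random.Generator(np.random.PCG64(8))
        s = mf.power_spectrum_2d(mf.GridField(gen.standard_normal((16, 16)), (8.0, 8.0)))
        single = mf.radial_average(s)
        rep = mf.average_over_frames([s] * 7)
        np.testing.assert_allclose(single.intensity, rep.intensity, rtol=1e-12)
        np.testing.assert_array_equal(rep.counts, 7 * single.counts)
        assert rep.n_frames == 7

    def test_empty_input_rejected(self):
        with pytest.raises(mf.SizeError):
            mf.average_over_frames([])

    def test_synthetic_ensemble_tracks_helfrich_spectrum(self):
        spec = mf.SyntheticSpec(Kc=30.0, box_lengths=(25.0, 25.0),
                                grid_spacing=0.5, n_frames=500, seed=21)
        ps = mf.average_over_frames(
            mf.power_spectrum_2d(f) for f in mf.sample_height_ensemble(spec)
        )
        sel = ps.counts >= 2  # skip count-1 shells where 3/sqrt(1) is vacuous anyway
        theory = 1.0 / (spec.Kc * ps.q[sel] ** 4)
        rel_err = np.abs(ps.intensity[sel] - theory) / theory
        assert np.all(rel_err < 3.0 / np.sqrt(ps.counts[sel]))

    def test_mixed_box_sizes_pool_counts(self):
        gen = np.random.Generator(np.random.PCG64(10))
        s1 = mf.power_spectrum_2d(mf.GridField(gen.standard_normal((16, 16)), (8.0, 8.0)))
        s2 = mf.power_spectrum_2d(mf.GridField(gen.standard_normal((20, 20)), (9.0, 9.0)))
        pooled = mf.average_over_frames([s1, s2], shell_width=0.4)
        c1 = mf.radial_average(s1, shell_width=0.4).counts.sum()
        c2 = mf.radial_average(s2, shell_width=0.4).counts.sum()
        assert pooled.counts.sum() == c1 + c2
        assert pooled.n_frames == 2

    def test_shell_intensity_is_unbiased_over_many_ensembles(self):
        # 100 independent 500-frame ensembles, batched generation
        spec = mf.SyntheticSpec(Kc=20.0, box_lengths=(8.0, 8.0),
                                grid_spacing=0.5, n_frames=500)
        base = mf.RandomStream(31)
        acc = None
        for e in range(100):
            from memfluct.synthetic import _sample_fields

            stack = _sample_fields(spec, base.spawn(e), "height", 500)
            ps = mf.radial_average(mf.mean_spectrum_2d(stack, spec.box_lengths))
            acc = ps.intensity if acc is None else acc + ps.intensity
        mean_intensity = acc / 100
        theory = 1.0 / (spec.Kc * ps.q**4)
        low = ps.q <= ps.q[3]  # the single-ring low-q shells where the fit lives
        assert np.all(np.abs(mean_intensity[low] - theory[low]) / theory[low] < 0.01)
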