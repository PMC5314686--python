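"""Helfrich-Canham elastic fits: exact inversions, parameter recovery,
window rule and error propagation."""

import numpy as np
import pytest

import memfluct as mf


def shell_spectrum(q, intensity, kind="height", counts=None):
    counts = np.ones(len(q), dtype=int) if counts is None else counts
    return mf.PowerSpectrum(q=q, intensity=intensity, counts=counts,
                            n_frames=1, kind=kind)


def height_ensemble_spectra(kc, L, n_frames, seed, spacing=0.5):
    spec = mf.SyntheticSpec(Kc=kc, box_lengths=(L, L), grid_spacing=spacing,
                            n_frames=n_frames, seed=seed)
    return [mf.power_spectrum_2d(f) for f in mf.sample_height_ensemble(spec)]


class TestFitWindowRule:
    @pytest.mark.parametrize("L,expected", [
        (21.0, 0.6),    # small patch (1500-lipid scale)
        (29.9, 0.6),
        (30.0, 0.4),
        (50.0, 0.4),    # medium
        (79.9, 0.4),
        (80.0, 0.2),
        (130.0, 0.2),   # large (55k-lipid scale)
    ])
    def test_patch_size_classes(self, L, expected):
        assert mf.default_fit_window((L, L)) == expected

    def test_uses_longest_edge(self):
        assert mf.default_fit_window((20.0, 90.0)) == 0.2

    def test_bad_box_rejected(self):
        with pytest.raises(mf.ParameterError):
            mf.default_fit_window((0.0, 0.0))


class TestBendingRigidityFit:
    def test_noiseless_inversion_is_exact(self):
        q = np.linspace(0.05, 0.55, 10)
        ps = shell_spectrum(q, 1.0 / (20.0 * q**4))
        fit = mf.fit_bending_rigidity(ps, 0.6)
        assert abs(fit.Kc - 20.0) / 20.0 < 1e-10
        assert fit.n_shells_used == 10

    def test_halving_intensities_doubles_kc_exactly(self):
        q = np.linspace(0.05, 0.55, 8)
        i0 = 1.0 / (20.0 * q**4)
        a = mf.fit_bending_rigidity(shell_spectrum(q, i0), 0.6)
        b = mf.fit_bending_rigidity(shell_spectrum(q, i0 / 2), 0.6)
        assert b.Kc == pytest.approx(2 * a.Kc, rel=1e-14)

    def test_parameter_recovery_synthetic_ensemble(self):
        kc = 25.0
        spectra = height_ensemble_spectra(kc, 40.0, 600, seed=13)
        ps = mf.average_over_frames(spectra)
        fit = mf.fit_bending_rigidity(ps, mf.default_fit_window((40.0, 40.0)))
        block_se, _ = mf.block_error(spectra, 0.4, n_blocks=6)
        combined = np.hypot(fit.Kc_se, block_se)
        assert abs(fit.Kc - kc) < 3 * combined

    def test_tilt_like_contamination_bias_shrinks_with_window(self):
        # additive 1/q^2 tail softens the apparent membrane; narrowing the
        # window walks the estimate monotonically back toward the truth
        q = np.linspace(0.02, 0.7, 60)
        ps = shell_spectrum(q, 1.0 / (20.0 * q**4) + 1.0 / q**2)
        kcs = [mf.fit_bending_rigidity(ps, qm).Kc for qm in (0.6, 0.4, 0.2, 0.1)]
        assert all(k < 20.0 for k in kcs)
        assert np.all(np.diff(kcs) > 0)  # approaches 20 as q_max -> 0

    def test_too_few_shells_rejected(self):
        q = np.array([0.1, 0.3, 0.7, 0.9])
        ps = shell_spectrum(q, 1.0 / (20 * q**4))
        with pytest.raises(mf.InsufficientDataError):
            mf.fit_bending_rigidity(ps, 0.4)

    def test_wrong_kind_rejected(self):
        q = np.linspace(0.1, 0.5, 6)
        ps = shell_spectrum(q, 1.0 / q**4, kind="thickness")
        with pytest.raises(mf.ParameterError):
            mf.fit_bending_rigidity(ps, 0.6)

    def test_rescaled_fit_has_lower_variance_than_raw_unweighted(self):
        # a raw least-squares fit of c/q^4 is dominated by the lowest shell;
        # the q^4-rescaled constant fit spreads the weight evenly
        kc = 25.0
        rescaled, raw = [], []
        for seed in range(25):
            ps = mf.average_over_frames(height_ensemble_spectra(kc, 16.0, 60, seed=100 + seed))
            sel = ps.q < 1.2
            q, i = ps.q[sel], ps.intensity[sel]
            rescaled.append(mf.fit_bending_rigidity(ps, 1.2).Kc)
            c_raw = np.sum(i * q**-4) / np.sum(q**-8.0)
            raw.append(1.0 / c_raw)
        assert np.std(rescaled) < np.std(raw)

    def test_rescaled_and_weighted_fits_agree_noiselessly(self):
        q = np.linspace(0.05, 0.55, 12)
        i = 1.0 / (20.0 * q**4)
        kc_rescaled = mf.fit_bending_rigidity(shell_spectrum(q, i), 0.6).Kc
        kc_raw = 1.0 / (np.sum(i * q**-4) / np.sum(q**-8.0))
        assert kc_rescaled == pytest.approx(kc_raw, rel=1e-12)
        assert kc_rescaled == pytest.approx(20.0, rel=1e-12)


class TestThicknessFit:
    def test_flat_spectrum_noiseless_limit(self):
        q = np.linspace(0.1, 1.5, 12)
        ps = shell_spectrum(q, np.full(12, 1.0 / 26.7), kind="thickness")
        fit = mf.fit_thickness_moduli(ps)
        assert fit.Ke == pytest.approx(26.7, rel=1e-8)
        assert fit.Kd == pytest.approx(0.0, abs=1e-8)

    def test_exact_helfrich_thickness_inverts(self):
        q = np.linspace(0.1, 3.0, 30)
        ps = shell_spectrum(q, 1.0 / (2.4 * q**4 + 26.7), kind="thickness")
        fit = mf.fit_thickness_moduli(ps)
        assert fit.Kd == pytest.approx(2.4, rel=1e-6)
        assert fit.Ke == pytest.approx(26.7, rel=1e-6)

    def test_parameter_recovery_synthetic_ensemble(self):
        spec = mf.SyntheticSpec(Kd=2.4, Ke=26.7, box_lengths=(25.0, 25.0),
                                grid_spacing=0.5, n_frames=600, seed=19)
        spectra = []
        for f in mf.sample_thickness_ensemble(spec):
            centered = mf.GridField(f.values - f.values.mean(), f.box_lengths,
                                    kind="thickness")
            spectra.append(mf.power_spectrum_2d(centered))
        ps = mf.average_over_frames(spectra)
        fit = mf.fit_thickness_moduli(ps)
        assert abs(fit.Kd - 2.4) < 3 * fit.Kd_se
        assert abs(fit.Ke - 26.7) < 3 * fit.Ke_se
        assert not fit.low_q_anomaly

    def test_low_q_rise_flagged_as_non_helfrich(self):
        q = np.linspace(0.1, 1.5, 12)
        i = np.full(12, 1.0 / 26.7)
        i[0] *= 2.0  # spectrum rising again at the lowest q
        ps = shell_spectrum(q, i, kind="thickness",
                            counts=np.full(12, 10_000, dtype=int))
        fit = mf.fit_thickness_moduli(ps)
        assert fit.low_q_anomaly

    def test_too_few_shells_rejected(self):
        q = np.linspace(0.1, 0.4, 4)
        ps = shell_spectrum(q, np.full(4, 0.03), kind="thickness")
        with pytest.raises(mf.InsufficientDataError):
            mf.fit_thickness_moduli(ps)


class TestBlockError:
    def test_identical_frames_give_zero_se(self):
        gen = np.random.Generator(np.random.PCG64(23))
        s = mf.power_spectrum_2d(mf.GridField(gen.standard_normal((32, 32)), (16.0, 16.0)))
        se, kcs = mf.block_error([s] * 10, 1.2, n_blocks=5)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(kcs) == pytest.approx(0.0, abs=1e-12)

    def test_iid_frames_match_analytic_propagation(self):
        spectra = height_ensemble_spectra(25.0, 32.0, 600, seed=29)
        ps = mf.average_over_frames(spectra)
        fit = mf.fit_bending_rigidity(ps, 0.6)
        block_se, _ = mf.block_error(spectra, 0.6, n_blocks=10)
        # Gaussian-mode oracle: shell means have rel var 1/(modes*frames)
        sel = (ps.q > 0) & (ps.q < 0.6)
        y = ps.q[sel] ** 4 * ps.intensity[sel]
        var_c = np.sum(y**2 / ps.counts[sel]) / sel.sum() ** 2
        se_theory = np.sqrt(var_c) / fit.fitted_constant**2
        ratio = block_se / se_theory
        assert 1 / 1.5 < ratio < 1.5

    def test_more_blocks_than_frames_rejected(self):
        gen = np.random.Generator(np.random.PCG64(2))
        s = mf.power_spectrum_2d(mf.GridField(gen.standard_normal((16, 16)), (8.0, 8.0)))
        with pytest.raises(mf.SizeError):
            mf.block_error([s] * 4, 1.2, n_blocks=5)


class TestRecoveryAcrossStiffnesses:
    def test_five_percent_recovery_in_95_percent_of_seeds(self):
        # published-range stiffnesses; 600-frame ensembles on a medium patch
        kcs = [10.2, 16.1, 25.0, 30.9, 49.1]
        ok = 0
        base = mf.RandomStream(4242)
        from memfluct.synthetic import _sample_fields

        trials = 0
        for i, kc in enumerate(kcs):
            spec = mf.SyntheticSpec(Kc=kc, box_lengths=(32.0, 32.0),
                                    grid_spacing=0.5, n_frames=600)
            for s in range(10):
                stack = _sample_fields(spec, base.spawn(1000 * i + s), "height", 600)
                ps = mf.radial_average(mf.mean_spectrum_2d(stack, spec.box_lengths))
                kc_hat = mf.fit_bending_rigidity(ps, 0.4).Kc
                trials += 1
                ok += abs(kc_hat - kc) / kc < 0.05
        assert trials == 50
        assert ok / trials >= 0.95
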