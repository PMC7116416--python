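import math

import numpy as np
import pytest

from shellopt import (Compartment, PhantomConfig, angular_spectrum,
                      detectable_lmax, generate_directions, make_dwi,
                      n_even_sh_coeffs, noise_floor,
                      rotational_power_spectrum, select_single_fibre_voxels,
                      sh_fit)
from shellopt.angular import real_sh_basis


@pytest.fixture(scope="module")
def dirs60():
    return generate_directions(60, seed=1).vectors


class TestCoefficientCounts:
    @pytest.mark.parametrize("lmax, expected", [
        (0, 1), (2, 6), (4, 15), (6, 28), (8, 45),
    ])
    def test_even_order_counts(self, lmax, expected):
        assert n_even_sh_coeffs(lmax) == expected

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError):
            n_even_sh_coeffs(3)


class TestShFit:
    def test_constant_signal_is_pure_l0(self, dirs60):
        c = sh_fit(dirs60, np.ones(60), 4)
        assert c[0] == pytest.approx(math.sqrt(4 * math.pi))
        assert np.abs(c[1:]).max() < 1e-10

    def test_single_basis_function_recovered(self, dirs60):
        basis = real_sh_basis(4, dirs60)
        for j in (2, 7, 11):
            c = sh_fit(dirs60, basis[:, j], 4)
            expected = np.zeros(15)
            expected[j] = 1.0
            assert np.allclose(c, expected, atol=1e-8)

    def test_band_limited_roundtrip(self, dirs60, rng):
        c_true = rng.normal(size=n_even_sh_coeffs(6))
        sig = real_sh_basis(6, dirs60) @ c_true
        c_fit = sh_fit(dirs60, sig, 6)
        assert np.allclose(c_fit, c_true, atol=1e-6)

    def test_underdetermined_rejected(self, dirs60):
        with pytest.raises(ValueError, match="underdetermined"):
            sh_fit(dirs60[:10], np.ones(10), 4)


class TestPowerSpectrum:
    def test_delta_coefficient(self):
        c = np.zeros(n_even_sh_coeffs(4))
        c[3] = 1.7  # an l=2 coefficient
        power = rotational_power_spectrum(c)
        assert power[2] == pytest.approx(1.7**2)
        assert power[0] == 0.0 and power[4] == 0.0

    def test_all_zero(self):
        power = rotational_power_spectrum(np.zeros(6))
        assert all(v == 0.0 for v in power.values())

    def test_rotation_invariance(self, dirs60, rng):
        """Resampling a band-limited signal on rotated directions and
        refitting leaves every per-order power unchanged."""
        c_true = rng.normal(size=n_even_sh_coeffs(4))
        p_ref = rotational_power_spectrum(c_true)
        for _ in range(3):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            rotated = dirs60 @ q.T
            sig = real_sh_basis(4, rotated) @ c_true  # signal at R⁻¹u
            c_rot = sh_fit(dirs60, sig, 4)
            p_rot = rotational_power_spectrum(c_rot)
            for ell in p_ref:
                assert p_rot[ell] == pytest.approx(p_ref[ell], abs=1e-8)


class TestDetectability:
    def _band_limited(self, dirs, lmax, rng, scale=0.3):
        c = np.zeros(n_even_sh_coeffs(lmax))
        c[0] = 3.0
        c[1:] = scale * rng.normal(size=c.size - 1)
        return real_sh_basis(lmax, dirs) @ c

    @pytest.mark.parametrize("lmax_true, expected_dirs", [(2, 6), (4, 15)])
    def test_noiseless_band_limited_signal(self, dirs60, rng, lmax_true,
                                           expected_dirs):
        sig = self._band_limited(dirs60, lmax_true, rng)
        spectrum = angular_spectrum(dirs60, sig, 8, sigma=0.0, seed=0)
        assert spectrum.detectable_lmax == lmax_true
        assert spectrum.min_directions == expected_dirs

    def test_pure_noise_shell_detects_nothing(self, dirs60):
        rng = np.random.default_rng(17)
        values = rng.normal(0.0, 0.2, size=(40, 60))
        spectrum = angular_spectrum(dirs60, values, 8, sigma=0.2, seed=23)
        assert spectrum.detectable_lmax == 0
        assert spectrum.min_directions == 1

    def test_floor_scales_with_sigma(self, dirs60):
        lo = noise_floor(dirs60, 4, sigma=0.1, n_trials=200, seed=5)
        hi = noise_floor(dirs60, 4, sigma=0.2, n_trials=200, seed=5)
        for ell in lo:
            assert hi[ell] == pytest.approx(4.0 * lo[ell], rel=1e-6)

    def test_strong_signal_beats_its_own_noise(self, dirs60, rng):
        sig = self._band_limited(dirs60, 4, rng, scale=0.5)
        noisy = sig[None, :] + np.random.default_rng(3).normal(
            0.0, 0.02, size=(60, 60))
        spectrum = angular_spectrum(dirs60, noisy, 8, sigma=0.02, seed=4)
        assert spectrum.detectable_lmax == 4


class TestGenerateDirections:
    def test_single_direction_zero_energy(self):
        d = generate_directions(1, seed=0)
        assert d.n == 1 and d.energy == 0.0

    def test_three_directions_orthogonal_triad(self):
        """The electrostatic optimum for three antipodal charges is the
        orthogonal triad (verified against random restarts)."""
        best = min((generate_directions(3, seed=s) for s in range(5)),
                   key=lambda d: d.energy)
        dots = np.abs(best.vectors @ best.vectors.T)
        np.fill_diagonal(dots, 0.0)
        worst_angle = math.degrees(math.acos(dots.max()))
        assert worst_angle > 89.0

    def test_energy_non_increasing_over_iterations(self):
        energies = [generate_directions(12, seed=4, max_iter=k).energy
                    for k in (1, 5, 20, 100, 500)]
        assert np.all(np.diff(energies) <= 1e-12)

    def test_deterministic_per_seed(self):
        a = generate_directions(20, seed=9)
        b = generate_directions(20, seed=9)
        assert np.array_equal(a.vectors, b.vectors)

    def test_fifty_directions_well_separated(self):
        d = generate_directions(50, seed=0)
        assert d.min_angle_deg() >= 14.0


class TestSingleFibreSelection:
    def _phantom(self, f_single, f_iso, f_cross, shape=(6, 6, 2)):
        nv = int(np.prod(shape))
        comps = [
            Compartment("fibre", axial=1.9e-3, radial=0.6e-3,
                        orientation=(1, 0, 0),
                        fraction_map=f_single.reshape(shape)),
            Compartment("iso", diffusivity=1.4e-3,
                        fraction_map=f_iso.reshape(shape)),
            Compartment("cross-a", axial=1.9e-3, radial=0.6e-3,
                        orientation=(1, 0, 0),
                        fraction_map=(f_cross / 2).reshape(shape)),
            Compartment("cross-b", axial=1.9e-3, radial=0.6e-3,
                        orientation=(0, 1, 0),
                        fraction_map=(f_cross / 2).reshape(shape)),
        ]
        cfg = PhantomConfig(shape=shape, compartments=comps,
                            bvalues=(0.0, 1000.0, 2500.0),
                            counts=(5, 40, 50), noise=None, sigma=0.0, seed=2)
        return make_dwi(cfg)

    def test_single_tensor_population_fully_retained(self):
        nv = 72
        ds, truth = self._phantom(np.ones(nv), np.zeros(nv), np.zeros(nv))
        sel = select_single_fibre_voxels(ds)
        assert sel.mask.all()

    def test_isotropic_phantom_retains_nothing(self):
        nv = 72
        ds, _ = self._phantom(np.zeros(nv), np.ones(nv), np.zeros(nv))
        with pytest.raises(Exception, match="no single-fibre"):
            select_single_fibre_voxels(ds)

    def test_mixed_phantom_matches_labels(self):
        nv = 72
        f_single = np.zeros(nv)
        f_single[:36] = 1.0
        f_iso = np.zeros(nv)
        f_iso[36:54] = 1.0
        f_cross = np.zeros(nv)
        f_cross[54:] = 1.0
        ds, truth = self._phantom(f_single, f_iso, f_cross)
        sel = select_single_fibre_voxels(ds)
        label_frac = truth["single_fibre"].mean()
        pred_frac = sel.mask.mean()
        assert pred_frac == pytest.approx(label_frac, abs=0.1)

    def test_realigned_profile_peaks_along_z(self):
        """After realignment the mean single-fibre ADC is highest along the
        common +z axis, i.e. the signal is lowest there."""
        nv = 72
        rng = np.random.default_rng(0)
        ds, _ = self._phantom(np.ones(nv), np.zeros(nv), np.zeros(nv))
        sel = select_single_fibre_voxels(ds)
        z_align = np.abs(sel.directions[:, 2])
        near_z = sel.mean_profile[z_align > 0.9].mean()
        near_xy = sel.mean_profile[z_align < 0.3].mean()
        assert near_z < near_xy


class TestDirectionTextIO:
    def test_bvec_and_mrtrix_roundtrip(self, tmp_path, dirs60):
        from shellopt import read_directions, write_directions
        from shellopt.angular import DirectionSet
        ds = DirectionSet(vectors=dirs60[:12], energy=0.0)
        for style in ("bvec", "mrtrix"):
            path = tmp_path / f"dirs.{style}"
            write_directions(ds, path, style=style)
            back = read_directions(path)
            assert np.allclose(back.vectors, ds.vectors, atol=1e-7)


def test_basis_csv_export(tmp_path, rng):
    import json

    import pandas as pd
    from shellopt import decompose
    basis = decompose(rng.uniform(0.1, 2.0, size=(4, 30)),
                      bvalues=(0, 500, 1000, 2000))
    csv, meta = tmp_path / "basis.csv", tmp_path / "basis.json"
    basis.to_csv(csv, metadata_path=meta)
    df = pd.read_csv(csv)
    assert np.allclose(df.filter(like="component_").to_numpy(), basis.H)
    payload = json.loads(meta.read_text())
    assert payload["n_voxels"] == 30
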