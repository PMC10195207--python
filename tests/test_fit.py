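import numpy as np
import pytest

from dbsi import (
    AnisoComponent,
    DBSIParams,
    IsotropicSpectrum,
    compute_fractions,
    dbsi_signal,
    dti_fit,
    fit_map,
    fit_voxel,
)
from dbsi.fit import FitConfig, sphere_candidates, _nnls
from dbsi.synthetic import LesionSpec, PhantomSpec, archetype_params, make_phantom
from tests.conftest import spike_spectrum

Z = np.array([0.0, 0.0, 1.0])


class TestComputeFractions:
    def make_iso(self, grid, placements):
        return IsotropicSpectrum(grid, spike_spectrum(grid, placements))

    def test_three_band_split(self, spectrum_grid):
        iso = self.make_iso(spectrum_grid, {0.5: 0.5, 1.2: 0.3, 2.0: 0.2})
        assert compute_fractions(iso, 0.0) == pytest.approx((0.0, 0.5, 0.3, 0.2))

    def test_band_edges_are_inclusive(self, spectrum_grid):
        # D = 1.0 belongs to restricted, D = 1.5 to hindered
        at_one = self.make_iso(spectrum_grid, {1.0: 1.0})
        assert compute_fractions(at_one, 0.0)[1] == pytest.approx(1.0)
        at_one_five = self.make_iso(spectrum_grid, {1.5: 1.0})
        assert compute_fractions(at_one_five, 0.0)[2] == pytest.approx(1.0)

    def test_renormalizes_with_fiber(self, spectrum_grid):
        iso = self.make_iso(spectrum_grid, {0.5: 1.0})
        f = compute_fractions(iso, 1.0)
        assert f == pytest.approx((0.5, 0.5, 0.0, 0.0))

    def test_zero_total_weight_is_error(self, spectrum_grid):
        iso = IsotropicSpectrum(spectrum_grid, np.zeros(len(spectrum_grid)))
        with pytest.raises(ValueError):
            compute_fractions(iso, 0.0)


class TestFitVoxel:
    def test_pure_isotropic_voxel(self, table, config, spectrum_grid):
        iso = IsotropicSpectrum(spectrum_grid, spike_spectrum(spectrum_grid, {1.2: 1.0}))
        s = dbsi_signal(table, DBSIParams(aniso=(), iso=iso))
        res = fit_voxel(s, table, config)
        assert res.hindered_fraction >= 0.95
        assert res.fiber_fraction <= 0.02

    def test_stick_plus_free_water_mixture(self, table, config, spectrum_grid):
        stick = AnisoComponent(0.5, 1.5, 0.2, Z)
        iso = IsotropicSpectrum(spectrum_grid, spike_spectrum(spectrum_grid, {2.5: 0.5}))
        s = dbsi_signal(table, DBSIParams(aniso=(stick,), iso=iso))
        res = fit_voxel(s, table, config)
        assert res.fiber_fraction == pytest.approx(0.5, abs=0.05)
        assert res.nonrestricted_fraction == pytest.approx(0.5, abs=0.05)

    def test_zero_diffusivity_limit(self, table, config):
        res = fit_voxel(np.ones(len(table)), table, config)
        assert res.restricted_fraction == pytest.approx(1.0, abs=1e-3)

    def test_all_zero_signals_rejected(self, table, config):
        with pytest.raises(ValueError, match="degenerate"):
            fit_voxel(np.zeros(len(table)), table, config)

    def test_fractions_sum_to_one(self, table, config):
        rng = np.random.default_rng(3)
        from dbsi.synthetic import random_voxel_params

        for _ in range(5):
            p = random_voxel_params(rng)
            res = fit_voxel(dbsi_signal(table, p), table, config)
            assert res.fractions.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(res.fractions >= 0) and np.all(res.fractions <= 1)

    def test_stage2_objective_beats_exhaustive_two_component_grid(self, table):
        # oracle: the NNLS solution's residual is no worse than any
        # hand-constructed non-negative weighting of two basis signals
        b = table.bvalues_ms_um2
        A = np.column_stack([np.exp(-b * 0.4), np.exp(-b * 2.0)])
        y = 0.35 * A[:, 0] + 0.4 * A[:, 1] + 0.01 * np.sin(np.arange(len(b)))
        y = np.abs(y)
        x, _ = _nnls(A, y)
        best = np.inf
        for w1 in np.linspace(0, 1, 101):
            for w2 in np.linspace(0, 1, 101):
                best = min(best, np.sum((A @ [w1, w2] - y) ** 2))
        assert np.sum((A @ x - y) ** 2) <= best + 1e-12


class TestFitMap:
    def small_phantom(self, snr=np.inf, seed=0):
        rng = np.random.default_rng(seed)
        return PhantomSpec(
            shape=(4, 4, 2),
            background=archetype_params("white_matter", rng),
            lesions=[LesionSpec(center=(2, 2, 1), radius=1.2, clip=True,
                                params=archetype_params("edema", rng))],
            snr=snr,
            seed=seed,
        )

    def test_noise_free_phantom_round_trip(self, config):
        vol, table, labels, gt = make_phantom(self.small_phantom())
        maps = fit_map(vol, table, np.ones(vol.shape3d, dtype=bool), config)
        err = np.concatenate(
            [
                np.abs(maps.fiber - gt.fiber).ravel(),
                np.abs(maps.restricted - gt.restricted).ravel(),
                np.abs(maps.hindered - gt.hindered).ravel(),
                np.abs(maps.nonrestricted - gt.nonrestricted).ravel(),
            ]
        )
        assert err.mean() < 0.02

    def test_deterministic_and_zero_outside_mask(self, config):
        vol, table, labels, _ = make_phantom(self.small_phantom(snr=30, seed=7))
        mask = np.zeros(vol.shape3d, dtype=bool)
        mask[:2] = True
        m1 = fit_map(vol, table, mask, config)
        m2 = fit_map(vol, table, mask, config)
        for name, arr in m1.as_dict().items():
            np.testing.assert_array_equal(arr, m2.as_dict()[name])
            assert np.all(arr[~mask] == 0)

    def test_empty_mask_is_error(self, config):
        vol, table, *_ = make_phantom(self.small_phantom())
        with pytest.raises(ValueError, match="empty"):
            fit_map(vol, table, np.zeros(vol.shape3d, dtype=bool), config)


def closed_form_fa(lams):
    lams = np.asarray(lams, dtype=float)
    return float(np.sqrt(1.5) * np.linalg.norm(lams - lams.mean()) / np.linalg.norm(lams))


class TestDtiFit:
    def test_isotropic_voxel(self, table):
        b = table.bvalues_ms_um2
        s = np.exp(-b * 1.1)
        adc, fa, lams = dti_fit(s, table)
        assert adc == pytest.approx(1.1, abs=1e-6)
        assert fa == pytest.approx(0.0, abs=1e-6)

    def test_single_tensor_eigenvalue_recovery(self, table):
        # hand-computed oracle: FA(1.7, 0.3, 0.3) = 0.799
        comp = AnisoComponent(1.0, 1.7, 0.3, Z)
        s = dbsi_signal(
            table,
            DBSIParams(aniso=(comp,), iso=IsotropicSpectrum(np.array([1.0]), np.array([0.0]))),
        )
        adc, fa, lams = dti_fit(s, table)
        np.testing.assert_allclose(sorted(lams), [0.3, 0.3, 1.7], atol=1e-4)
        assert fa == pytest.approx(closed_form_fa([1.7, 0.3, 0.3]), abs=1e-4)
        assert fa == pytest.approx(0.799, abs=1e-3)

    def test_adc_invariant_under_rotation(self, table):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [30, 45, 60], degrees=True).as_matrix()
        for axis in (Z, R @ Z):
            comp = AnisoComponent(1.0, 1.7, 0.3, axis / np.linalg.norm(axis))
            s = dbsi_signal(
                table,
                DBSIParams(aniso=(comp,), iso=IsotropicSpectrum(np.array([1.0]), np.array([0.0]))),
            )
            adc, *_ = dti_fit(s, table)
            assert adc == pytest.approx((1.7 + 0.3 + 0.3) / 3, abs=1e-4)

    def test_insufficient_directions_is_error(self):
        from dbsi import GradientTable

        dirs = np.zeros((7, 3))
        dirs[1:] = [0, 0, 1.0]
        t = GradientTable(directions=dirs, bvalues=np.r_[0, np.full(6, 1000.0)])
        with pytest.raises(ValueError, match="directions"):
            dti_fit(np.ones(7), t)


def test_sphere_candidates_are_unit_hemisphere():
    pts = sphere_candidates(60)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.all(pts[:, 2] >= 0)
    # antipodal uniqueness: no two points nearly parallel
    dots = np.abs(pts @ pts.T) - np.eye(60)
    assert dots.max() < 0.999
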