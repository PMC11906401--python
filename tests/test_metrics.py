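"""FSC, threshold resolution, molecular masks and cross-correlation scores."""

import numpy as np
import pytest

from emboost.fixtures import DegradationParams, degrade, random_structure
from emboost.grid import VoxelGrid
from emboost.metrics import (
    FscCurve,
    cc_scores,
    fsc,
    molecular_mask,
    resolution_at,
)
from emboost.simulate import gaussian_params_from_resolution, simulate_map
from emboost.structure import AtomicStructure


def brute_force_fsc(a: np.ndarray, b: np.ndarray, voxel: float = 1.0):
    """Naive oracle: bin Fourier voxels by rounded radial index with loops."""
    n = a.shape[0]
    fa = np.fft.fftn(a.astype(np.float64))
    fb = np.fft.fftn(b.astype(np.float64))
    freqs = np.fft.fftfreq(n, d=voxel)
    ds = 1.0 / (n * voxel)
    cross = {}
    pa = {}
    pb = {}
    for iz in range(n):
        for iy in range(n):
            for ix in range(n):
                s = np.sqrt(freqs[iz] ** 2 + freqs[iy] ** 2 + freqs[ix] ** 2)
                sh = int(round(s / ds))
                cross[sh] = cross.get(sh, 0.0) + (fa[iz, iy, ix] * np.conj(fb[iz, iy, ix])).real
                pa[sh] = pa.get(sh, 0.0) + abs(fa[iz, iy, ix]) ** 2
                pb[sh] = pb.get(sh, 0.0) + abs(fb[iz, iy, ix]) ** 2
    out = {}
    for sh in sorted(cross):
        denom = np.sqrt(pa[sh] * pb[sh])
        out[sh] = cross[sh] / denom if denom > 0 else 0.0
    return out


@pytest.fixture(scope="module")
def fixture_map():
    s = random_structure(120, motif="blob", box=32.0, seed=17)
    params = gaussian_params_from_resolution(4.0)
    template = VoxelGrid(np.zeros((32, 32, 32), dtype=np.float32))
    return simulate_map(s, params, template), s


class TestFsc:
    def test_self_correlation_is_one(self, fixture_map):
        m, _ = fixture_map
        curve = fsc(m, m)
        power = np.abs(np.fft.fftn(m.data.astype(np.float64))) ** 2
        assert (curve.correlations[curve.correlations != 0] == pytest.approx(1.0, abs=1e-9))

    def test_positive_affine_transform_changes_only_dc_shell(self, fixture_map):
        m, _ = fixture_map
        scaled = m.with_data(2.5 * m.data + 0.3)
        curve = fsc(m, scaled)
        assert curve.correlations[1:] == pytest.approx(1.0, abs=1e-6)

    def test_sign_flip_gives_minus_one(self, fixture_map):
        m, _ = fixture_map
        curve = fsc(m, m.with_data(-m.data))
        nonzero = curve.correlations[np.abs(curve.correlations) > 1e-12]
        assert nonzero == pytest.approx(-1.0, abs=1e-9)

    def test_matches_naive_binning_oracle(self):
        rng = np.random.default_rng(3)
        a = VoxelGrid(rng.random((16, 16, 16), dtype=np.float32))
        b = VoxelGrid(rng.random((16, 16, 16), dtype=np.float32))
        curve = fsc(a, b)
        oracle = brute_force_fsc(a.data, b.data)
        for i, c in enumerate(curve.correlations):
            assert c == pytest.approx(np.clip(oracle[i], -1, 1), abs=1e-9), f"shell {i}"

    def test_geometry_mismatch_rejected(self, fixture_map):
        m, _ = fixture_map
        other = VoxelGrid(np.zeros((16, 16, 16), dtype=np.float32))
        with pytest.raises(ValueError):
            fsc(m, other)

    def test_bounded_and_increasing_frequencies(self, fixture_map):
        m, _ = fixture_map
        curve = fsc(m, m)
        assert np.abs(curve.correlations).max() <= 1.0
        assert (np.diff(curve.shell_centers) > 0).all()
        assert curve.shell_centers[-1] <= curve.nyquist + curve.shell_width


class TestResolutionAt:
    def test_never_crossing_reports_nyquist_limit(self):
        curve = FscCurve(np.linspace(0, 0.5, 12), np.ones(12), 0.05, 0.5)
        est = resolution_at(curve, 0.5)
        assert est.limit_reached
        assert est.resolution == pytest.approx(2.0)

    def test_sharp_lowpass_crossing_near_cutoff(self, fixture_map):
        m, _ = fixture_map
        n = m.data.shape[0]
        f = np.fft.fftfreq(n, d=1.0)
        s = np.sqrt(
            f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2
        )
        fc = 0.25  # 1/Å
        # smooth roll-off centred at fc so the crossing is interpolable
        filt = 1.0 / (1.0 + np.exp((s - fc) / 0.02))
        fil = np.fft.ifftn(np.fft.fftn(m.data.astype(np.float64)) * filt).real
        rng = np.random.default_rng(0)
        noisy = fil + rng.normal(0, 0.05 * m.data.max(), fil.shape)
        curve = fsc(m, VoxelGrid(noisy.astype(np.float32)))
        est = resolution_at(curve, 0.5)
        assert not est.limit_reached
        assert est.resolution == pytest.approx(1.0 / fc, rel=0.25)

    def test_interpolates_between_shells(self):
        centers = np.array([0.0, 0.1, 0.2, 0.3])
        corr = np.array([1.0, 1.0, 0.6, 0.4])
        est = resolution_at(FscCurve(centers, corr, 0.1, 0.5), 0.5)
        # crossing between 0.2 and 0.3: f = 0.2 + 0.1·(0.6-0.5)/(0.6-0.4) = 0.25
        assert est.resolution == pytest.approx(4.0)

    def test_monotone_under_blur_ladder(self, fixture_map):
        m, _ = fixture_map
        res = []
        for sigma in (0.0, 1.0, 2.0):
            deg = degrade(m, DegradationParams(blur_sigma=sigma, noise_sigma=0.05, seed=5))
            res.append(resolution_at(fsc(m, deg), 0.5).resolution)
        assert res[0] <= res[1] <= res[2]

    def test_degradation_worsens_cc_box(self, fixture_map):
        m, s = fixture_map
        mask = molecular_mask(s, m, radius=3.0)
        ccs = []
        for noise in (0.0, 0.05, 0.2):
            deg = degrade(m, DegradationParams(blur_sigma=1.0, noise_sigma=noise, seed=6))
            ccs.append(cc_scores(deg, m, mask).cc_box)
        assert ccs[0] >= ccs[1] >= ccs[2]


class TestMolecularMask:
    def test_single_atom_count_matches_lattice_enumeration(self):
        template = VoxelGrid(np.zeros((15, 15, 15), dtype=np.float32))
        s = AtomicStructure(["C"], [6], [[7.0, 7.0, 7.0]], ["A"])
        mask = molecular_mask(s, template, radius=3.0)
        # lattice-point enumeration oracle around the centre voxel
        count = sum(
            1
            for dz in range(-3, 4)
            for dy in range(-3, 4)
            for dx in range(-3, 4)
            if dx * dx + dy * dy + dz * dz <= 9
        )
        assert int(mask.sum()) == count

    def test_radius_monotonicity(self, fixture_map):
        m, s = fixture_map
        small = molecular_mask(s, m, radius=2.0)
        large = molecular_mask(s, m, radius=3.5)
        assert (large | small == large).all()

    def test_mask_of_union_is_union_of_masks(self, fixture_map):
        m, _ = fixture_map
        a = AtomicStructure(["C"], [6], [[8.0, 8.0, 8.0]], ["A"])
        b = AtomicStructure(["O"], [8], [[20.0, 20.0, 20.0]], ["B"])
        both = a.concat(b)
        np.testing.assert_array_equal(
            molecular_mask(both, m, 3.0),
            molecular_mask(a, m, 3.0) | molecular_mask(b, m, 3.0),
        )

    def test_empty_structure_or_bad_radius_rejected(self, fixture_map):
        m, s = fixture_map
        with pytest.raises(ValueError):
            molecular_mask(s, m, radius=0.0)


class TestCcScores:
    def test_self_correlation_is_perfect(self, fixture_map):
        m, s = fixture_map
        mask = molecular_mask(s, m, 3.0)
        rep = cc_scores(m, m, mask)
        assert (rep.cc_box, rep.cc_mask, rep.cc_peaks) == pytest.approx((1.0, 1.0, 1.0))
        assert not rep.degenerate

    def test_invariant_under_positive_affine_transform(self, fixture_map):
        m, s = fixture_map
        mask = molecular_mask(s, m, 3.0)
        other = m.with_data((1.7 * m.data + 0.2).astype(np.float32))
        rep = cc_scores(m, other, mask)
        assert rep.cc_box == pytest.approx(1.0, abs=1e-6)
        assert rep.cc_mask == pytest.approx(1.0, abs=1e-6)

    def test_hand_built_4cube_matches_naive_computation(self):
        """3-voxel mask on a 4³ pair: all three scores against an explicit
        naive computation including the top-N union rule."""
        rng = np.random.default_rng(9)
        exp = rng.random((4, 4, 4)).astype(np.float32)
        mod = rng.random((4, 4, 4)).astype(np.float32)
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = mask[1, 2, 3] = mask[3, 3, 0] = True

        def pearson(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))

        n = 3
        top_exp = set(np.argsort(exp.ravel())[-n:])
        top_mod = set(np.argsort(mod.ravel())[-n:])
        union = sorted(top_exp | top_mod)
        expected = (
            pearson(exp.ravel(), mod.ravel()),
            pearson(exp[mask], mod[mask]),
            pearson(exp.ravel()[union], mod.ravel()[union]),
        )
        rep = cc_scores(VoxelGrid(exp), VoxelGrid(mod), mask)
        assert (rep.cc_box, rep.cc_mask, rep.cc_peaks) == pytest.approx(expected, abs=1e-7)

    def test_cc_peaks_equals_cc_mask_when_topn_sets_coincide(self):
        # construct maps whose top-N voxels are exactly the mask voxels
        exp = np.zeros((4, 4, 4), dtype=np.float32)
        mod = np.zeros((4, 4, 4), dtype=np.float32)
        mask = np.zeros((4, 4, 4), dtype=bool)
        coords = [(0, 0, 0), (1, 1, 1), (2, 2, 2)]
        for i, c in enumerate(coords):
            exp[c] = 5.0 + i
            mod[c] = 7.0 + 2 * i
            mask[c] = True
        rep = cc_scores(VoxelGrid(exp), VoxelGrid(mod), mask)
        assert rep.cc_peaks == pytest.approx(rep.cc_mask, abs=1e-9)

    def test_constant_region_flagged_not_nan(self):
        exp = VoxelGrid(np.ones((4, 4, 4), dtype=np.float32))
        mod = VoxelGrid(np.random.default_rng(0).random((4, 4, 4), dtype=np.float32))
        mask = np.ones((4, 4, 4), dtype=bool)
        rep = cc_scores(exp, mod, mask)
        assert rep.degenerate
        assert np.isfinite([rep.cc_box, rep.cc_mask, rep.cc_peaks]).all()

    def test_empty_mask_rejected(self, fixture_map):
        m, _ = fixture_map
        with pytest.raises(ValueError):
            cc_scores(m, m, np.zeros(m.data.shape, dtype=bool))
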