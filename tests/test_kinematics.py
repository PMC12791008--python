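import numpy as np
import pytest
from scipy import ndimage

from morphaline import synthgen as gen
from morphaline.grids import FieldFrame, GridSpec, VelocityFrame, VelocitySequence
from morphaline.kinematics import (
    DisplacementField,
    autocorr_matrix,
    corr_to_ensemble,
    displacement_field,
    ensemble_average_flow,
    integrate_pathlines,
    piv_estimate,
    segment_modules,
    time_average_flow,
)
from morphaline.similarity import SimilarityMatrix
from tests.conftest import rotation_sequence


def smooth_texture(grid, seed, sigma=1.0):
    rng = np.random.default_rng(seed)
    mode = ("nearest", "wrap") if grid.periodic2 else "nearest"
    return ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma, mode=mode)


class TestPIV:
    def test_integer_translation(self):
        g = GridSpec(64, 64, 1.0, 1.0, periodic2=True, truncation_fraction=0.0)
        tex = smooth_texture(g, 0)
        a = FieldFrame(g, tex, 0.0)
        b = FieldFrame(g, np.roll(tex, (3, 0), axis=(0, 1)), 1.0)
        vf = piv_estimate(a, b, window=8, search=4)
        interior = vf.valid.copy()
        interior[-1] = False  # bottom blocks cannot see the +3-shifted content
        assert np.abs(vf.v1[interior] - 3.0).max() < 1e-9
        assert np.abs(vf.v2[interior]).max() < 1e-9

    def test_identity_zero_field(self):
        g = GridSpec(48, 48, 1.0, 1.0, periodic2=True, truncation_fraction=0.0)
        tex = smooth_texture(g, 1)
        vf = piv_estimate(FieldFrame(g, tex, 0.0), FieldFrame(g, tex, 1.0), window=8)
        assert np.abs(vf.v1[vf.valid]).max() == 0.0
        assert np.abs(vf.v2[vf.valid]).max() == 0.0

    def test_subpixel_half_shift(self):
        from scipy.ndimage import fourier_shift

        g = GridSpec(64, 64, 1.0, 1.0, periodic2=True, truncation_fraction=0.0)
        tex = smooth_texture(g, 2, sigma=2.0)
        shifted = np.real(np.fft.ifft2(fourier_shift(np.fft.fft2(tex), (0.5, 0.0))))
        vf = piv_estimate(FieldFrame(g, tex, 0.0), FieldFrame(g, shifted, 1.0), window=8)
        assert abs(np.nanmedian(vf.v1[vf.valid]) - 0.5) < 0.1

    def test_flat_window_masked(self):
        g = GridSpec(32, 32, 1.0, 1.0, periodic2=True, truncation_fraction=0.0)
        tex = smooth_texture(g, 3)
        tex[:8, :8] = 0.0  # flat block
        vf = piv_estimate(FieldFrame(g, tex, 0.0), FieldFrame(g, tex, 1.0), window=8)
        assert not vf.valid[0, 0]

    def test_window_minimum(self):
        g = GridSpec(64, 64, 1.0, 1.0, periodic2=True, truncation_fraction=0.0)
        a = FieldFrame(g, smooth_texture(g, 4), 0.0)
        with pytest.raises(ValueError):
            piv_estimate(a, FieldFrame(g, a.values, 1.0), window=4)


class TestPathlines:
    def test_constant_field_exact(self, small_grid):
        g = small_grid
        frames = [
            VelocityFrame(g, np.full(g.shape, 1.2), np.zeros(g.shape), float(k)) for k in range(11)
        ]
        seq = VelocitySequence(frames, 1.0)
        p = integrate_pathlines(seq, 0.0, 10.0, 0.2, seeds=np.array([[2.0, 8.0]]))
        d = displacement_field(p)
        assert d.delta[0] == pytest.approx(12.0, abs=1e-12)

    def test_zero_field_stationary(self, small_grid):
        g = small_grid
        frames = [VelocityFrame(g, np.zeros(g.shape), np.zeros(g.shape), float(k)) for k in range(6)]
        p = integrate_pathlines(VelocitySequence(frames, 1.0), 0.0, 5.0, 0.5)
        assert np.all(p.positions[:, -1] == p.positions[:, 0])

    def test_rotation_closed_form(self):
        g = GridSpec(41, 41, 1.0, 1.0, periodic2=False, truncation_fraction=0.0)
        seq = rotation_sequence(g, 0.1, 11)
        seeds = np.array([[20.0, 25.0], [15.0, 20.0], [24.0, 16.0]])
        p = integrate_pathlines(seq, 0.0, 10.0, 0.2, seeds=seeds)
        d = displacement_field(p)
        r = np.linalg.norm(seeds - 20.0, axis=1)
        chord = 2.0 * r * np.sin(0.1 * 10.0 / 2.0)
        assert d.delta == pytest.approx(chord, rel=1e-3)

    def test_rk4_convergence_halving(self):
        g = GridSpec(41, 41, 1.0, 1.0, periodic2=False, truncation_fraction=0.0)
        seq = rotation_sequence(g, 0.1, 11)
        seeds = np.array([[20.0, 26.0]])
        d1 = displacement_field(integrate_pathlines(seq, 0.0, 10.0, 0.2, seeds=seeds)).delta[0]
        d2 = displacement_field(integrate_pathlines(seq, 0.0, 10.0, 0.1, seeds=seeds)).delta[0]
        assert abs(d1 - d2) / d2 < 1e-4

    def test_escaped_seed_frozen_and_flagged(self, small_grid):
        g = small_grid
        frames = [
            VelocityFrame(g, np.full(g.shape, 5.0), np.zeros(g.shape), float(k)) for k in range(6)
        ]
        p = integrate_pathlines(
            VelocitySequence(frames, 1.0), 0.0, 5.0, 0.5, seeds=np.array([[13.0, 8.0]])
        )
        assert p.escaped[0]
        assert p.positions[0, -1, 0] <= (g.n1 - 1) * g.spacing1

    def test_bad_window(self, small_grid):
        g = small_grid
        frames = [VelocityFrame(g, np.zeros(g.shape), np.zeros(g.shape), float(k)) for k in range(3)]
        with pytest.raises(ValueError):
            integrate_pathlines(VelocitySequence(frames, 1.0), 2.0, 1.0)


class TestDisplacementField:
    def test_pythagorean(self):
        pos = np.zeros((1, 2, 2))
        pos[0, 1] = [3.0, 4.0]
        from morphaline.kinematics import PathlineSet

        p = PathlineSet(np.zeros((1, 2)), pos, 0.0, 1.0, 1.0, np.zeros(1, dtype=bool))
        assert displacement_field(p).delta[0] == pytest.approx(5.0)

    def test_full_circle_near_zero_displacement(self):
        # closed orbit: chord ~ 0 although path length ~ 2*pi*R
        g = GridSpec(81, 81, 1.0, 1.0, periodic2=False, truncation_fraction=0.0)
        omega = 2.0 * np.pi / 50.0
        seq = rotation_sequence(g, omega, 51)
        seeds = np.array([[40.0, 48.0]])
        p = integrate_pathlines(seq, 0.0, 50.0, 0.2, seeds=seeds)
        d = displacement_field(p)
        assert d.delta[0] < 0.05  # R = 8, path length ~ 50

    def test_nonnegative_invariant(self):
        with pytest.raises(ValueError):
            DisplacementField(np.array([-1.0]), np.array([True]))


class TestAutocorrAndModules:
    def test_stationary_flow_all_ones(self):
        spec = gen.DEFAULT_GRID
        mods = [gen.ModuleSpec("extension_quadrupole", 0.0, 10.0)]
        flow = gen.make_modular_flow(spec, mods, 1.0, 10, 0.0, 0)
        m = autocorr_matrix(flow, "vorticity")
        assert np.allclose(m.values, 1.0, atol=1e-9)

    def test_sign_flip_blocks(self):
        spec = gen.DEFAULT_GRID
        mods = [
            gen.ModuleSpec("extension_quadrupole", 0.0, 5.0, envelope=1.0),
            gen.ModuleSpec("extension_quadrupole", 5.0, 10.0, envelope=-1.0),
        ]
        flow = gen.make_modular_flow(spec, mods, 1.0, 10, 0.0, 0)
        m = autocorr_matrix(flow, "vorticity")
        assert np.allclose(m.values[:5, :5], 1.0, atol=1e-9)
        assert np.allclose(m.values[5:, :5], -1.0, atol=1e-9)

    def test_two_phase_off_block_matches_direct_value(self):
        from morphaline.similarity import corr_vorticity

        spec = gen.DEFAULT_GRID
        mods = [
            gen.ModuleSpec("furrow_convergence", 0.0, 4.0),
            gen.ModuleSpec("extension_quadrupole", 4.0, 8.0),
        ]
        flow = gen.make_modular_flow(spec, mods, 1.0, 8, 0.0, 0)
        m = autocorr_matrix(flow, "vorticity")
        direct = corr_vorticity(flow[0], flow[5])
        assert np.allclose(m.values[:4, 4:], direct, atol=1e-9)

    def test_symmetric_unit_diagonal(self):
        spec = gen.DEFAULT_GRID
        mods = [gen.ModuleSpec("extension_quadrupole", 0.0, 8.0, envelope=lambda t: 1.0 + 0.1 * t)]
        flow = gen.make_modular_flow(spec, mods, 1.0, 8, 0.01, 3)
        m = autocorr_matrix(flow, "vorticity")
        assert np.allclose(m.values, m.values.T, atol=1e-12)
        assert np.allclose(np.diag(m.values), 1.0, atol=1e-9)

    def test_perfect_two_block_segmentation(self):
        v = np.zeros((12, 12))
        v[:6, :6] = 1.0
        v[6:, 6:] = 1.0
        seg = segment_modules(SimilarityMatrix(v, np.arange(12.0), np.arange(12.0)), 0.6, 3)
        assert len(seg.modules) == 2
        assert seg.modules[0][:2] == (0.0, 6.0)
        assert seg.modules[1][:2] == (6.0, 12.0)

    def test_all_ones_single_module(self):
        v = np.ones((10, 10))
        seg = segment_modules(SimilarityMatrix(v, np.arange(10.0), np.arange(10.0)), 0.6, 3)
        assert len(seg.modules) == 1
        assert seg.modules[0][:2] == (0.0, 10.0)

    def test_noisy_three_module_recovery(self):
        bounds = [(0, 18), (22, 40), (44, 60)]
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = np.zeros((60, 60))
            for s, e in bounds:
                v[s:e, s:e] = 0.9
            noise = 0.2 * rng.standard_normal((60, 60))
            v = np.clip(v + (noise + noise.T) / np.sqrt(2.0), -1, 1)
            np.fill_diagonal(v, 1.0)
            seg = segment_modules(SimilarityMatrix(v, np.arange(60.0), np.arange(60.0)), 0.6, 3)
            assert len(seg.modules) == 3
            for (t0, t1, _, _), (s, e) in zip(seg.modules, bounds):
                assert abs(t0 - s) <= 2 and abs(t1 - e) <= 2

    def test_segmentation_scale_invariance(self):
        # magnitude-invariant measure -> same matrix -> same segmentation
        spec = gen.DEFAULT_GRID
        mods = [
            gen.ModuleSpec("furrow_convergence", 0.0, 8.0),
            gen.ModuleSpec("extension_quadrupole", 10.0, 20.0),
        ]
        f1 = gen.make_modular_flow(spec, mods, 1.0, 20, 0.0, 0)
        mods2 = [
            gen.ModuleSpec("furrow_convergence", 0.0, 8.0, envelope=2.0),
            gen.ModuleSpec("extension_quadrupole", 10.0, 20.0, envelope=2.0),
        ]
        f2 = gen.make_modular_flow(spec, mods2, 1.0, 20, 0.0, 0)
        s1 = segment_modules(autocorr_matrix(f1, "vorticity"))
        s2 = segment_modules(autocorr_matrix(f2, "vorticity"))
        assert [m[:2] for m in s1.modules] == [m[:2] for m in s2.modules]


class TestFlowAveraging:
    def _stationary(self, n=6, seed=0, noise=0.0):
        spec = GridSpec(16, 24, 1.0, 1.0, periodic2=True, truncation_fraction=0.0)
        mods = [gen.ModuleSpec("extension_quadrupole", 0.0, float(n))]
        return gen.make_modular_flow(spec, mods, 1.0, n, noise, seed)

    def test_stationary_time_average_equals_frames(self):
        seq = self._stationary()
        avg = time_average_flow(seq)
        assert np.allclose(avg.v1, seq[0].v1) and np.allclose(avg.v2, seq[0].v2)
        trace = corr_to_ensemble(avg, seq, "vorticity")
        assert np.allclose(trace.values, 1.0, atol=1e-9)

    def test_identical_members_mean_is_member(self):
        seq = self._stationary()
        ens = ensemble_average_flow([seq, seq, seq])
        assert np.allclose(ens[2].v1, seq[2].v1)

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            ensemble_average_flow([self._stationary()])

    def test_noise_averaging_keeps_high_correlation(self):
        members = [self._stationary(seed=k, noise=0.2) for k in range(8)]
        ens = ensemble_average_flow(members)
        trace = corr_to_ensemble(members[0], ens, "vorticity")
        assert np.nanmean(trace.values) >= 0.9
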