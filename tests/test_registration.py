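"""Registration: similarity metrics, pair/sequence estimation, composition."""

import numpy as np
import pytest
from scipy import ndimage

from cinestrain.bspline import BSplineGrid
from cinestrain.core import ValidationError
from cinestrain.phantom import PhantomSpec, generate_sax_phantom
from cinestrain.registration import (
    RegistrationParams,
    compose_to_reference,
    register_pair,
    register_sequence,
    similarity_cost,
    temporal_roughness,
)
from cinestrain.tracking import propagate_with_transforms


class TestSimilarity:
    def test_identical_frames_zero(self, rng):
        img = rng.normal(size=(32, 32))
        assert similarity_cost(img, img) == 0.0
        assert similarity_cost(img, img, "NCC") == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_closed_form(self, rng):
        img = rng.normal(size=(32, 32))
        c = 0.37
        assert similarity_cost(img, img + c) == pytest.approx(c**2)

    def test_matches_direct_loop(self, rng):
        a = rng.normal(size=(16, 16))
        b = rng.normal(size=(16, 16))
        direct = sum(
            (b[i, j] - a[i, j]) ** 2 for i in range(16) for j in range(16)
        ) / 256.0
        assert similarity_cost(a, b) == pytest.approx(direct, rel=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValidationError):
            similarity_cost(rng.normal(size=(8, 8)), rng.normal(size=(8, 9)))


class TestRegisterPair:
    def test_identity_recovery(self, small_sax, fast_params):
        spec, seq, _ = small_sax
        res = register_pair(seq.frames[0], seq.frames[0], seq.pixel_spacing, fast_params)
        ys, xs = seq.pixel_coords_mm()
        field = res.grid.dense_field(ys, xs)
        assert np.abs(field).max() / spec.pixel_spacing < 0.05

    def test_known_translation_recovery(self, fast_params, rng):
        """A 3.2 mm synthetic shift is recovered to < 0.1 px in the interior."""
        base = ndimage.gaussian_filter(rng.normal(size=(96, 96)), 3.0)
        base /= base.std()
        shift_px = (0.0, -2.0)  # (rows, cols): 3.2 mm along x
        moved = ndimage.shift(base, shift_px, order=3, mode="nearest")
        res = register_pair(base, moved, (1.6, 1.6), fast_params)
        ys = (np.arange(96) - 47.5) * 1.6
        inner = slice(24, 72)
        field = res.grid.dense_field(ys, ys)
        # content moved 2 px left, so fixed-frame positions map 2 px left
        mean_dx = field[0][inner, inner].mean() / 1.6
        mean_dy = field[1][inner, inner].mean() / 1.6
        assert abs(mean_dx - (-2.0)) < 0.1
        assert abs(mean_dy) < 0.1

    def test_phantom_pair_endpoint_error(self, small_sax, fast_params):
        """Consecutive phantom frames: mean myocardial endpoint error < 0.5 px."""
        spec, seq, gt = small_sax
        res = register_pair(seq.frames[0], seq.frames[1], seq.pixel_spacing, fast_params)
        ys, xs = seq.pixel_coords_mm()
        X, Y = np.meshgrid(xs, ys)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        R = np.hypot(pts[:, 0], pts[:, 1])
        myo = (R >= spec.endo_radius_ed) & (R <= spec.epi_radius_ed)
        est = res.grid.evaluate(pts[myo])
        true = gt.material_map(pts[myo], 1) - pts[myo]
        epe = np.linalg.norm(est - true, axis=1).mean()
        assert epe / spec.pixel_spacing < 0.5

    def test_deterministic(self, small_sax, fast_params):
        spec, seq, _ = small_sax
        r1 = register_pair(seq.frames[0], seq.frames[1], seq.pixel_spacing, fast_params)
        r2 = register_pair(seq.frames[0], seq.frames[1], seq.pixel_spacing, fast_params)
        assert np.array_equal(r1.grid.coeffs, r2.grid.coeffs)

    def test_cost_trace_non_increasing(self, small_sax, fast_params):
        spec, seq, _ = small_sax
        res = register_pair(seq.frames[0], seq.frames[2], seq.pixel_spacing, fast_params)
        trace = np.asarray(res.cost_trace)
        # traces are per-level; within the final (full-resolution) level the
        # accepted L-BFGS iterates never increase the total cost
        assert len(trace) > 0
        assert res.final_cost <= res.identity_cost + 1e-15

    def test_never_worse_than_identity(self, rng, fast_params):
        """Pure-noise frames: the returned transform can't cost more than
        the identity initialisation."""
        a = rng.normal(size=(48, 48))
        b = rng.normal(size=(48, 48))
        res = register_pair(a, b, (1.6, 1.6), fast_params)
        assert res.final_cost <= res.identity_cost + 1e-15


class TestRegisterSequence:
    def test_static_sequence_identity(self, fast_params):
        spec = PhantomSpec(
            grid_size=64, n_frames=4, es_frame=2,
            endo_radius_es=25.0, epi_radius_es=35.0, noise_sd=0.0,
        )
        seq, _ = generate_sax_phantom(spec)
        results = register_sequence(seq, fast_params)
        ys, xs = seq.pixel_coords_mm()
        for r in results:
            assert np.abs(r.grid.dense_field(ys, xs)).max() / spec.pixel_spacing < 0.05

    def test_coherent_roughness_not_larger(self, small_sax):
        _, seq, _ = small_sax
        p_seq = RegistrationParams(pyramid_levels=2, max_iterations=40)
        p_coh = RegistrationParams(
            pyramid_levels=2, max_iterations=40, temporal_mode="coherent"
        )
        rough_s = temporal_roughness([r.grid for r in register_sequence(seq, p_seq)])
        rough_c = temporal_roughness([r.grid for r in register_sequence(seq, p_coh)])
        assert rough_c <= rough_s

    def test_coherent_helps_on_heavy_noise(self):
        """Averaged over 5 seeds, coherent tracking of a heavily noisy
        phantom is at least as accurate as sequential tracking."""
        errs = {"sequential": [], "coherent": []}
        for seed in range(5):
            spec = PhantomSpec(grid_size=64, n_frames=5, es_frame=2,
                               noise_sd=0.15, seed=100 + seed)
            seq, gt = generate_sax_phantom(spec)
            truth = gt.material_map(gt.ed_endo.points, spec.es_frame)
            for mode in errs:
                p = RegistrationParams(pyramid_levels=2, max_iterations=40,
                                       temporal_mode=mode)
                grids = [r.grid for r in register_sequence(seq, p)]
                moved = propagate_with_transforms(gt.ed_endo, grids, spec.es_frame)
                errs[mode].append(
                    np.linalg.norm(moved.points - truth, axis=1).mean()
                )
        assert np.mean(errs["coherent"]) <= np.mean(errs["sequential"])


class TestCompose:
    def translation_grid(self, dx, dy, shape=(64, 64), spacing=(1.6, 1.6)):
        ny, nx = shape
        sy, sx = spacing
        half_y, half_x = (ny - 1) / 2 * sy, (nx - 1) / 2 * sx
        g = BSplineGrid.for_domain(
            (-half_x - 30, half_x + 30), (-half_y - 30, half_y + 30), (12.8, 12.8)
        )
        g.coeffs[0] = dx
        g.coeffs[1] = dy
        return g

    def test_t0_is_zero_field(self):
        g = self.translation_grid(2.0, 1.0)
        fld = compose_to_reference([g], 0, (64, 64), (1.6, 1.6))
        assert np.all(fld.disp == 0.0)

    def test_identity_transforms_compose_to_zero(self):
        gs = [self.translation_grid(0.0, 0.0) for _ in range(3)]
        for t in range(4):
            fld = compose_to_reference(gs, t, (64, 64), (1.6, 1.6))
            assert np.abs(fld.disp).max() < 1e-12

    def test_translations_add(self):
        a = self.translation_grid(2.0, -1.0)
        b = self.translation_grid(-0.5, 3.0)
        fld = compose_to_reference([a, b], 2, (64, 64), (1.6, 1.6))
        assert np.abs(fld.disp[0] - 1.5).max() < 1e-6
        assert np.abs(fld.disp[1] - 2.0).max() < 1e-6

    def test_out_of_range_frame(self):
        g = self.translation_grid(1.0, 0.0)
        with pytest.raises(ValidationError):
            compose_to_reference([g], 5, (64, 64), (1.6, 1.6))


def test_invalid_params():
    with pytest.raises(ValidationError):
        RegistrationParams(similarity="MI")
    with pytest.raises(ValidationError):
        RegistrationParams(regularization_weight=-1.0)
    with pytest.raises(ValidationError):
        RegistrationParams(pyramid_levels=0)
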