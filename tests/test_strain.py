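"""Strain computation: AHA sectors, Ecc/Err/Ell, rates, end-systole."""

import numpy as np
import pandas as pd
import pytest

from cinestrain.core import ValidationError
from cinestrain.strain import (
    StrainCurves,
    build_segment_model,
    circumferential_strain,
    detect_end_systole,
    lax_segment_labels,
    longitudinal_strain,
    radial_strain,
    strain_rate,
    summarize,
)
from cinestrain.tracking import Contour, midwall_contour, pair_endo_epi


def circle(radius, n=120, centre=(0.0, 0.0), role="midwall"):
    ang = np.arange(n) / n * 2 * np.pi
    pts = np.array(centre) + radius * np.column_stack([np.cos(ang), np.sin(ang)])
    return Contour(pts, closed=True, role=role)


def transform_stack(c, fns):
    """Apply point transforms to build a per-frame contour stack."""
    return [
        Contour(fn(c.points.copy()), c.closed, c.role, view=c.view, frame=t)
        for t, fn in enumerate(fns)
    ]


def open_arc(n=60, radius=30.0):
    ang = np.linspace(-2.0, 2.0, n)
    pts = radius * np.column_stack([np.sin(ang), np.cos(ang)])
    return Contour(pts, closed=False, role="midwall", view="LAX")


class TestSegmentModel:
    def test_six_equal_sectors_cover_circle(self):
        m = build_segment_model("mid", 0.0)
        widths = [b[1] - b[0] for b in m.sector_bounds]
        assert np.allclose(widths, np.pi / 3)
        assert len(m.labels) == 6
        assert m.sector_bounds[-1][1] - m.sector_bounds[0][0] == pytest.approx(2 * np.pi)

    def test_apical_four_sectors(self):
        m = build_segment_model("apical", 0.0)
        widths = [b[1] - b[0] for b in m.sector_bounds]
        assert np.allclose(widths, np.pi / 2)
        assert m.labels == ["anterior", "septal", "inferior", "lateral"]

    def test_axis_rotation_equivariance(self):
        delta = 0.7
        m0 = build_segment_model("basal", 0.0)
        m1 = build_segment_model("basal", delta)
        for (a0, b0, _), (a1, b1, _) in zip(m0.sector_bounds, m1.sector_bounds):
            assert a1 - a0 == pytest.approx(delta)
            assert b1 - b0 == pytest.approx(delta)
        ang = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        assert np.array_equal(m0.assign(ang), m1.assign(ang + delta))


class TestCircumferential:
    def test_identity_motion_zero(self):
        model = build_segment_model("mid")
        stack = transform_stack(circle(25.0), [lambda p: p] * 4)
        curves = circumferential_strain(stack, model)
        assert np.all(curves.values.to_numpy() == 0.0)

    def test_uniform_scaling_exact(self):
        model = build_segment_model("mid")
        stack = transform_stack(circle(25.0), [lambda p: p, lambda p: 0.9 * p])
        curves = circumferential_strain(stack, model)
        assert np.allclose(curves.values.iloc[1].to_numpy(), -10.0, atol=1e-9)

    def test_rigid_motion_invariance(self):
        model = build_segment_model("mid")
        th = 0.6
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        stack = transform_stack(circle(25.0), [lambda p: p, lambda p: p @ R.T + [3.0, -2.0]])
        curves = circumferential_strain(stack, model)
        assert np.abs(curves.values.iloc[1].to_numpy()).max() < 0.1


class TestRadial:
    def make_annulus_stack(self, r_endo, r_epi):
        frames_endo, frames_epi = [], []
        for t, (rn, rp) in enumerate(zip(r_endo, r_epi)):
            frames_endo.append(Contour(circle(rn).points, True, "endo", frame=t))
            frames_epi.append(Contour(circle(rp).points, True, "epi", frame=t))
        return frames_endo, frames_epi

    def test_identity_zero(self):
        endo, epi = self.make_annulus_stack([25, 25], [35, 35])
        model = build_segment_model("mid")
        curves = radial_strain(endo, epi, model)
        assert np.allclose(curves.values.to_numpy(), 0.0, atol=1e-9)

    def test_reference_thickening(self):
        """Wall 10 mm -> 13 mm gives +30% in every segment."""
        endo, epi = self.make_annulus_stack([25, 20], [35, 33])
        model = build_segment_model("mid")
        curves = radial_strain(endo, epi, model)
        assert np.allclose(curves.values.iloc[1].to_numpy(), 30.0, atol=1e-6)

    def test_uniform_scaling_exact(self):
        endo0, epi0 = circle(25.0, role="endo"), circle(35.0, role="epi")
        endo = transform_stack(endo0, [lambda p: p, lambda p: 0.9 * p])
        epi = transform_stack(epi0, [lambda p: p, lambda p: 0.9 * p])
        model = build_segment_model("mid")
        curves = radial_strain(endo, epi, model)
        assert np.allclose(curves.values.iloc[1].to_numpy(), -10.0, atol=1e-9)


class TestLongitudinal:
    def test_identity_zero(self):
        stack = transform_stack(open_arc(), [lambda p: p] * 3)
        curves = longitudinal_strain(stack)
        assert np.all(curves.values.to_numpy() == 0.0)

    def test_uniform_scaling_exact_every_segment(self):
        stack = transform_stack(open_arc(), [lambda p: p, lambda p: 0.85 * p])
        curves = longitudinal_strain(stack)
        assert np.allclose(curves.values.iloc[1].to_numpy(), -15.0, atol=1e-9)
        assert list(curves.values.columns) == lax_segment_labels()

    def test_short_contour_rejected(self):
        ang = np.linspace(-2, 2, 17)
        pts = 30 * np.column_stack([np.sin(ang), np.cos(ang)])
        c = Contour(pts, closed=False, role="midwall", view="LAX")
        with pytest.raises(ValidationError):
            longitudinal_strain([c, c])


class TestStrainRate:
    def make_curves(self, values, times):
        df = pd.DataFrame(np.asarray(values, dtype=float), columns=["anterior"])
        return StrainCurves("Ecc_SAX", df, np.asarray(times, dtype=float))

    def test_constant_zero(self):
        c = self.make_curves([0, 0, 0, 0], [0.0, 0.1, 0.2, 0.3])
        assert np.all(strain_rate(c).to_numpy() == 0.0)

    def test_linear_exact_interior(self):
        t = np.array([0.0, 0.1, 0.2, 0.3])
        c = self.make_curves(-40.0 * t, t)  # a = -40 %/s, zero at frame 0
        rate = strain_rate(c).to_numpy()[:, 0]
        assert np.allclose(rate, -40.0, atol=1e-9)

    def test_half_sine_matches_analytic_derivative(self):
        """Contraction-phase Ecc ~ half-sine: central differences track
        the analytic rate within 5% at interior frames."""
        n, es = 40, 39
        t = np.arange(n) * 0.02
        ecc = -15.0 * np.sin(0.5 * np.pi * np.arange(n) / es)
        c = self.make_curves(ecc, t)
        rate = strain_rate(c).to_numpy()[1:-1, 0]
        analytic = (
            -15.0 * 0.5 * np.pi / (es * 0.02)
            * np.cos(0.5 * np.pi * np.arange(n) / es)[1:-1]
        )
        assert np.abs(rate - analytic).max() < 0.05 * np.abs(analytic).max()

    def test_non_monotone_times_rejected(self):
        c = self.make_curves([0, 1, 2], [0.0, 0.2, 0.1])
        c.frame_times = np.array([0.0, 0.2, 0.1])
        with pytest.raises(ValidationError):
            strain_rate(c)


class TestEndSystole:
    def curve_with_min(self, at, n=30):
        v = np.zeros((n, 1))
        v[:, 0] = -10 * np.exp(-0.5 * ((np.arange(n) - at) / 4.0) ** 2)
        v[0, 0] = 0.0
        return StrainCurves("Ecc_SAX", pd.DataFrame(v, columns=["anterior"]), np.arange(n))

    def test_minimum_at_construction_peak(self):
        assert detect_end_systole([self.curve_with_min(10)]) == 10

    def test_monotone_decreasing_returns_last(self):
        v = -np.linspace(0, 20, 30)[:, None]
        c = StrainCurves("Ecc_SAX", pd.DataFrame(v, columns=["a"]), np.arange(30))
        assert detect_end_systole([c]) == 29

    def test_tie_breaks_to_earliest_of_mean_curve(self):
        a, b = self.curve_with_min(9), self.curve_with_min(11)
        es = detect_end_systole([a, b])
        mean = 0.5 * (a.values.to_numpy() + b.values.to_numpy())[:, 0]
        assert es == int(np.argmin(mean))

    def test_override_wins(self):
        assert detect_end_systole([self.curve_with_min(10)], es_override=7) == 7


class TestSummarize:
    def test_global_is_mean_of_segments(self):
        v = np.zeros((3, 2))
        v[2] = [-10.0, -20.0]
        c = StrainCurves("Ecc_SAX", pd.DataFrame(v, columns=["a", "b"]), np.arange(3))
        s = summarize(c, 2)
        assert s.es_global == pytest.approx(-15.0)

    def test_missing_segments_excluded(self):
        v = np.zeros((3, 3))
        v[2] = [-10.0, -20.0, np.nan]
        v[:, 2] = np.nan
        c = StrainCurves("Ecc_SAX", pd.DataFrame(v, columns=["a", "b", "c"]), np.arange(3))
        s = summarize(c, 2)
        assert s.es_global == pytest.approx(-15.0)
        assert c.missing_segments == ["c"]

    def test_global_equals_segment_mean_exactly(self, rng):
        v = np.vstack([np.zeros(6), rng.normal(-15, 3, size=(4, 6))])
        c = StrainCurves(
            "Ecc_SAX", pd.DataFrame(v, columns=list("abcdef")), np.arange(5)
        )
        s = summarize(c, 3)
        assert abs(s.es_global - v[3].mean()) < 1e-12
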