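import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from endplate.errors import DegenerateSectionError, ParameterError
from endplate.morphometry import find_margin_points, measure_profile, smoothed
from endplate.profiles import Profile
from endplate.synthetic import SyntheticEndplateSpec, generate_profile


def test_semicircle_exact_geometry(semicircle):
    m = measure_profile(semicircle)
    assert m.chord_length == pytest.approx(10.0, abs=1e-9)
    assert m.concavity_depth == pytest.approx(5.0, abs=1e-9)
    assert m.length_end1 == pytest.approx(math.sqrt(50), abs=1e-9)
    assert m.length_end2 == pytest.approx(math.sqrt(50), abs=1e-9)
    assert m.ratio == pytest.approx(1.0, abs=1e-9)


def test_parabola_closed_form(parabola):
    m = measure_profile(parabola)
    assert m.chord_length == pytest.approx(20.0, abs=1e-12)
    assert m.concavity_depth == pytest.approx(2.0, abs=1e-12)
    assert m.apex == pytest.approx((0.0, -2.0), abs=1e-12)
    assert m.ratio == pytest.approx(1.0, abs=1e-12)


def test_margin_points_semicircle(semicircle):
    (s1, h1), (s2, h2) = find_margin_points(semicircle)
    assert (s1, h1) == pytest.approx((-5.0, 0.0), abs=1e-9)
    assert (s2, h2) == pytest.approx((5.0, 0.0), abs=1e-9)


def test_margin_point_prefers_raised_lip():
    s = np.linspace(-10, 10, 201)
    h = -2 * (1 - (s / 10) ** 2)
    h[2] = 0.5  # raised posterior lip inside the margin window
    prof = Profile(s, h, plane="sagittal")
    (s1, h1), _ = find_margin_points(prof)
    assert h1 == pytest.approx(0.5)
    assert s1 == pytest.approx(s[2])


def test_margin_window_overlap_rejected(parabola):
    with pytest.raises(ParameterError):
        find_margin_points(parabola, margin_fraction=0.5)


def test_uniform_profile_margins_at_endpoints():
    spec = SyntheticEndplateSpec(depth_sagittal=2.0)
    prof = generate_profile(spec, "sagittal")
    (s1, h1), (s2, h2) = find_margin_points(prof)
    assert s1 == pytest.approx(prof.s[0])
    assert s2 == pytest.approx(prof.s[-1])
    assert h1 == h2 == pytest.approx(0.0, abs=1e-12)


def test_asymmetric_profile_metrics():
    """Apex at 35% of the chord: depth exact, ratio >= 1.3."""
    # offset 0.15 of chord => apex 35% from the anterior end
    spec = SyntheticEndplateSpec(shape_class_sagittal="asymmetric_concave",
                                 apex_offset_sagittal=0.15,
                                 depth_sagittal=1.5, resolution=401)
    m = measure_profile(generate_profile(spec, "sagittal"))
    assert m.concavity_depth == pytest.approx(1.5, abs=0.01)
    assert m.ratio >= 1.3


@given(angle=st.floats(-0.25, 0.25), dx=st.floats(-50, 50),
       dy=st.floats(-50, 50))
def test_rigid_motion_invariance(angle, dx, dy):
    """In-plane rotation + translation changes no metric beyond 1e-9."""
    th = np.linspace(np.pi, 2 * np.pi, 181)
    s, h = 5 * np.cos(th), 5 * np.sin(th)
    base = measure_profile(Profile(s, h, plane="sagittal"))
    c, sn = np.cos(angle), np.sin(angle)
    s2 = c * s - sn * h + dx
    h2 = sn * s + c * h + dy
    order = np.argsort(s2)
    moved = measure_profile(Profile(s2[order], h2[order], plane="sagittal"))
    for attr in ("chord_length", "concavity_depth", "length_end1",
                 "length_end2", "ratio", "plateau_fraction"):
        assert getattr(moved, attr) == pytest.approx(
            getattr(base, attr), rel=1e-9, abs=1e-9)


def test_depth_monotone_in_generator_depth():
    depths = np.linspace(1.0, 4.0, 13)
    measured = []
    for d in depths:
        spec = SyntheticEndplateSpec(depth_sagittal=d)
        measured.append(
            measure_profile(generate_profile(spec, "sagittal")).concavity_depth)
    assert (np.diff(measured) >= -1e-12).all()


def test_symmetric_profile_equal_lengths():
    spec = SyntheticEndplateSpec(depth_sagittal=2.5, resolution=129)
    prof = generate_profile(spec, "sagittal")
    m = measure_profile(prof)
    grid = prof.s[1] - prof.s[0]
    assert abs(m.length_end1 - m.length_end2) <= grid


@given(st.integers(0, 2**31 - 1))
def test_depth_equals_brute_force_point_to_chord_distance(seed):
    """Oracle equivalence: depth == max over points of the exact
    point-to-chord-line distance, computed independently."""
    rng = np.random.default_rng(seed)
    s = np.sort(rng.uniform(-20, 20, size=40))
    s += np.arange(40) * 1e-6  # ensure strictly increasing
    h = rng.uniform(-3, 1, size=40)
    prof = Profile(s, h, plane="sagittal")
    m = measure_profile(prof)
    (x1, y1), (x2, y2) = m.margin_points
    best = 0.0
    for sx, hx in zip(s, h):
        if not (min(x1, x2) <= sx <= max(x1, x2)):
            continue
        num = (x2 - x1) * (y1 - hx) - (x1 - sx) * (y2 - y1)
        dist = num / math.hypot(x2 - x1, y2 - y1)
        if dist > best:
            best = dist
    assert m.concavity_depth == pytest.approx(best, abs=1e-12)


def test_convex_profile_reports_zero_depth():
    s = np.linspace(-5, 5, 101)
    prof = Profile(s, 1 - (s / 5) ** 2, plane="sagittal")  # dome
    m = measure_profile(prof)
    assert m.concavity_depth == 0.0
    assert m.ratio == 1.0
    assert m.plateau_fraction == 0.0


def test_plateau_fraction_tracks_generator():
    spec = SyntheticEndplateSpec(shape_class_sagittal="flat_bottom",
                                 depth_sagittal=2.0, plateau_fraction=0.4,
                                 resolution=257)
    m = measure_profile(generate_profile(spec, "sagittal"))
    # clipped raised cosine: floor at >= 0.9 max depth spans ~0.44 chord
    assert 0.35 <= m.plateau_fraction <= 0.52


def test_too_few_points_between_margins():
    # margin maxima sit on interior points, leaving only 2 points between
    with pytest.raises(DegenerateSectionError):
        measure_profile(Profile([0, 1, 2, 3], [-1, 0, 0, -1],
                                plane="sagittal"),
                        margin_fraction=0.45)


def test_smoothing_window_validation(parabola):
    with pytest.raises(ParameterError):
        smoothed(parabola, 4)
    assert smoothed(parabola, 1) is parabola


def test_smoothing_reduces_noise_bias():
    """The 5-point pre-filter removes most of the max-statistic depth bias
    on a noisy flat plate."""
    spec = SyntheticEndplateSpec(shape_class_sagittal="flat",
                                 depth_sagittal=0.3, noise_sd=0.1, seed=11)
    prof = generate_profile(spec, "sagittal")
    raw = measure_profile(prof).concavity_depth
    filt = measure_profile(prof, smooth_window=5).concavity_depth
    assert filt < raw
    assert filt == pytest.approx(0.3, abs=0.25)
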