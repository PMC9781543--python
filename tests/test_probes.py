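import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

import histostereo as hs
from histostereo import (
    ProbeError,
    SamplingDesign,
    ShrinkageModel,
    UndefinedCEError,
    cavalieri_volume,
    count_in_frame,
    gundersen_ce,
    intersect_fiber_sphere,
    optical_fractionator,
    place_srs_grid,
    point_count_section,
    run_probe,
    spaceballs_length,
    sphere_zone_area,
)

IC_DESIGN = SamplingDesign()  # every 30th 50 µm section, 2000² grid, 150² frame


# ---------------------------------------------------------------------------
# SRS site placement
# ---------------------------------------------------------------------------

def test_srs_expected_site_count_matches_area_ratio():
    """4000×2000 µm rectangle on a 2000×2000 grid: E[sites] → area ratio 2
    as the frame shrinks to a point."""
    rect = box(0, 0, 4000, 2000)
    counts = [
        len(place_srs_grid(rect, (2000.0, 2000.0), seed=s, frame_um=(1.0, 1.0)))
        for s in range(1000)
    ]
    assert np.mean(counts) == pytest.approx(2.0, rel=0.05)


def test_srs_determinism_and_degenerate_polygon():
    rect = box(0, 0, 900, 900)
    a = place_srs_grid(rect, (500.0, 500.0), seed=3)
    b = place_srs_grid(rect, (500.0, 500.0), seed=3)
    np.testing.assert_array_equal(a, b)
    degenerate = Polygon([(0, 0), (1, 0), (0, 0)])
    assert len(place_srs_grid(degenerate, (500.0, 500.0), seed=0)) == 0


def test_srs_small_polygon_site_bound():
    tiny = box(100, 100, 150, 150)  # smaller than one grid cell
    ns = [
        len(place_srs_grid(tiny, (2000.0, 2000.0), seed=s, frame_um=(150.0, 150.0)))
        for s in range(200)
    ]
    # the sparse frame can miss a tiny polygon entirely; at most the 4
    # neighbouring translates can reach it
    assert all(0 <= n <= 4 for n in ns)
    assert any(n >= 1 for n in ns)


# ---------------------------------------------------------------------------
# counting frame
# ---------------------------------------------------------------------------

def test_frame_half_open_boundaries():
    frame = ((0.0, 0.0), (100.0, 100.0))
    z = (1.0, 19.0)
    # half-open: inclusion edges at the origin, exclusion edges opposite —
    # every point belongs to exactly one frame of a tiling
    assert count_in_frame(np.array([[0.0, 50.0, 10.0]]), *frame, z) == 1
    assert count_in_frame(np.array([[100.0, 50.0, 10.0]]), *frame, z) == 0
    assert count_in_frame(np.array([[50.0, 100.0, 10.0]]), *frame, z) == 0
    # center of frame, inside disector
    assert count_in_frame(np.array([[50.0, 50.0, 10.0]]), *frame, z) == 1
    # guard zones excluded
    assert count_in_frame(np.array([[50.0, 50.0, 0.5]]), *frame, z) == 0
    assert count_in_frame(np.array([[50.0, 50.0, 19.0]]), *frame, z) == 0


def test_frame_tiling_census_identity():
    """Tiling a section with frames recovers the exact point count."""
    rng = np.random.default_rng(17)
    pts = np.column_stack(
        [rng.uniform(0, 1000, 10_000), rng.uniform(0, 1000, 10_000), rng.uniform(0, 20, 10_000)]
    )
    total = 0
    for i in range(10):
        for j in range(10):
            total += count_in_frame(pts, (i * 100.0, j * 100.0), (100.0, 100.0), (0.0, 20.0))
    assert total == 10_000


# ---------------------------------------------------------------------------
# Cavalieri
# ---------------------------------------------------------------------------

def test_point_count_expectation_square():
    """2×2 mm square, 1000 µm spacing: E[P] = 4."""
    sq = box(0, 0, 2000, 2000)
    counts = [point_count_section(sq, 1000.0, seed=s) for s in range(1000)]
    assert np.mean(counts) == pytest.approx(4.0, rel=0.05)


def test_point_count_fine_grid_matches_shoelace_area():
    poly = Polygon([(0, 0), (3200, 400), (2800, 2600), (900, 3100), (-300, 1500)])
    spacing = 3500.0 / 100.0
    counts = [point_count_section(poly, spacing, seed=s) for s in range(30)]
    est_area = np.mean(counts) * spacing**2
    assert est_area == pytest.approx(poly.area, rel=5e-3)


def test_point_count_degenerate():
    assert point_count_section(None, 100.0, seed=0) == 0
    assert point_count_section(Polygon(), 100.0, seed=0) == 0


def test_cavalieri_printed_volume_arithmetic():
    """d=1500 µm, a_p=4×10⁶ µm², ΣP=227 → 1362 mm³ (the LIC Cavalieri volume)."""
    counts = [227]
    est = cavalieri_volume(counts, 1500.0, 4e6)
    assert est.value == pytest.approx(1.362e12)
    assert est.value / 1e9 == pytest.approx(1362.0)
    est2 = cavalieri_volume([1], 1000.0, 1e6)
    assert est2.value / 1e9 == pytest.approx(1.0)


def test_cavalieri_zero_and_empty():
    est = cavalieri_volume([0, 0, 0], 1000.0, 1e6)
    assert est.value == 0.0 and not est.ce_defined
    with pytest.raises(ProbeError):
        cavalieri_volume([], 1000.0, 1e6)


def test_cavalieri_consistency_with_prism_volume(sphere_region):
    """k=1 and fine point spacing reproduce the stack's prism volume to 0.5%."""
    stack = hs.section_stack(None, 50.0, ShrinkageModel.identity(), region=sphere_region)
    design = SamplingDesign(
        section_period=1, cavalieri_spacing_um=2000.0 / 100.0, mounted_thickness_um=50.0,
        disector_height_um=48.0,
    )
    counts = run_probe(stack, design, probe_kind="cavalieri", seed=4)
    est = cavalieri_volume(counts.tallies, 50.0, design.cavalieri_spacing_um**2)
    prism = 50.0 * sum(
        stack.section_polygon(i).area
        for i in range(stack.n_sections)
        if stack.section_polygon(i) is not None
    )
    assert est.value == pytest.approx(prism, rel=5e-3)


# ---------------------------------------------------------------------------
# Gundersen–Jensen CE
# ---------------------------------------------------------------------------

def test_ce_hand_arithmetic_flat_counts():
    # A=400, B=300, C=200 → Var = (1200-1200+200)/240
    expect = math.sqrt(200.0 / 240.0) / 40.0
    assert gundersen_ce([10, 10, 10, 10], smoothness_m=1) == pytest.approx(expect, abs=1e-12)
    assert expect == pytest.approx(0.0228, abs=5e-5)


def test_ce_single_section_closed_form():
    # one section: CE = sqrt(3/240) independent of the count
    for n in (1, 10, 1000):
        assert gundersen_ce([n], smoothness_m=1) == pytest.approx(math.sqrt(3.0 / 240.0))
    assert gundersen_ce([7], smoothness_m=1) == pytest.approx(0.1118, abs=5e-5)


def test_ce_with_nugget():
    # A-ν=360 → Var_SRS = (1080-1200+200)/240 = 1/3; + ν = 40
    expect = math.sqrt(80.0 / 240.0 + 40.0) / 40.0
    assert gundersen_ce([10, 10, 10, 10], smoothness_m=1, nugget=True) == pytest.approx(expect)
    assert expect == pytest.approx(0.1588, abs=5e-5)


def test_ce_m0_divisor_and_errors():
    c = [5, 8, 3]
    a = gundersen_ce(c, smoothness_m=0)
    b = gundersen_ce(c, smoothness_m=1)
    assert a == pytest.approx(b * math.sqrt(240.0 / 12.0))
    with pytest.raises(UndefinedCEError):
        gundersen_ce([0, 0, 0])
    with pytest.raises(UndefinedCEError):
        gundersen_ce([])


# ---------------------------------------------------------------------------
# optical fractionator
# ---------------------------------------------------------------------------

def test_fractionator_identity_fractions():
    design = SamplingDesign(
        section_period=1, grid_um=(100.0, 100.0), frame_um=(100.0, 100.0),
        mounted_thickness_um=20.0, disector_height_um=20.0, guard_um=0.0,
    )
    est = optical_fractionator([3, 4, 5], design)
    assert est.value == pytest.approx(12.0)


def test_fractionator_printed_scale_arithmetic():
    """IC design scale factor 30 × (2000²/150²) × (20/18) applied to ΣQ=818
    lands on the printed ~4.85 million CN total."""
    scale = 30.0 * (2000.0**2 / 150.0**2) * (20.0 / 18.0)
    est = optical_fractionator([818], IC_DESIGN)
    assert est.value == pytest.approx(818 * scale, rel=1e-12)
    assert est.value == pytest.approx(4.85e6, rel=1e-3)


def test_fractionator_zero_counts_flagged():
    est = optical_fractionator([0, 0], IC_DESIGN)
    assert est.value == 0.0 and not est.ce_defined


def test_estimate_reproducible_from_components(small_design):
    for est in (
        optical_fractionator([5, 9, 2], small_design),
        cavalieri_volume([10, 12, 8], 1500.0, 4e6),
        spaceballs_length([4, 6], IC_DESIGN, n_sites=20, reference_volume_um3=1e9),
    ):
        assert est.value_from_components() == pytest.approx(est.value, rel=1e-12)


def test_design_invariants_enforced():
    with pytest.raises(ProbeError):
        SamplingDesign(disector_height_um=19.5, guard_um=1.0, mounted_thickness_um=20.0)
    with pytest.raises(ProbeError):
        SamplingDesign(frame_um=(3000.0, 150.0))
    with pytest.raises(ProbeError):
        SamplingDesign(section_period=0)


# ---------------------------------------------------------------------------
# census identity and unbiasedness via run_probe
# ---------------------------------------------------------------------------

def _census_design(t: float) -> SamplingDesign:
    return SamplingDesign(
        section_period=1, grid_um=(5000.0, 5000.0), frame_um=(5000.0, 5000.0),
        cut_thickness_um=t, mounted_thickness_um=t, disector_height_um=t, guard_um=0.0,
    )


def test_census_identity_counts_every_item(sphere_region):
    """All sampling fractions 1 → the probe is an exhaustive census."""
    pts = hs.simulate_neuron_field(sphere_region, 20000.0, {"none": 1.0}, seed=8)
    stack = hs.section_stack(pts, 50.0, ShrinkageModel.identity(), region=sphere_region)
    counts = run_probe(stack, _census_design(50.0), probe_kind="fractionator", seed=0)
    est = optical_fractionator(counts, _census_design(50.0))
    assert counts.total == len(pts)
    assert est.value == pytest.approx(len(pts))


def test_fractionator_unbiasedness(small_ellipsoid, small_design):
    """Mean estimate over 200 seeds within ~1% of λV (SE-scaled bound)."""
    dens = 10000.0
    truth = dens * small_ellipsoid.true_volume_mm3
    shr = ShrinkageModel(xy_linear_factor=1.0, z_collapse_factor=0.4)
    vals = []
    for s in range(200):
        pts = hs.simulate_neuron_field(small_ellipsoid, dens, {"none": 1.0}, seed=s)
        stack = hs.section_stack(pts, 50.0, shr, region=small_ellipsoid)
        counts = run_probe(stack, small_design, probe_kind="fractionator", seed=10_000 + s)
        vals.append(optical_fractionator(counts, small_design).value)
    mean = np.mean(vals)
    sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(mean - truth) < max(0.01 * truth, 3.5 * sem)


def test_run_probe_empty_stack_and_determinism(sphere_region):
    pts = hs.simulate_neuron_field(sphere_region, 3000.0, {"none": 1.0}, seed=1)
    stack = hs.section_stack(pts, 50.0, ShrinkageModel(1.0, 0.4, 0.0), region=sphere_region)
    a = run_probe(stack, SamplingDesign(section_period=3, grid_um=(500.0, 500.0)), seed=5)
    b = run_probe(stack, SamplingDesign(section_period=3, grid_um=(500.0, 500.0)), seed=5)
    np.testing.assert_array_equal(a.tallies, b.tallies)
    with pytest.raises(ProbeError):
        run_probe(
            hs.section_stack(None, 50.0, z_range_um=(0.0, 0.0)),
            SamplingDesign(),
            probe_kind="fractionator",
        )


# ---------------------------------------------------------------------------
# Spaceballs
# ---------------------------------------------------------------------------

def test_sphere_zone_area_closed_forms():
    assert sphere_zone_area(18.0, 18.0) == pytest.approx(2.0 * np.pi * 18.0 * 18.0)
    assert sphere_zone_area(18.0, 18.0) == pytest.approx(2035.75, abs=0.01)
    # slab taller than the sphere → full sphere area
    assert sphere_zone_area(10.0, 50.0) == pytest.approx(4.0 * np.pi * 100.0)


def test_spaceballs_closed_form_density():
    """One site, I=2, r=h=18 → Lv = 4/2035.75 µm⁻² = 1.965 m/mm³."""
    est = spaceballs_length([2], IC_DESIGN, n_sites=1)
    assert est.value == pytest.approx(4.0 / 2035.75, rel=1e-4)
    assert est.value * 1e3 == pytest.approx(1.965, abs=1e-3)


def test_spaceballs_expected_intersections_identity():
    """E[I] per site = Lv·S/2 ≈ 1.72 at the printed CN length density."""
    lv_um2 = 1.69e-3
    S = sphere_zone_area(18.0, 18.0)
    expected_I = lv_um2 * S / 2.0
    assert expected_I == pytest.approx(1.72, abs=0.01)
    # and the estimator inverts the identity exactly
    est = spaceballs_length([100], IC_DESIGN, n_sites=int(round(100 / expected_I)))
    assert est.value == pytest.approx(lv_um2, rel=0.01)


def test_spaceballs_errors():
    with pytest.raises(ProbeError):
        spaceballs_length([1], IC_DESIGN, n_sites=0)
    with pytest.raises(ProbeError):
        spaceballs_length([1], IC_DESIGN, n_sites=5, reference_volume_um3=-1.0)


# ---------------------------------------------------------------------------
# fiber–sphere intersection kernel
# ---------------------------------------------------------------------------

def test_chord_through_center_counts_two():
    seg = np.array([-50.0, 0.0, 10.0, 50.0, 0.0, 10.0])
    assert intersect_fiber_sphere(seg, (0.0, 0.0, 10.0), 18.0, slab_um=(-50.0, 50.0)) == 2


def test_segment_inside_sphere_counts_zero():
    seg = np.array([-5.0, 0.0, 10.0, 5.0, 0.0, 10.0])
    assert intersect_fiber_sphere(seg, (0.0, 0.0, 10.0), 18.0, slab_um=(-50.0, 50.0)) == 0


def _crossings_bruteforce(seg, center, r, slab, n_steps=4001):
    """Sign-change scan along the segment with bisection refinement."""
    a, b = seg[:3], seg[3:]
    t = np.linspace(0.0, 1.0, n_steps)
    p = a[None, :] + t[:, None] * (b - a)[None, :]
    f = np.linalg.norm(p - center, axis=1) - r
    crossings = 0
    for i in np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]:
        lo, hi = t[i], t[i + 1]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            fm = np.linalg.norm(a + mid * (b - a) - center) - r
            if np.sign(fm) == np.sign(f[i]):
                lo = mid
            else:
                hi = mid
        z = a[2] + 0.5 * (lo + hi) * (b[2] - a[2])
        if slab[0] <= z <= slab[1]:
            crossings += 1
    return crossings


def test_intersection_kernel_against_bruteforce_oracle():
    rng = np.random.default_rng(23)
    center = np.array([0.0, 0.0, 10.0])
    r, slab = 18.0, (1.0, 19.0)
    mismatches = 0
    for _ in range(2000):
        mid = rng.uniform(-30, 30, 3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        L = rng.uniform(5.0, 80.0)
        seg = np.concatenate([mid - 0.5 * L * u, mid + 0.5 * L * u])
        fast = intersect_fiber_sphere(seg, center, r, slab_um=slab)
        slow = _crossings_bruteforce(seg, center, r, slab)
        mismatches += fast != slow
    assert mismatches == 0


def test_spaceballs_unbiasedness_isotropic(sphere_region):
    """Isotropic field: mean recovered Lv within ~2% over many seeds."""
    lv = 3.0  # m/mm³
    design = SamplingDesign(
        section_period=3, grid_um=(300.0, 300.0), frame_um=(150.0, 150.0),
        cut_thickness_um=50.0, mounted_thickness_um=20.0,
    )
    vals = []
    for s in range(50):
        segs = hs.simulate_fiber_field(sphere_region, lv, mean_segment_length_um=250.0, seed=s)
        stack = hs.section_stack(segs, 50.0, ShrinkageModel.identity(), region=sphere_region)
        counts = run_probe(stack, design, probe_kind="spaceballs", seed=30_000 + s)
        vals.append(spaceballs_length(counts, design).value * 1e3)
    mean = np.mean(vals)
    sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(mean - lv) < max(0.02 * lv, 3.5 * sem)


def test_spaceballs_axis_aligned_fibers_are_biased(sphere_region):
    """Fully z-aligned fibers under the slab-truncated sphere: documented
    negative bias well beyond 5% (the zone misses near-axial crossings)."""
    lv = 3.0
    lv_um2 = lv / 1e3
    L = 250.0
    rng = np.random.default_rng(77)
    dilated = hs.make_region("dil", {"ellipsoid": {"semi_axes_um": [1250.0] * 3}})
    n = int(lv_um2 / L * dilated.true_volume_um3)
    mid = dilated.sample_uniform(n, rng)
    u = np.tile([0.0, 0.0, 1.0], (n, 1))
    from histostereo.synthetic import clip_segments_to_ellipsoid

    segs = clip_segments_to_ellipsoid(
        mid - 0.5 * L * u, mid + 0.5 * L * u, sphere_region.geometry
    )
    design = SamplingDesign(section_period=3, grid_um=(300.0, 300.0))
    stack = hs.section_stack(segs, 50.0, ShrinkageModel.identity(), region=sphere_region)
    counts = run_probe(stack, design, probe_kind="spaceballs", seed=5)
    est_lv = spaceballs_length(counts, design).value * 1e3
    assert est_lv < 0.9 * lv  # bias exists and exceeds 5%
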