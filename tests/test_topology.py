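import numpy as np
import pytest

from prmtopo.classify import BinaryClassMap
from prmtopo.io_geometry import LungMask
from prmtopo.synthetic import (
    FieldSpec,
    bernoulli_field,
    clustered_field,
    expected_random_curves,
)
from prmtopo.topology import (
    MinkowskiRecord,
    TopologyMaps,
    WindowSpec,
    alpha_descriptor,
    display_map,
    global_alpha,
    global_minkowski,
    local_minkowski_maps,
    summarize_subject,
    surface_density,
)

SP = (1.0, 1.0, 1.0)


def _full_mask(shape):
    return LungMask(np.ones(shape, dtype=bool), SP)


def _map(values):
    return BinaryClassMap(values, SP, label="fsad")


# ---------------------------------------------------------------------------
# WindowSpec validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("edge, stride, cov", [
    (2, 1, 0.5),    # even edge
    (1, 1, 0.5),    # too small
    (21, 0, 0.5),   # stride below 1
    (21, 22, 0.5),  # stride above edge
    (21, 5, 0.0),   # zero coverage
])
def test_window_spec_rejects_invalid(edge, stride, cov):
    with pytest.raises(ValueError):
        WindowSpec(edge, stride, cov)


# ---------------------------------------------------------------------------
# global measures
# ---------------------------------------------------------------------------

def test_global_solid_class_fills_mask():
    shape = (24, 24, 24)
    mask = _full_mask(shape)
    rec = global_minkowski(_map(np.ones(shape, dtype=bool)), mask)
    assert rec.v_density == 1.0
    assert rec.s_density == 0.0          # no internal interface
    assert rec.V == pytest.approx(24**3)
    assert rec.chi == 1


def test_global_empty_map_all_zero():
    rec = global_minkowski(_map(np.zeros((8, 8, 8), dtype=bool)), _full_mask((8, 8, 8)))
    assert rec.V == rec.S == rec.B == rec.chi == 0
    assert rec.v_density == rec.s_density == 0.0


def test_global_empty_mask_rejected():
    mask = LungMask(np.zeros((4, 4, 4), dtype=bool), SP)
    with pytest.raises(ValueError, match="empty mask"):
        global_minkowski(_map(np.ones((4, 4, 4), dtype=bool)), mask)


def test_geometry_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        global_minkowski(_map(np.ones((4, 4, 4), dtype=bool)), _full_mask((5, 5, 5)))


def test_surface_density_complement_invariant(rng):
    region = np.ones((16, 16, 16), dtype=bool)
    fg = rng.random((16, 16, 16)) < 0.3
    assert surface_density(fg, region, SP) == pytest.approx(
        surface_density(~fg, region, SP), rel=1e-12
    )


def test_surface_density_single_voxel_region_is_zero():
    region = np.zeros((4, 4, 4), dtype=bool)
    region[1, 1, 1] = True
    assert surface_density(region.copy(), region, SP) == 0.0


# ---------------------------------------------------------------------------
# local maps
# ---------------------------------------------------------------------------

def test_local_homogeneous_map_is_one_everywhere():
    shape = (32, 32, 32)
    tm = local_minkowski_maps(_map(np.ones(shape, dtype=bool)), _full_mask(shape),
                              WindowSpec(11, 5, 0.5))
    defined = tm.defined
    assert defined.any()
    assert np.allclose(tm["v"][defined], 1.0)
    assert np.allclose(tm["s"][defined], 0.0)  # wholly-foreground windows


def test_local_v_tracks_bernoulli_fraction(full_mask_64):
    f = bernoulli_field(FieldSpec(p=0.3, seed=11))
    tm = local_minkowski_maps(f, full_mask_64, metrics=("v",))
    mean_v = float(np.nanmean(tm["v"][tm.defined]))
    assert mean_v == pytest.approx(0.3, abs=0.01)


def test_low_coverage_sites_are_nan_not_zero():
    shape = (32, 32, 32)
    mask_values = np.zeros(shape, dtype=bool)
    mask_values[:, :, 16:] = True  # half the volume is lung
    mask = LungMask(mask_values, SP)
    tm = local_minkowski_maps(_map(mask_values.copy()), mask, WindowSpec(11, 5, 0.6))
    assert (~tm.defined).any()
    assert np.isnan(tm["v"][~tm.defined]).all()
    assert (tm.coverage[~tm.defined] < 0.6).all()
    # defined sites inside the lung read density 1
    assert np.allclose(tm["v"][tm.defined], 1.0)


def test_window_larger_than_volume_rejected():
    shape = (16, 16, 16)
    with pytest.raises(ValueError, match="window edge"):
        local_minkowski_maps(_map(np.ones(shape, dtype=bool)), _full_mask(shape),
                             WindowSpec(21, 5))


def test_unknown_metric_rejected():
    shape = (16, 16, 16)
    with pytest.raises(ValueError, match="unknown metrics"):
        local_minkowski_maps(_map(np.ones(shape, dtype=bool)), _full_mask(shape),
                             WindowSpec(11, 5), metrics=("volume",))


def test_local_grid_geometry():
    shape = (30, 25, 40)
    tm = local_minkowski_maps(_map(np.ones(shape, dtype=bool)), _full_mask(shape),
                              WindowSpec(11, 5), metrics=("v",))
    assert tm.grid_shape == (6, 5, 8)
    coords = tm.site_coordinates()
    assert coords[0][-1] == 25.0 and coords[2][-1] == 35.0


# ---------------------------------------------------------------------------
# alpha
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def window_curves():
    return expected_random_curves(reps=8, shape=(21, 21, 21), seed=7)


def test_alpha_near_zero_for_random_field(full_mask_64, window_curves):
    f = bernoulli_field(FieldSpec(p=0.3, seed=5))
    tm = local_minkowski_maps(f, full_mask_64, metrics=("v", "chi"))
    alpha = alpha_descriptor(tm, window_curves)
    assert abs(np.nanmean(alpha[tm.defined])) < 0.01


def test_alpha_negative_for_clustered_field(full_mask_64, window_curves):
    f = clustered_field(FieldSpec(p=0.3, pattern="clustered",
                                  correlation_length=6, seed=5))
    tm = local_minkowski_maps(f, full_mask_64, metrics=("v", "chi"))
    alpha_c = float(np.nanmean(alpha_descriptor(tm, window_curves)[tm.defined]))
    fb = bernoulli_field(FieldSpec(p=0.3, seed=5))
    tmb = local_minkowski_maps(fb, full_mask_64, metrics=("v", "chi"))
    alpha_b = float(np.nanmean(alpha_descriptor(tmb, window_curves)[tmb.defined]))
    assert alpha_c < -0.03          # far fewer components than a random field
    assert abs(alpha_b) < abs(alpha_c) / 3


def test_alpha_undefined_on_empty_class(window_curves):
    shape = (32, 32, 32)
    tm = local_minkowski_maps(_map(np.zeros(shape, dtype=bool)), _full_mask(shape),
                              WindowSpec(11, 5), metrics=("v", "chi"))
    alpha = alpha_descriptor(tm, window_curves)
    assert np.isnan(alpha[tm.defined]).all()


def test_alpha_requires_curves(full_mask_64):
    f = bernoulli_field(FieldSpec(p=0.3, seed=5))
    tm = local_minkowski_maps(f, full_mask_64, metrics=("v", "chi"))
    with pytest.raises(ValueError, match="missing reference curves"):
        alpha_descriptor(tm, None)


def test_global_alpha_near_zero_for_random_field(window_curves):
    mask = _full_mask((21, 21, 21))
    f = bernoulli_field(FieldSpec(shape=(21, 21, 21), p=0.4, seed=9))
    rec = global_alpha(global_minkowski(f, mask), window_curves)
    assert abs(rec.alpha_density) < 0.01


# ---------------------------------------------------------------------------
# subject summary
# ---------------------------------------------------------------------------

def _summary_inputs(s_values, coverage=None):
    grid = np.asarray(s_values, dtype=float)
    cov = np.ones_like(grid) if coverage is None else np.asarray(coverage, float)
    tm = TopologyMaps(
        maps={"s": grid}, coverage=cov, window=WindowSpec(11, 5, 0.5),
        spacing=SP, native_shape=(32, 32, 32), meta={"class": "FSAD"},
    )
    rec = MinkowskiRecord(V=1, S=1, B=1, chi=1, v_density=0.5, s_density=0.4,
                          b_density=0.0, chi_density=0.0, n_mask_voxels=10,
                          masked_volume_mm3=10.0)
    from prmtopo.classify import PRMClass, ClassFractions

    fractions = ClassFractions(
        {PRMClass.NORMAL: 50.0, PRMClass.FSAD: 40.0, PRMClass.EMPH: 10.0,
         PRMClass.UNCLASSIFIED: 0.0, PRMClass.EXCLUDED: 0.0},
        "in_mask", 100, 100,
    )
    return tm, rec, fractions


def test_subject_mean_of_constant_map_is_constant():
    tm, rec, fr = _summary_inputs(np.full((2, 2, 2), 0.5))
    assert summarize_subject(tm, rec, fr).local_means["s"] == pytest.approx(0.5)


def test_subject_mean_of_two_sites():
    tm, rec, fr = _summary_inputs(np.array([[[0.2, 0.6]]]))
    summary = summarize_subject(tm, rec, fr)
    assert summary.local_means["s"] == pytest.approx(0.4)
    assert summary.n_defined_sites == 2
    row = summary.to_row()
    assert row["pct_fsad"] == 40.0 and row["global_s"] == 0.4


def test_subject_coverage_weighted_mean():
    tm, rec, fr = _summary_inputs(np.array([[[0.2, 0.6]]]),
                                  coverage=np.array([[[1.0, 0.5]]]))
    summary = summarize_subject(tm, rec, fr, weighting="coverage")
    assert summary.local_means["s"] == pytest.approx((0.2 * 1.0 + 0.6 * 0.5) / 1.5)


def test_subject_zero_defined_sites_rejected():
    tm, rec, fr = _summary_inputs(np.full((2, 2, 2), np.nan),
                                  coverage=np.zeros((2, 2, 2)))
    with pytest.raises(ValueError, match="no defined analysis sites"):
        summarize_subject(tm, rec, fr)


# ---------------------------------------------------------------------------
# display maps
# ---------------------------------------------------------------------------

def test_display_map_native_shape_and_mask_zeroing():
    shape = (32, 32, 32)
    mask_values = np.ones(shape, dtype=bool)
    mask_values[:4] = False
    mask = LungMask(mask_values, SP)
    f = bernoulli_field(FieldSpec(shape=shape, p=0.4, seed=3))
    tm = local_minkowski_maps(f, mask, WindowSpec(11, 5), metrics=("v", "s"))
    disp = display_map(tm, "s", mask=mask)
    assert disp.shape == shape
    assert (disp[:4] == 0).all()


def test_display_values_bounded_by_contributing_sites(full_mask_64):
    f = bernoulli_field(FieldSpec(p=0.4, seed=3))
    tm = local_minkowski_maps(f, full_mask_64, metrics=("v", "s"))
    product = np.nan_to_num(tm["s"] * tm["v"])
    disp = display_map(tm, "s")
    assert disp.min() >= product.min() - 1e-9
    assert disp.max() <= product.max() + 1e-9


def test_display_zero_where_local_v_zero():
    shape = (32, 32, 32)
    tm = local_minkowski_maps(_map(np.zeros(shape, dtype=bool)), _full_mask(shape),
                              WindowSpec(11, 5), metrics=("v", "s", "chi"))
    assert (display_map(tm, "chi") == 0).all()


def test_display_unknown_metric_rejected(full_mask_64):
    f = bernoulli_field(FieldSpec(p=0.4, seed=3))
    tm = local_minkowski_maps(f, full_mask_64, metrics=("v", "s"))
    with pytest.raises(ValueError, match="display metric"):
        display_map(tm, "v")
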