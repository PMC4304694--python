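"""maps module: MRC I/O, statistics, interpolation, scoring, masking,
sharpening, scaling and combination."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emfit.maps import (DensityMap, SphereRegion, average_maps,
                        composite_maps, interpolate, lowpass_map,
                        mask_by_model, radial_amplitude, read_mrc,
                        robust_map_stats, scale_to_reference, segment_sphere,
                        sharpen_map, trilinear, write_mrc, z_weighted_score,
                        SEGMENT_RADIUS_PROTEIN, SEGMENT_RADIUS_RNA)
from emfit.model import Atom, AtomicModel, Residue
from emfit.synth import build_ideal_helix, simulate_map


def make_map(values, voxel=1.0, origin=(0.0, 0.0, 0.0)):
    return DensityMap(np.asarray(values, float),
                      np.array([voxel] * 3), np.asarray(origin, float))


# --- MRC round trip ---------------------------------------------------------

def test_mrc_round_trip(tmp_path):
    ramp = np.arange(512.0).reshape(8, 8, 8)
    m = make_map(ramp, voxel=1.25)
    path = str(tmp_path / "a.mrc")
    write_mrc(m, path)
    back = read_mrc(path)
    assert np.allclose(back.values, m.values, atol=1e-5)
    assert np.allclose(back.voxel_size, m.voxel_size, atol=1e-5)


def test_mrc_origin_preserved(tmp_path):
    m = make_map(np.random.default_rng(0).normal(size=(8, 8, 8)),
                 voxel=1.0, origin=(-4.0, -4.0, -4.0))
    path = str(tmp_path / "o.mrc")
    write_mrc(m, path)
    assert np.allclose(read_mrc(path).origin, m.origin, atol=1e-4)


# --- robust_map_stats -------------------------------------------------------

def test_robust_stats_modal_bin_discard():
    gen = np.random.default_rng(2)
    vals = np.zeros(20 ** 3)
    n_sig = len(vals) // 10
    vals[:n_sig] = gen.normal(5.0, 1.0, size=n_sig)
    dmap = make_map(vals.reshape(20, 20, 20))
    stats = robust_map_stats(dmap)
    oracle = vals[:n_sig].mean()
    assert abs(stats.mean - oracle) < 0.1


def test_robust_stats_constant_map_errors():
    with pytest.raises(Exception):
        robust_map_stats(make_map(np.ones((8, 8, 8))))


def test_robust_stats_pure_gaussian():
    gen = np.random.default_rng(3)
    vals = gen.normal(size=16 ** 3)
    stats = robust_map_stats(make_map(vals.reshape(16, 16, 16)))
    assert abs(stats.mean) < 3.0 / np.sqrt(len(vals))


# --- interpolation ----------------------------------------------------------

def test_interpolate_voxel_center():
    gen = np.random.default_rng(4)
    vals = gen.normal(size=(6, 6, 6))
    dmap = make_map(vals)
    assert interpolate(dmap, [2.0, 3.0, 4.0]) == pytest.approx(
        vals[2, 3, 4], abs=1e-12)


def test_interpolate_midpoint():
    vals = np.ones((4, 4, 4))
    vals[1, 1, 1] = 0.0
    vals[2, 1, 1] = 2.0
    dmap = make_map(vals)
    assert interpolate(dmap, [1.5, 1.0, 1.0]) == pytest.approx(1.0, abs=1e-12)


def test_interpolate_out_of_bounds_zero():
    dmap = make_map(np.ones((4, 4, 4)))
    vals, inside = trilinear(dmap, np.array([[99.0, 0.0, 0.0]]))
    assert vals[0] == 0.0
    assert not inside[0]


def brute_trilinear(dmap, p):
    q = (np.asarray(p) - dmap.origin) / dmap.voxel_size
    i0 = np.floor(q).astype(int)
    f = q - i0
    total = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wx = f[0] if dx else 1 - f[0]
                wy = f[1] if dy else 1 - f[1]
                wz = f[2] if dz else 1 - f[2]
                total += wx * wy * wz * dmap.values[i0[0] + dx,
                                                    i0[1] + dy,
                                                    i0[2] + dz]
    return total


def test_trilinear_matches_brute_force():
    gen = np.random.default_rng(5)
    dmap = make_map(gen.normal(size=(6, 6, 6)))
    pts = gen.uniform(0.5, 4.4, size=(100, 3))
    got, inside = trilinear(dmap, pts)
    assert inside.all()
    want = [brute_trilinear(dmap, p) for p in pts]
    assert np.allclose(got, want, atol=1e-10)


# --- z_weighted_score -------------------------------------------------------

def atoms_at(points, element="C"):
    res = Residue("ALA", 1, [
        Atom(f"C{k}", element, np.asarray(p, float), 1.0, 20.0)
        for k, p in enumerate(points)], kind="protein")
    return AtomicModel([("A", [res])])


def test_z_score_unit_weights_simple():
    gen = np.random.default_rng(6)
    dmap = make_map(gen.normal(size=(8, 8, 8)))
    stats = robust_map_stats(dmap)
    dmap.values[2, 2, 2] = stats.mean + stats.sd
    model = atoms_at([[2.0, 2.0, 2.0]] * 4)
    score = z_weighted_score(dmap, stats, model, weight_mode="unit")
    assert score == pytest.approx(4.0, abs=1e-6)


def test_z_score_brute_force_oracle():
    gen = np.random.default_rng(7)
    dmap = make_map(gen.normal(size=(6, 6, 6)))
    stats = robust_map_stats(dmap)
    pts = gen.uniform(0.5, 4.4, size=(10, 3))
    model = atoms_at(pts, element="N")
    got = z_weighted_score(dmap, stats, model)
    want = sum(7.0 * (brute_trilinear(dmap, p) - stats.mean) / stats.sd
               for p in pts)
    assert got == pytest.approx(want, abs=1e-8)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(offset=st.floats(-5.0, 5.0), scale=st.floats(0.1, 10.0))
def test_z_score_affine_invariance(offset, scale):
    gen = np.random.default_rng(8)
    vals = gen.normal(size=(8, 8, 8))
    a = make_map(vals)
    b = make_map(vals * scale + offset)
    model = atoms_at(gen.uniform(1.0, 6.0, size=(5, 3)))
    sa = z_weighted_score(a, robust_map_stats(a), model)
    sb = z_weighted_score(b, robust_map_stats(b), model)
    assert sa == pytest.approx(sb, rel=1e-6, abs=1e-6)


# --- masking / segmentation -------------------------------------------------

def test_mask_radius_larger_than_box():
    dmap = make_map(np.random.default_rng(9).normal(size=(8, 8, 8)))
    model = atoms_at([[4.0, 4.0, 4.0]])
    out = mask_by_model(dmap, model, 100.0)
    assert np.array_equal(out.values, dmap.values)


def test_mask_single_atom_distance_oracle():
    dmap = make_map(np.ones((9, 9, 9)))
    model = atoms_at([[4.0, 4.0, 4.0]])
    out = mask_by_model(dmap, model, 1.0, soft_edge=0.0)
    idx = np.indices((9, 9, 9)).reshape(3, -1).T.astype(float)
    dist = np.linalg.norm(idx - 4.0, axis=1).reshape(9, 9, 9)
    assert np.array_equal(out.values != 0, dist <= 1.0)


def test_mask_nonzero_monotone_in_radius():
    dmap = make_map(np.ones((12, 12, 12)))
    model = atoms_at([[6.0, 6.0, 6.0]])
    counts = [np.count_nonzero(mask_by_model(dmap, model, r).values)
              for r in (1.0, 2.0, 4.0, 8.0)]
    assert counts == sorted(counts)


def test_segment_sphere_whole_map():
    dmap = make_map(np.random.default_rng(10).normal(size=(8, 8, 8)))
    seg = segment_sphere(dmap, SphereRegion(np.array([3.5] * 3), 100.0))
    pts = np.random.default_rng(11).uniform(1.0, 6.0, size=(20, 3))
    for p in pts:
        assert interpolate(seg, p) == pytest.approx(interpolate(dmap, p),
                                                    abs=1e-12)


def test_segment_sphere_coordinate_preservation():
    dmap = make_map(np.random.default_rng(12).normal(size=(16, 16, 16)))
    seg = segment_sphere(dmap, SphereRegion(np.array([8.0] * 3), 5.0))
    gen = np.random.default_rng(13)
    for _ in range(50):
        # sample well inside the sphere: interpolation within one voxel of
        # the boundary legitimately mixes zeroed outside voxels
        p = np.array([8.0] * 3) + gen.uniform(-1.9, 1.9, size=3)
        assert interpolate(seg, p) == pytest.approx(interpolate(dmap, p),
                                                    abs=1e-10)


def test_segment_presets():
    assert SEGMENT_RADIUS_PROTEIN == 34.0
    assert SEGMENT_RADIUS_RNA == 17.0


def test_segment_no_intersection_errors():
    dmap = make_map(np.ones((8, 8, 8)))
    with pytest.raises(Exception):
        segment_sphere(dmap, SphereRegion(np.array([500.0] * 3), 2.0))


# --- sharpen / scale --------------------------------------------------------

def test_sharpen_b_zero_identity():
    dmap = make_map(np.random.default_rng(14).normal(size=(16, 16, 16)))
    out = sharpen_map(dmap, 0.0)
    assert np.allclose(out.values, dmap.values, atol=1e-6)


def test_sharpen_inverse():
    dmap = make_map(np.random.default_rng(15).normal(size=(16, 16, 16)))
    out = sharpen_map(sharpen_map(dmap, 30.0), -30.0)
    assert np.allclose(out.values, dmap.values,
                       atol=1e-6 * np.abs(dmap.values).max())


def test_sharpen_shell_profile_oracle():
    dmap = make_map(np.random.default_rng(16).normal(size=(24, 24, 24)))
    B = 40.0
    out = sharpen_map(dmap, B)
    fa = np.fft.rfftn(dmap.values)
    fb = np.fft.rfftn(out.values)
    s2 = None
    # brute-force s grid for an rfft layout
    freqs = [np.fft.fftfreq(24, 1.0), np.fft.fftfreq(24, 1.0),
             np.fft.rfftfreq(24, 1.0)]
    s2 = (freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2 +
          freqs[2][None, None, :] ** 2)
    expected = np.exp(-B * s2 / 4.0)
    mask = np.abs(fa) > 1e-8
    assert np.allclose(np.abs(fb[mask]) / np.abs(fa[mask]), expected[mask],
                       atol=1e-6)


def test_sharpen_conserves_f0():
    dmap = make_map(np.random.default_rng(17).normal(size=(12, 12, 12)))
    out = sharpen_map(dmap, -50.0)
    assert out.values.sum() == pytest.approx(dmap.values.sum(), rel=1e-9)


def test_scale_to_self_identity():
    dmap = make_map(np.random.default_rng(18).normal(size=(16, 16, 16)))
    out = scale_to_reference(dmap, dmap)
    assert np.allclose(out.values, dmap.values,
                       atol=1e-6 * np.abs(dmap.values).max())


def test_scale_undoes_sharpening():
    dmap = make_map(np.random.default_rng(19).normal(size=(16, 16, 16)))
    out = scale_to_reference(sharpen_map(dmap, 25.0), dmap)
    assert np.allclose(out.values, dmap.values,
                       atol=1e-5 * np.abs(dmap.values).max())


def test_scale_half_maps_equal_profiles(helix20):
    from emfit.synth import NoiseSpec, simulate_half_maps
    c = helix20.centroid()
    h1, h2 = simulate_half_maps(helix20, (32, 32, 32), 1.0, 4.0,
                                NoiseSpec(0.3), (5, 6), origin=c - 16.0)
    ref = simulate_map(helix20, (32, 32, 32), 1.0, 4.0, origin=c - 16.0)
    s1, a1 = radial_amplitude(scale_to_reference(h1, ref))
    s2, a2 = radial_amplitude(scale_to_reference(h2, ref))
    good = a1 > 1e-8
    assert np.allclose(a1[good], a2[good], rtol=1e-6)


# --- combination ------------------------------------------------------------

def test_average_with_self_identity():
    dmap = make_map(np.random.default_rng(20).normal(size=(8, 8, 8)))
    out = average_maps([dmap, dmap])
    assert np.allclose(out.values, dmap.values, atol=1e-12)


def test_composite_disjoint_masks_copied():
    a = make_map(np.full((8, 8, 8), 1.0))
    b = make_map(np.full((8, 8, 8), 3.0))
    ma = np.zeros((8, 8, 8))
    ma[:4] = 1.0
    mb = 1.0 - ma
    out = composite_maps([a, b], [make_map(ma), make_map(mb)])
    assert np.array_equal(out.values[:4], a.values[:4])
    assert np.array_equal(out.values[4:], b.values[4:])


def test_composite_overlap_averages():
    a = make_map(np.full((4, 4, 4), 1.0))
    b = make_map(np.full((4, 4, 4), 3.0))
    half = make_map(np.full((4, 4, 4), 0.5))
    out = composite_maps([a, b], [half, half])
    assert np.allclose(out.values, 2.0, atol=1e-12)


def test_combine_grid_mismatch_errors():
    a = make_map(np.ones((8, 8, 8)))
    b = make_map(np.ones((9, 9, 9)))
    with pytest.raises(Exception):
        average_maps([a, b])


def test_lowpass_reduces_high_frequency_power():
    gen = np.random.default_rng(21)
    dmap = make_map(gen.normal(size=(24, 24, 24)))
    out = lowpass_map(dmap, 5.0)
    fa = np.abs(np.fft.rfftn(dmap.values))
    fb = np.abs(np.fft.rfftn(out.values))
    freqs = [np.fft.fftfreq(24, 1.0), np.fft.fftfreq(24, 1.0),
             np.fft.rfftfreq(24, 1.0)]
    s2 = (freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2 +
          freqs[2][None, None, :] ** 2)
    high = s2 > (1.0 / 5.0) ** 2 + 1e-9
    assert fb[high].max() < 1e-6 * fa.max()
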