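"""refine module: energy terms with finite-difference oracles, multi-target
selection, backtracking refinement, symmetry-aware nonbonded handling,
masked-region refinement, and half-map cross-validation."""
import importlib

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from emfit.fsc import cross_validate
from emfit.maps import DensityMap, mask_by_model
from emfit.model import Atom, AtomicModel, Residue, RTOperator, SymmetryGroup
from emfit.restraints import (DistanceRestraint, RestraintSet, geman_mcclure,
                              detect_base_pairs,
                              generate_base_pair_restraints,
                              generate_jelly_restraints)
from emfit.synth import (NoiseSpec, build_ideal_helix, shake_model,
                         simulate_half_maps, simulate_map)

# the package re-exports the refine *function* at the top level, shadowing
# `emfit.refine` as an attribute; import the module explicitly
refmod = importlib.import_module("emfit.refine")
from test_restraints import gu_model  # noqa: E402  (shared fixture helper)


# --- geometry_energy --------------------------------------------------------

def test_geometry_zero_at_targets(helix20):
    rset = generate_jelly_restraints(helix20)
    value, grad = refmod.geometry_energy(helix20, rset)
    assert value == pytest.approx(0.0, abs=1e-12)
    assert np.abs(grad).max() < 1e-9


def test_geometry_hand_evaluation():
    """Single restraint displaced +0.1 A: value = GM(d - d_t, c) / sigma^2."""
    m = AtomicModel([("A", [
        Residue("ALA", 1, [Atom("CA", "C", np.zeros(3), 1.0, 20.0)]),
        Residue("ALA", 2, [Atom("CA", "C", np.array([2.1, 0.0, 0.0]),
                                1.0, 20.0)])])])
    r = DistanceRestraint(("A", 1, "CA"), ("A", 2, "CA"), [(2.0, 0.1)],
                          "reference")
    value, grad = refmod.geometry_energy(m, RestraintSet(distance=[r]),
                                         gm_scale=0.5)
    assert value == pytest.approx(geman_mcclure(0.1, 0.5)[0] / 0.1 ** 2,
                                  rel=1e-12)
    # gradient along the bond axis, equal and opposite
    assert np.allclose(grad[0], -grad[1], atol=1e-12)
    assert abs(grad[0][1]) < 1e-12 and abs(grad[0][2]) < 1e-12


def test_geometry_missing_atom_errors(helix20):
    r = DistanceRestraint(("A", 1, "CA"), ("Z", 99, "CA"), [(3.0, 0.1)],
                          "reference")
    with pytest.raises(Exception):
        refmod.geometry_energy(helix20, RestraintSet(distance=[r]))


def fd_gradient(fun, coords, indices, h=1e-5):
    """Central finite differences of scalar fun(coords) at flat indices."""
    out = {}
    for idx in indices:
        i, k = divmod(idx, 3)
        cp, cm = coords.copy(), coords.copy()
        cp[i, k] += h
        cm[i, k] -= h
        out[idx] = (fun(cp) - fun(cm)) / (2 * h)
    return out


def test_geometry_gradient_finite_differences():
    truth = build_ideal_helix(5)
    shaken = shake_model(truth, 0.2, seed=4)
    rset = generate_jelly_restraints(truth)
    coords = shaken.coords()
    value, grad = refmod.geometry_energy(shaken, rset, coords=coords)
    assert value > 0
    gen = np.random.default_rng(0)
    picks = gen.choice(coords.size, size=12, replace=False)
    fd = fd_gradient(lambda c: refmod.geometry_energy(shaken, rset,
                                                      coords=c)[0],
                     coords, picks)
    for idx, g_fd in fd.items():
        i, k = divmod(idx, 3)
        assert grad[i, k] == pytest.approx(
            g_fd, rel=1e-5, abs=1e-5 * max(1.0, np.abs(grad).max()))


# --- density_energy ---------------------------------------------------------

@pytest.fixture(scope="module")
def tri_fixture():
    truth = build_ideal_helix(3)
    c = truth.centroid()
    dmap = simulate_map(truth, (24, 24, 24), 1.0, 4.0, origin=c - 12.0)
    return truth, dmap


@pytest.mark.parametrize("mode", ["real", "reciprocal"])
def test_density_gradient_finite_differences(tri_fixture, mode):
    truth, dmap = tri_fixture
    shaken = shake_model(truth, 0.3, seed=6)
    coords = shaken.coords()
    value, grad = refmod.density_energy(shaken, dmap, mode=mode,
                                        d_min=4.0, coords=coords)
    gen = np.random.default_rng(1)
    picks = gen.choice(coords.size, size=10, replace=False)
    fd = fd_gradient(lambda c: refmod.density_energy(
        shaken, dmap, mode=mode, d_min=4.0, coords=c)[0], coords, picks,
        h=1e-4)
    scale = max(1.0, np.abs(grad).max())
    for idx, g_fd in fd.items():
        i, k = divmod(idx, 3)
        assert grad[i, k] == pytest.approx(g_fd, rel=1e-4, abs=1e-4 * scale)


def test_density_stationary_at_truth(helix20, helix20_map):
    """Reciprocal mode: F_obs = F_calc at the truth, so the residual target
    is exactly stationary; any displacement raises it.  Real mode's
    trilinear interpolant is only piecewise linear, so its pointwise
    gradient does not vanish — only the energy-increase check applies."""
    v_rec, g_rec = refmod.density_energy(helix20, helix20_map,
                                         mode="reciprocal", d_min=3.5)
    scale_rec = np.abs(refmod.density_energy(
        shake_model(helix20, 0.3, seed=1), helix20_map, mode="reciprocal",
        d_min=3.5)[1]).max()
    assert np.abs(g_rec).max() < 1e-6 * scale_rec
    moved = helix20.transformed(
        RTOperator(np.eye(3), np.array([0.5, 0.0, 0.0])))
    for mode in ("real", "reciprocal"):
        v0, _ = refmod.density_energy(helix20, helix20_map, mode=mode,
                                      d_min=3.5)
        v1, _ = refmod.density_energy(moved, helix20_map, mode=mode,
                                      d_min=3.5)
        assert v1 > v0


def test_density_weight_zero(helix20, helix20_map):
    value, grad = refmod.density_energy(helix20, helix20_map, mode="real",
                                        weight=0.0, d_min=3.5)
    assert value == 0.0
    assert np.all(grad == 0.0)


def test_density_degenerate_stats_errors(helix20):
    flat = DensityMap(np.ones((40, 40, 40)), np.ones(3),
                      helix20.centroid() - 20.0)
    with pytest.raises(Exception):
        refmod.density_energy(helix20, flat, mode="real", d_min=3.5)


# --- select_multi_targets ---------------------------------------------------

def gu_restraints(cfg):
    model = gu_model(cfg)
    return model, generate_base_pair_restraints(detect_base_pairs(model))


def test_select_wobble_geometry():
    model, rset = gu_restraints("GU_wobble")
    active, chosen = refmod.select_multi_targets(model, rset)
    assert set(chosen.values()) == {0}
    for r in active.distance:
        assert len(r.targets) == 1


def test_select_reverse_wobble_geometry():
    model, rset = gu_restraints("GU_reverse_wobble")
    # restraints regenerated in *wobble* ordering carry both alternatives;
    # build them from the wobble-geometry model, then select on the
    # reverse-wobble geometry: the reverse targets must win
    wob_model, wob_rset = gu_restraints("GU_wobble")
    _, chosen = refmod.select_multi_targets(model, wob_rset)
    assert set(chosen.values()) == {1}


def test_select_single_target_unaffected(helix20):
    rset = generate_jelly_restraints(helix20)
    active, chosen = refmod.select_multi_targets(helix20, rset)
    assert chosen == {}
    assert len(active.distance) == len(rset.distance)


def test_selection_stable_at_convergence():
    model, rset = gu_restraints("GU_wobble")
    c = model.centroid()
    dmap = simulate_map(model, (24, 24, 24), 1.0, 3.0, origin=c - 12.0)
    params = refmod.RefineParams(n_cycles=6, d_min=3.0)
    result = refmod.refine_coords(shake_model(model, 0.1, seed=2), dmap,
                                  rset, params)
    assert result.cycles[-1].selected_targets == \
        result.cycles[-2].selected_targets


# --- refine_coords ----------------------------------------------------------

def test_refine_monotone_and_deterministic(helix20, helix20_map):
    shaken = shake_model(helix20, 0.3, seed=3)
    rset = generate_jelly_restraints(helix20)
    params = refmod.RefineParams(n_cycles=8, d_min=3.5)
    r1 = refmod.refine_coords(shaken, helix20_map, rset, params)
    totals = [c.total for c in r1.cycles]
    assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))
    r2 = refmod.refine_coords(shaken, helix20_map, rset, params)
    assert np.array_equal(r1.model.coords(), r2.model.coords())
    assert r1.model.rmsd_to(helix20) < shaken.rmsd_to(helix20)


@pytest.fixture(scope="module")
def w0_runs(helix20, helix20_map):
    shaken = shake_model(helix20, 0.3, seed=3)
    rset = generate_jelly_restraints(shaken)
    params = refmod.RefineParams(n_cycles=10, data_weight=0.0, d_min=3.5)
    res_a = refmod.refine_coords(shaken, helix20_map, rset, params)
    gen = np.random.default_rng(0)
    junk = DensityMap(gen.normal(size=(40, 40, 40)), helix20_map.voxel_size,
                      helix20_map.origin)
    res_b = refmod.refine_coords(shaken, junk, rset, params)
    return res_a, res_b


def test_w0_geometry_decreases(w0_runs):
    res_a, _ = w0_runs
    assert res_a.cycles[-1].geometry < 0.1 * res_a.cycles[0].geometry


def test_w0_map_independent(w0_runs):
    res_a, res_b = w0_runs
    assert np.allclose(res_a.model.coords(), res_b.model.coords())


# --- symmetry ---------------------------------------------------------------

@pytest.fixture(scope="module")
def c2_fixture():
    grp = SymmetryGroup.cyclic(2)
    op = grp.operators[1]
    base = build_ideal_helix(10)
    xyz0 = base.coords() - base.centroid()
    ax = np.linalg.svd(xyz0, full_matrices=False)[2][0]
    R = Rotation.align_vectors([[0, 0, 1]], [ax])[0].as_matrix()
    mono = base.transformed(RTOperator(R, np.array([5.0, 0.0, 0.0])
                                       - R @ base.centroid()))
    dimer = mono.copy()
    dimer.chains = [("A", mono.copy().chains[0][1]),
                    ("B", mono.transformed(op).chains[0][1])]
    dmap = simulate_map(dimer, (44, 44, 44), 1.0, 4.0,
                        origin=np.zeros(3) - 22.0)
    start = shake_model(mono, 0.25, seed=9)
    rset = generate_jelly_restraints(start)
    runs = {}
    for label, sym in (("C2", grp), ("none", None)):
        params = refmod.RefineParams(n_cycles=10, data_weight=1.0,
                                     d_min=4.0, symmetry=sym)
        runs[label] = refmod.refine_coords(start, dmap, rset, params)
    return op, mono, runs


def min_mate_dist(model, op):
    xyz = model.coords()
    mate = xyz @ op.rotation.T + op.translation
    return cKDTree(xyz).query(mate)[0].min()


def test_c2_symmetry_keeps_clearance(c2_fixture):
    op, mono, runs = c2_fixture
    assert min_mate_dist(runs["C2"].model, op) >= 2.2


def test_no_symmetry_interface_collapses(c2_fixture):
    op, mono, runs = c2_fixture
    assert min_mate_dist(runs["none"].model, op) < \
        min_mate_dist(runs["C2"].model, op)
    assert min_mate_dist(runs["none"].model, op) < 2.2


def test_c2_symmetry_recovers_monomer(c2_fixture):
    op, mono, runs = c2_fixture
    assert runs["C2"].model.rmsd_to(mono) < 0.2


# --- masked-region refinement -----------------------------------------------

@pytest.fixture(scope="module")
def masked_fixture():
    a = build_ideal_helix(12)
    b = build_ideal_helix(12).transformed(
        RTOperator(np.eye(3), np.array([14.0, 0.0, 0.0])))
    two = a.copy()
    two.chains = [("A", a.chains[0][1]), ("B", b.chains[0][1])]
    ct = two.centroid()
    dmap = simulate_map(two, (48, 48, 48), 1.0, 4.0, origin=ct - 24.0)
    shaken_a = shake_model(a, 0.3, seed=5)
    rset = generate_jelly_restraints(shaken_a)
    params = refmod.RefineParams(n_cycles=8, d_min=4.0)
    return a, dmap, shaken_a, rset, params


def test_masked_domain_improves(masked_fixture):
    a, dmap, shaken_a, rset, params = masked_fixture
    result = refmod.refine_masked_region(shaken_a, dmap, 6.0, rset, params)
    assert result.model.rmsd_to(a) < 0.7 * shaken_a.rmsd_to(a)


def test_masked_infinite_radius_matches_unmasked(masked_fixture):
    a, dmap, shaken_a, rset, params = masked_fixture
    r_inf = refmod.refine_masked_region(shaken_a, dmap, 1e6, rset, params)
    r_un = refmod.refine_coords(shaken_a, dmap, rset, params)
    for x, y in zip(r_inf.cycles, r_un.cycles):
        assert abs(x.total - y.total) < 1e-6


def test_masked_insensitive_to_outside_noise(masked_fixture):
    a, dmap, shaken_a, rset, params = masked_fixture
    rm = refmod.refine_masked_region(shaken_a, dmap, 6.0, rset, params)
    outside = mask_by_model(dmap, shaken_a, 6.0).values == 0
    gen = np.random.default_rng(8)
    noisy = dmap.values.copy()
    noisy[outside] += gen.normal(scale=5.0, size=int(outside.sum()))
    noisy_map = DensityMap(noisy, dmap.voxel_size, dmap.origin)
    rn = refmod.refine_masked_region(shaken_a, noisy_map, 6.0, rset, params)
    for x, y in zip(rn.cycles, rm.cycles):
        assert abs(x.total - y.total) < 1e-6


# --- cross-validation -------------------------------------------------------

def test_cross_validate_identical_halves(helix20):
    c = helix20.centroid()
    h1, _ = simulate_half_maps(helix20, (40, 40, 40), 1.0, 3.5,
                               NoiseSpec(0.05), (11, 12), origin=c - 20.0)
    params = refmod.RefineParams(n_cycles=10, data_weight=1.0, d_min=3.5)
    report = cross_validate(helix20, h1, h1, params, shake_rms=0.3, seed=2)
    assert report.max_gap < 1e-12
    assert report.fsc_work.same_shells(report.fsc_test)


def test_cross_validate_restrained_low_noise(helix20):
    c = helix20.centroid()
    h1, h2 = simulate_half_maps(helix20, (40, 40, 40), 1.0, 3.5,
                                NoiseSpec(0.05), (11, 12), origin=c - 20.0)
    params = refmod.RefineParams(n_cycles=10, data_weight=1.0, d_min=3.5)
    report = cross_validate(helix20, h1, h2, params, shake_rms=0.3, seed=2)
    assert report.max_gap < 0.05
    assert report.d_cut == 3.5
    assert report.shake_rms == 0.3
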