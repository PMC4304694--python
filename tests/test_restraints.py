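"""restraints module: reference/jelly/hbond/fragment generation, base-pair
detection and multi-target G:U restraints, stacking planes, Geman-McClure,
exte/JSON serialization.  Energy/gradient behavior lives in test_refine."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emfit import bases
from emfit.model import Atom, AtomicModel, Residue, RTOperator
from emfit.restraints import (PROTEIN_RESTRAINED, detect_base_pairs,
                              detect_stacking, geman_mcclure,
                              generate_base_pair_restraints,
                              generate_hbond_restraints,
                              generate_helix_fragment_restraints,
                              generate_jelly_restraints,
                              generate_reference_restraints, read_exte,
                              restraint_set_from_json, restraint_set_to_json,
                              write_exte)
from emfit.synth import (bend_model, build_ideal_duplex, build_ideal_helix,
                         shake_model)


def atom_positions(model):
    pos = {}
    for cid, residues in model.chains:
        for r in residues:
            for a in r.atoms:
                pos[(cid, r.seq_id, a.name)] = a.position
    return pos


def restraint_deviation(r, pos):
    d = np.linalg.norm(pos[r.atom_a] - pos[r.atom_b])
    return min(abs(d - t) for t, _ in r.targets)


# --- reference restraints ---------------------------------------------------

def test_reference_identical_models_zero_deviation(helix20):
    rs = generate_reference_restraints(helix20, helix20)
    pos = atom_positions(helix20)
    assert len(rs.distance) > 0
    assert max(restraint_deviation(r, pos) for r in rs.distance) < 1e-9


def test_reference_no_target_at_or_above_threshold(helix20):
    rs = generate_reference_restraints(helix20, helix20)
    for r in rs.distance:
        for t, sigma in r.targets:
            assert t < 4.2
            assert sigma > 0


def test_reference_count_brute_force_oracle():
    """Independent O(n^2) enumeration of qualifying pairs on a 5-residue
    helix: restrained-subset atoms, |seq separation| >= 2, distance < 4.2."""
    m = build_ideal_helix(5)
    rs = generate_reference_restraints(m, m)
    atoms = [(cid, r.seq_id, a.name, a.position)
             for cid, residues in m.chains for r in residues
             for a in r.atoms if a.name in PROTEIN_RESTRAINED]
    count = 0
    for (c1, s1, _, p1), (c2, s2, _, p2) in itertools.combinations(atoms, 2):
        if c1 == c2 and abs(s1 - s2) < 2:
            continue
        if np.linalg.norm(p1 - p2) < 4.2:
            count += 1
    assert len(rs.distance) == count


def test_reference_empty_correspondence_errors(helix20):
    with pytest.raises(Exception):
        generate_reference_restraints(helix20, helix20, correspondence={})


# --- jelly restraints -------------------------------------------------------

def test_jelly_zero_at_generation_and_count(helix20):
    rs = generate_jelly_restraints(helix20)
    pos = atom_positions(helix20)
    assert max(restraint_deviation(r, pos) for r in rs.distance) < 1e-9
    ref = generate_reference_restraints(helix20, helix20)
    assert len(rs.distance) == len(ref.distance)


def test_jelly_energy_positive_after_shake(helix20):
    rs = generate_jelly_restraints(helix20)
    shaken = shake_model(helix20, 0.3, seed=1)
    pos = atom_positions(shaken)
    assert max(restraint_deviation(r, pos) for r in rs.distance) > 0.05


# --- hbond / helix fragment -------------------------------------------------

def test_hbond_12mer_exactly_eight():
    rs = generate_hbond_restraints(build_ideal_helix(12))
    assert len(rs.distance) == 8
    for r in rs.distance:
        assert r.kind == "hbond"
        assert r.atom_a[2] == "O" and r.atom_b[2] == "N"
        assert r.atom_b[1] - r.atom_a[1] == 4
        assert r.targets == [(2.9, 0.2)]


def extended_chain(n=12):
    """Residues with locally intact geometry laid out 6 A apart along x:
    no O(i)-N(i+4) contact, backbone nowhere near helical."""
    template = build_ideal_helix(1)
    residues = []
    for i in range(n):
        src = template.chains[0][1][0]
        shift = np.array([6.0 * i, 0.0, 0.0]) - src.atoms[0].position
        atoms = [Atom(a.name, a.element, a.position + shift, a.occupancy,
                      a.b_factor) for a in src.atoms]
        residues.append(Residue(src.name, i + 1, atoms, kind="protein"))
    return AtomicModel([("A", residues)])


def test_extended_chain_no_hbond_no_fragment():
    m = extended_chain(12)
    assert len(generate_hbond_restraints(m).distance) == 0
    assert len(generate_helix_fragment_restraints(m).distance) == 0


def test_helix_fragment_on_ideal_helix(helix20):
    rs = generate_helix_fragment_restraints(helix20)
    assert len(rs.distance) > 0
    for r in rs.distance:
        assert r.kind == "helix_fragment"
        for t, _ in r.targets:
            assert t < 4.2


def test_bent_helix_fragments_survive(helix20):
    mid = helix20.chains[0][1][9].seq_id
    bent = bend_model(helix20, mid, np.array([1.0, 0.0, 0.0]), 10.0)
    assert len(generate_helix_fragment_restraints(bent).distance) > 0


# --- base-pair detection ----------------------------------------------------

def test_detect_gcau_duplex_pairs():
    dup = build_ideal_duplex("GCAU")
    pairs = detect_base_pairs(dup)
    assert len(pairs) == 4
    by_pos = {}
    for p in pairs:
        cid, seq, name = p.residue_a
        key = seq if cid == "A" else 5 - seq
        by_pos[key] = p.pair_class
    assert by_pos == {1: "WC_GC", 2: "WC_GC", 3: "WC_AU", 4: "WC_AU"}


def test_detect_single_strand_empty():
    dup = build_ideal_duplex("GCAU")
    single = AtomicModel([dup.chains[0]])
    assert detect_base_pairs(single) == []


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_detect_random_duplexes(seed):
    gen = np.random.default_rng(seed)
    n = int(gen.integers(4, 11))
    seq = "".join(gen.choice(list("ACGU"), size=n))
    pairs = detect_base_pairs(build_ideal_duplex(seq))
    assert len(pairs) == n
    wc = {"A": "WC_AU", "U": "WC_AU", "G": "WC_GC", "C": "WC_GC"}
    found = {}
    for p in pairs:
        for cid, s, name in (p.residue_a, p.residue_b):
            if cid == "A":
                found[s] = p.pair_class
    assert found == {i + 1: wc[letter] for i, letter in enumerate(seq)}


def gu_model(configuration):
    """One G:U pair from the shipped in-plane templates, z = 0."""
    g2d, u2d = bases.gu_pair_coords(configuration)

    def res(name, seq, coords2d):
        atoms = [Atom(n, "C" if n.startswith("C") else n[0],
                      np.array([x, y, 0.0]), 1.0, 20.0)
                 for n, (x, y) in coords2d.items()]
        return Residue(name, seq, atoms, kind="rna")

    return AtomicModel([("A", [res("G", 1, g2d)]),
                        ("B", [res("U", 1, u2d)])])


def test_gu_wobble_detection():
    pairs = detect_base_pairs(gu_model("GU_wobble"))
    assert len(pairs) == 1
    assert pairs[0].pair_class == "GU_wobble"
    assert len(pairs[0].hbonds) == 2


def test_gu_reverse_wobble_detection():
    pairs = detect_base_pairs(gu_model("GU_reverse_wobble"))
    assert len(pairs) == 1
    assert pairs[0].pair_class == "GU_reverse_wobble"


# --- base-pair restraints ---------------------------------------------------

def test_wc_gc_three_single_target_restraints():
    dup = build_ideal_duplex("G")
    pairs = detect_base_pairs(dup)
    assert len(pairs) == 1 and pairs[0].pair_class == "WC_GC"
    rs = generate_base_pair_restraints(pairs)
    assert len(rs.distance) == 3
    for r in rs.distance:
        assert len(r.targets) == 1
        assert r.kind == "basepair"


def test_gu_restraints_two_targets():
    for cfg in ("GU_wobble", "GU_reverse_wobble"):
        rs = generate_base_pair_restraints(detect_base_pairs(gu_model(cfg)))
        assert len(rs.distance) >= 2
        for r in rs.distance:
            assert len(r.targets) == 2


def test_restraint_generation_deterministic():
    dup = build_ideal_duplex("GCAU")
    a = restraint_set_to_json(
        generate_base_pair_restraints(detect_base_pairs(dup)))
    b = restraint_set_to_json(
        generate_base_pair_restraints(detect_base_pairs(dup)))
    assert a == b


# --- stacking ---------------------------------------------------------------

def test_stacking_duplex_successive_bases():
    dup = build_ideal_duplex("GCAU")
    planes = detect_stacking(dup)
    # 3 successive intra-strand steps per strand
    assert len(planes) == 6


def base_at(model_letter, seq, z, chain="A", dx=0.0):
    coords = bases.base_coords_2d(model_letter)
    atoms = [Atom(n, "C" if n.startswith("C") else n[0],
                  np.array([xy[0] + dx, xy[1], z]), 1.0, 20.0)
             for n, xy in coords.items()]
    return Residue(model_letter, seq, atoms, kind="rna")


def test_far_apart_bases_not_stacked():
    m = AtomicModel([("A", [base_at("G", 1, 0.0), base_at("G", 2, 10.0)])])
    assert detect_stacking(m) == []


def test_coplanar_side_by_side_rejected():
    """Centroids 4 A apart but in-plane: normal-to-centroid angle ~90 deg
    distinguishes coplanarity from stacking."""
    m = AtomicModel([("A", [base_at("G", 1, 0.0),
                            base_at("G", 2, 0.0, dx=9.0)])])
    assert detect_stacking(m) == []


def test_stacked_pair_constructed():
    m = AtomicModel([("A", [base_at("G", 1, 0.0), base_at("G", 2, 3.4)])])
    assert len(detect_stacking(m)) == 1


# --- Geman-McClure ----------------------------------------------------------

def test_gm_zero_and_half_and_asymptote():
    v0, g0 = geman_mcclure(0.0, 1.5)
    assert v0 == 0.0 and g0 == 0.0
    vc, _ = geman_mcclure(1.5, 1.5)
    assert vc == pytest.approx(1.5 ** 2 / 2.0)
    v_big, g_big = geman_mcclure(1e6, 1.5)
    assert v_big == pytest.approx(1.5 ** 2, rel=1e-5)
    assert abs(g_big) < 1e-6


def test_gm_derivative_central_difference():
    h = 1e-6
    for delta in (-2.0, -0.3, 0.1, 0.7, 3.0):
        v_p, _ = geman_mcclure(delta + h, 1.2)
        v_m, _ = geman_mcclure(delta - h, 1.2)
        _, g = geman_mcclure(delta, 1.2)
        assert g == pytest.approx((v_p - v_m) / (2 * h), abs=1e-6)


def test_gm_nonpositive_c_errors():
    with pytest.raises(Exception):
        geman_mcclure(1.0, 0.0)
    with pytest.raises(Exception):
        geman_mcclure(1.0, -1.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(delta=st.floats(-50, 50, allow_nan=False),
       c=st.floats(0.1, 10.0))
def test_gm_even_monotone_bounded(delta, c):
    v, _ = geman_mcclure(delta, c)
    v_neg, _ = geman_mcclure(-delta, c)
    assert v == pytest.approx(v_neg, rel=1e-12, abs=1e-12)
    assert 0.0 <= v <= c ** 2 + 1e-12
    v_further, _ = geman_mcclure(abs(delta) + 0.5, c)
    assert v_further >= v - 1e-12


# --- serialization ----------------------------------------------------------

def test_exte_round_trip_with_alt_groups():
    dup = build_ideal_duplex("GCAU")
    rs = generate_base_pair_restraints(detect_base_pairs(gu_model(
        "GU_wobble"))).merged(
        generate_reference_restraints(dup, dup))
    text = write_exte(rs)
    assert "exte dist first chain" in text
    assert "alt group" in text  # G:U multi-target lines share a group tag
    back = read_exte(text, kind="reference")
    # every (pair, target) survives the round trip to 3-decimal precision
    def flat(r):
        return sorted((min(d.atom_a, d.atom_b), max(d.atom_a, d.atom_b),
                       round(t, 3), round(s, 3))
                      for d in r.distance for t, s in d.targets)
    assert flat(back) == flat(rs)
    multi = [d for d in back.distance if len(d.targets) == 2]
    assert len(multi) >= 2


def test_json_round_trip(helix20):
    rs = generate_jelly_restraints(helix20)
    back = restraint_set_from_json(restraint_set_to_json(rs))
    assert restraint_set_to_json(back) == restraint_set_to_json(rs)
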