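"""Structure parsing, superposition, superhelix geometry and contacts."""

import numpy as np
import pytest

from conftest import model_from_ca, quaternion_rmsd, random_rotation, write_model_pdb
from pprkit.io import make_ideal_helix
from pprkit.structgeom import (
    StructureError,
    StructureModel,
    contact_report,
    find_hbonds,
    kabsch,
    read_structure,
    repeat_centroids,
    segment_repeats,
    segmentation_from_ranges,
    superhelix,
    superpose,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein_model(n: int, rng: np.random.Generator, first_seqid: int = 1):
    seq = "".join(rng.choice(list(AAS), size=n))
    coords = rng.normal(size=(n, 3)) * 8.0
    return model_from_ca(seq, coords, first_seqid=first_seqid), seq, coords


# ---------------------------------------------------------------------------
# parsing

def test_pdb_and_mmcif_roundtrip_with_chain_classification(tmp_path, recognition):
    import gemmi

    model, _ = recognition
    pdb = tmp_path / "complex.pdb"
    write_model_pdb(model, pdb)
    reread = read_structure(pdb)
    assert {c.mol_class for c in reread.chains} == {"protein", "rna", "water"}
    assert len(reread.protein_chain.residues) == 70
    assert len(reread.rna_chain.residues) == 2
    assert len(reread.water_atoms()) == 2

    cif = tmp_path / "complex.cif"
    st = gemmi.read_structure(str(pdb))
    st.setup_entities()
    st.make_mmcif_document().write_file(str(cif))
    assert len(read_structure(cif).protein_chain.residues) == 70


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    pdb = tmp_path / "altloc.pdb"
    pdb.write_text(
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C\n"
        "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00 10.00           C\n"
        "ATOM      4  CA  ALA A   3       7.600   0.000   0.000  1.00 10.00           C\n"
        "END\n"
    )
    model = read_structure(pdb)
    res1 = model.protein_chain.residue_by_seqid(1)
    assert res1.atoms["CA"].pos[0] == pytest.approx(5.0)


def test_unparseable_and_missing_files_raise(tmp_path):
    bad = tmp_path / "garbage.cif"
    bad.write_text("this is not a structure\n")
    with pytest.raises(StructureError):
        read_structure(bad)
    with pytest.raises(StructureError, match="no such file"):
        read_structure(tmp_path / "absent.pdb")


# ---------------------------------------------------------------------------
# superposition

def test_kabsch_matches_quaternion_oracle_on_small_instances():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(3, 11))
        fixed = rng.normal(size=(n, 3)) * 5.0
        moving = (fixed + rng.normal(size=(n, 3)) * 0.5) @ random_rotation(rng).T
        moving += rng.normal(size=3) * 10.0
        _, _, rmsd = kabsch(moving, fixed)
        assert rmsd == pytest.approx(quaternion_rmsd(moving, fixed), abs=1e-8)


def test_self_superposition_is_exact_and_keeps_all_pairs():
    rng = np.random.default_rng(1)
    model, _, _ = _random_protein_model(40, rng)
    res = superpose(model, model)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert res.n_retained == res.n_initial == 40
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_rigid_transform_invariance_and_symmetry():
    rng = np.random.default_rng(2)
    model_a, seq, coords = _random_protein_model(30, rng)
    noisy = coords + rng.normal(size=coords.shape) * 0.3
    model_b = model_from_ca(seq, noisy)
    rmsd_ab = superpose(model_a, model_b).rmsd
    assert superpose(model_b, model_a).rmsd == pytest.approx(rmsd_ab, abs=1e-6)
    rot, trans = random_rotation(rng), rng.normal(size=3) * 20.0
    model_bt = model_b.transformed(rot, trans)
    assert superpose(model_a, model_bt).rmsd == pytest.approx(rmsd_ab, abs=1e-6)
    assert superpose(model_a.transformed(rot, trans), model_b).rmsd == pytest.approx(
        rmsd_ab, abs=1e-6
    )


def test_rotated_copy_superposes_to_zero():
    rng = np.random.default_rng(3)
    model, _, _ = _random_protein_model(25, rng)
    copy = model.transformed(random_rotation(rng), np.array([4.0, -7.0, 11.0]))
    res = superpose(model, copy)
    assert res.rmsd == pytest.approx(0.0, abs=1e-6)


def test_iterative_pruning_removes_displaced_outliers():
    rng = np.random.default_rng(4)
    model_a, seq, coords = _random_protein_model(50, rng)
    shifted = coords + rng.normal(size=coords.shape) * 0.1
    shifted[[5, 20, 33]] += 25.0  # three gross outliers
    model_b = model_from_ca(seq, shifted)
    res = superpose(model_a, model_b, prune_sigma=2.0, max_cycles=5)
    assert res.n_initial == 50
    assert res.n_retained == 47
    assert res.rmsd < 0.5


def test_numbering_based_pairing_available():
    rng = np.random.default_rng(5)
    model_a, seq, coords = _random_protein_model(20, rng)
    model_b = model_from_ca(seq, coords + 0.05, first_seqid=1)
    res = superpose(model_a, model_b, pair_by="numbering")
    assert res.n_initial == 20
    with pytest.raises(ValueError, match="pair_by"):
        superpose(model_a, model_b, pair_by="nonsense")


def test_too_few_pairs_is_a_degenerate_fit():
    with pytest.raises(StructureError, match=">= 3"):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# superhelix

@pytest.mark.parametrize("rise,twist,radius,n", [
    (7.0, 36.0, 25.0, 10),
    (3.0, 10.0, 10.0, 5),
    (10.0, 60.0, 40.0, 15),
    (5.5, 24.0, 18.0, 8),
])
def test_superhelix_recovers_generator_truth_within_one_percent(rise, twist, radius, n):
    model, truth, ranges = make_ideal_helix(rise, twist, radius, n, seed=17)
    params = superhelix(model, segmentation_from_ranges(ranges))
    assert params.rise == pytest.approx(truth["rise"], rel=0.01)
    assert params.twist == pytest.approx(truth["twist"], rel=0.01)
    assert params.diameter == pytest.approx(truth["diameter"], rel=0.01)
    assert params.period == pytest.approx(truth["period"], rel=0.01)
    assert params.handedness == "right"


def test_left_handed_helix_reported_left():
    model, truth, ranges = make_ideal_helix(7.0, -36.0, 25.0, 10, seed=17)
    assert superhelix(model, segmentation_from_ranges(ranges)).handedness == "left"


def test_superhelix_invariant_under_rigid_motion():
    rng = np.random.default_rng(8)
    model, truth, ranges = make_ideal_helix(7.0, 36.0, 25.0, 10, seed=2)
    seg = segmentation_from_ranges(ranges)
    moved = model.transformed(random_rotation(rng), rng.normal(size=3) * 30.0)
    p0, p1 = superhelix(model, seg), superhelix(moved, seg)
    assert p1.period == pytest.approx(p0.period, abs=1e-6)
    assert p1.diameter == pytest.approx(p0.diameter, abs=1e-6)
    assert p1.handedness == p0.handedness == "right"


def test_collinear_centroids_and_short_arrays_rejected():
    coords = np.column_stack([np.zeros(20), np.zeros(20), np.arange(20.0)])
    model = model_from_ca("A" * 20, coords)
    seg = segmentation_from_ranges([(1, 5), (6, 10), (11, 15), (16, 20)])
    with pytest.raises(StructureError, match="collinear"):
        superhelix(model, seg)
    model2, _, ranges2 = make_ideal_helix(7.0, 36.0, 25.0, 4, seed=0)
    with pytest.raises(StructureError, match="at least 4"):
        superhelix(model2, segmentation_from_ranges(ranges2[:3]))


def test_repeat_centroids_are_mean_calpha():
    model, _, ranges = make_ideal_helix(7.0, 36.0, 25.0, 5, atoms_per_repeat=4, seed=9)
    seg = segmentation_from_ranges(ranges)
    cents = repeat_centroids(model, seg)
    chain = model.protein_chain
    manual = np.mean([chain.residues[0].atoms["CA"].pos,
                      chain.residues[1].atoms["CA"].pos,
                      chain.residues[2].atoms["CA"].pos,
                      chain.residues[3].atoms["CA"].pos], axis=0)
    assert np.allclose(cents[0], manual)


# ---------------------------------------------------------------------------
# segmentation

def test_anchor_tiling_reproduces_crystal_repeat_ranges():
    rng = np.random.default_rng(10)
    model, _, _ = _random_protein_model(450, rng, first_seqid=123)
    seg = segment_repeats(model, anchor=174, n_repeats=10)
    assert (seg.segments[0].start, seg.segments[0].end) == (174, 208)
    assert (seg.segments[-1].start, seg.segments[-1].end) == (489, 523)
    # auto mode tiles as many full windows as the chain supports
    trimmed, _, _ = _random_protein_model(401, rng, first_seqid=123)  # ends at 523
    assert len(segment_repeats(trimmed, anchor=174)) == 10


def test_segmentation_errors():
    rng = np.random.default_rng(11)
    model, _, _ = _random_protein_model(60, rng)
    with pytest.raises(StructureError, match="anchor"):
        segment_repeats(model, anchor=100)
    with pytest.raises(StructureError, match="missing"):
        segment_repeats(model, anchor=40, n_repeats=2)
    with pytest.raises(StructureError, match="not 35"):
        segment_repeats(model, ranges=[(1, 30)])
    with pytest.raises(StructureError, match="overlap"):
        segment_repeats(model, ranges=[(1, 35), (20, 54)])


# ---------------------------------------------------------------------------
# recognition contacts

def test_planted_recognition_geometry_detected_exactly_once(recognition):
    model, seg = recognition
    bonds, report = find_hbonds(model, seg)
    row1, row2 = report
    assert (row1.n_direct_pos5, row1.n_direct_pos35, row1.n_water_bridges) == (1, 0, 1)
    assert (row2.n_direct_pos5, row2.n_direct_pos35, row2.n_water_bridges) == (0, 0, 0)
    direct = [b for b in bonds if not b.water_mediated]
    assert len(direct) == 1
    assert direct[0].donor == "A/ASN5/ND2" and direct[0].acceptor == "R/U1/O2"
    assert direct[0].distance == pytest.approx(2.9, abs=1e-9)
    bridges = [b for b in bonds if b.water_mediated]
    assert len(bridges) == 1
    assert bridges[0].bridging_water == "W/HOH101/O"
    # uracil N3 donates into the bridge; the Asp carboxylate accepts
    assert bridges[0].donor == "R/U1/N3" and bridges[0].acceptor == "A/ASP35/OD1"


def test_hbond_detection_invariant_under_rigid_motion(recognition):
    rng = np.random.default_rng(12)
    model, seg = recognition
    moved = model.transformed(random_rotation(rng), rng.normal(size=3) * 15.0)
    bonds_a, report_a = find_hbonds(model, seg)
    bonds_b, report_b = find_hbonds(moved, seg)
    assert report_a == report_b
    assert [b.distance for b in bonds_a] == pytest.approx(
        [b.distance for b in bonds_b], abs=1e-9
    )


def test_water_bridges_can_be_disabled(recognition):
    model, seg = recognition
    bonds, report = find_hbonds(model, seg, include_water_bridges=False)
    assert all(not b.water_mediated for b in bonds)
    assert report[0].n_water_bridges == 0


def test_no_rna_chain_is_an_explicit_error(recognition):
    model, seg = recognition
    protein_only = StructureModel([model.chains[0]])
    with pytest.raises(StructureError, match="RNA"):
        find_hbonds(protein_only, seg)


def test_guanine_read_by_td_code_gets_two_direct_pos35_bonds(recognition):
    """Asp35 accepts from both N1 and N2 of guanine (the TD/G rule)."""
    from pprkit.structgeom import Atom, Residue

    model, seg = recognition
    g = Residue("G", 1, {})
    for name, element, pos in [
        ("N1", "N", (2.1, 1.2, 4.0)), ("N2", "N", (0.9, 0.6, 5.6)),
        ("N3", "N", (0.2, 1.0, 3.0)), ("O6", "O", (4.0, 2.0, 2.0)),
        ("C2", "C", (1.0, 1.0, 4.5)), ("C4", "C", (0.8, 1.5, 2.0)),
        ("C5", "C", (2.0, 2.2, 1.5)), ("C6", "C", (3.2, 2.0, 2.8)),
        ("N7", "N", (2.2, 2.8, 0.4)), ("C8", "C", (1.0, 2.5, -0.2)),
        ("N9", "N", (0.2, 1.8, 0.7)),
    ]:
        g.add_atom(Atom(name, element, np.asarray(pos, float)))
    # distances to Asp35 OD1 (2.1, 1.2, 5.6): N1 -> 1.6 A, N2 -> 1.3 A (both < cutoff)
    swapped = StructureModel([model.chains[0],
                              type(model.chains[1])("R", [g]),
                              model.chains[2]])
    _, report = find_hbonds(swapped, seg, include_water_bridges=False)
    assert report[0].n_direct_pos35 >= 2


def test_contact_report_flags_planted_contacts_and_incomplete_repeats(recognition):
    model, seg = recognition
    rows = contact_report(model, seg)
    row1, row2 = rows
    assert row1.val2_own_base and not row1.val2_prev_base
    assert row1.lys13_salt_bridge and row1.lys13_distance <= 3.0
    assert not row1.incomplete
    assert row2.incomplete
    assert not row2.lys13_salt_bridge
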