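"""Trajectory analysis: RMSD/Rg, occupancy maps, missing contacts, t-test."""

import numpy as np
import pandas as pd
import pytest

from cmphelix import (
    NoiseProfile,
    StructureModel,
    Trajectory,
    build_ideal_helix,
    missing_contacts,
    occupancy_map,
    parse_cmp,
    per_residue_rms,
    region_rg,
    region_rmsd,
    select_region,
    simulate_trajectory,
    two_sample_test,
    TripleHelixTopology,
)
from cmphelix.contacts import build_contact_map
from cmphelix.sequence import RegionSelection
from cmphelix.structures import ATOM_COLUMNS
from cmphelix.traj import region_series

EQ_NOISE = dict(sigma_core=0.12, sigma_terminal=0.25)


def tiny_structure(coords, resnums=None):
    rows = []
    for i, (x, y, z) in enumerate(coords):
        rows.append(("A", (resnums or list(range(1, len(coords) + 1)))[i], "GLY",
                     "CA", "C", x, y, z, 20.0, 1.0))
    return StructureModel(atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS))


def test_rg_closed_forms():
    s1 = tiny_structure([(0, 0, 0)])
    t1 = Trajectory(template=s1, frames=np.array([s1.coords, s1.coords]))
    sel = RegionSelection("central", 1, 1)
    assert region_rg(t1, sel).rg[0] == 0.0
    s2 = tiny_structure([(0, 0, 0), (2, 0, 0)], resnums=[1, 1])
    t2 = Trajectory(template=s2, frames=np.array([s2.coords, s2.coords]))
    assert region_rg(t2, RegionSelection("central", 1, 1)).rg[0] == pytest.approx(1.0)


def test_empty_selection_errors(ideal, topo):
    top = topo("Ac-(GPO)3-NH2")
    traj = simulate_trajectory(ideal("Ac-(GPO)3-NH2"), top, 2, NoiseProfile(0, 0))
    with pytest.raises(ValueError):
        region_series(traj, RegionSelection("central", 50, 52))


def test_rmsd_invariant_under_rigid_motion_with_superposition(ideal, topo):
    top = topo("Ac-(GPO)5-NH2")
    traj = simulate_trajectory(ideal("Ac-(GPO)5-NH2"), top, 6,
                               NoiseProfile(0.2, 0.4, seed=3))
    sel = select_region(top, "C_terminal")
    central = select_region(top, "central")
    base = region_series(traj, sel, superpose="central-region", central=central)
    # rotate + translate every frame except frame 0 (the reference)
    rng = np.random.default_rng(4)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    shift = np.array([5.0, -3.0, 2.0])
    frames = traj.frames.copy()
    for i in range(1, frames.shape[0]):
        frames[i] = frames[i] @ Q.T + shift
    moved = Trajectory(template=traj.template, frames=frames)
    series = region_series(moved, sel, superpose="central-region", central=central)
    np.testing.assert_allclose(series.rmsd, base.rmsd, atol=1e-8)


def test_ideal_cmp2_stable_contacts_have_unit_occupancy(ideal, topo):
    top = topo("Ac-(GPO)7-NH2", "CMP2")
    traj = simulate_trajectory(ideal("Ac-(GPO)7-NH2"), top, 2, NoiseProfile(0, 0))
    omap = occupancy_map(traj, top)
    cmap = build_contact_map(top)
    for pair in cmap.pairs(classes=("stable",)):
        assert omap.occupancy(*pair) == pytest.approx(1.0)
    # symmetry and bounds
    assert np.allclose(omap.matrix, omap.matrix.T)
    assert np.all(np.diag(omap.matrix) == 0)
    assert omap.matrix.max() <= 2.0


def test_two_frame_zero_noise_equals_single_structure_detection(ideal, topo):
    from cmphelix import detect_hbonds
    from cmphelix.helix import CHAIN_IDS
    from cmphelix.sequence import global_index

    top = topo("Ac-(GPO)7-NH2")
    model = ideal("Ac-(GPO)7-NH2")
    traj = simulate_trajectory(model, top, 2, NoiseProfile(0, 0))
    omap = occupancy_map(traj, top)
    chain_no = {c: i + 1 for i, c in enumerate(CHAIN_IDS)}
    static = set()
    for b in detect_hbonds(model):
        i = global_index(top, chain_no[b.donor_chain], b.donor_resnum)
        j = global_index(top, chain_no[b.acceptor_chain], b.acceptor_resnum)
        static.add((i, j))
    nonzero = {(i + 1, j + 1) for i, j in zip(*np.nonzero(omap.matrix))}
    assert {p for p in nonzero if p[0] < p[1]} == {
        tuple(sorted(p)) for p in static
    } or nonzero == {p for q in static for p in (q, q[::-1])}


@pytest.mark.parametrize(
    "formula, name, loose, pair",
    [
        ("Ac-(POG)7-NH2", "CMP1", (2, "C"), (42, 63)),
        ("Ac-G(POG)7-NH2", "CMP3", (2, "C"), (44, 66)),
    ],
)
def test_loose_chain_reports_designated_pair(formula, name, loose, pair, ideal, topo):
    top = topo(formula, name)
    model = ideal(formula)
    traj = simulate_trajectory(model, top, 60,
                               NoiseProfile(**EQ_NOISE, loose_chain=loose, seed=17))
    omap = occupancy_map(traj, top)
    miss = missing_contacts(omap, build_contact_map(top), reference=model)
    assert pair in miss
    assert omap.occupancy(*pair) < 0.05


def test_ester_loose_run_reports_pair_against_amide_reference(ideal, topo):
    top2e = topo("Ac-(GPO)7-OCH3", "CMP2E")
    top2 = topo("Ac-(GPO)7-NH2", "CMP2")
    model2e = ideal("Ac-(GPO)7-OCH3")
    traj = simulate_trajectory(model2e, top2e, 60,
                               NoiseProfile(**EQ_NOISE, loose_chain=(1, "C"), seed=19))
    omap = occupancy_map(traj, top2e)
    miss = missing_contacts(omap, build_contact_map(top2), reference=ideal("Ac-(GPO)7-NH2"))
    assert (21, 42) in miss


def test_tight_run_reports_nothing_missing(ideal, topo):
    top = topo("Ac-(GPO)7-NH2", "CMP2")
    model = ideal("Ac-(GPO)7-NH2")
    traj = simulate_trajectory(model, top, 60, NoiseProfile(**EQ_NOISE, seed=23))
    omap = occupancy_map(traj, top)
    assert missing_contacts(omap, build_contact_map(top), reference=model) == []


def test_topology_mismatch_errors(ideal, topo):
    top2 = topo("Ac-(GPO)7-NH2", "CMP2")
    top1 = topo("Ac-(POG)7-NH2", "CMP1")
    traj = simulate_trajectory(ideal("Ac-(GPO)7-NH2"), top2, 2, NoiseProfile(0, 0))
    omap = occupancy_map(traj, top2)
    with pytest.raises(ValueError):
        missing_contacts(omap, build_contact_map(top1))


def test_tight_cterm_moves_less_than_loose(ideal, topo):
    """The GPO-capped trimer keeps a tight C-terminus: lower RMSD and
    smaller Rg than a loose POG-style run, at high significance."""
    top2 = topo("Ac-(GPO)7-NH2", "CMP2")
    top1 = topo("Ac-(POG)7-NH2", "CMP1")
    t2 = simulate_trajectory(ideal("Ac-(GPO)7-NH2"), top2, 80,
                             NoiseProfile(**EQ_NOISE, seed=29))
    t1 = simulate_trajectory(ideal("Ac-(POG)7-NH2"), top1, 80,
                             NoiseProfile(**EQ_NOISE, loose_chain=(2, "C"), seed=31))
    s2 = region_series(t2, select_region(top2, "C_terminal"))
    s1 = region_series(t1, select_region(top1, "C_terminal"))
    assert s2.rmsd_mean < s1.rmsd_mean
    assert s2.rg_mean < s1.rg_mean
    t, p = two_sample_test(s1.rmsd[1:], s2.rmsd[1:])
    assert p < 1e-3 and t > 0


def test_two_sample_test_contracts():
    assert two_sample_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)
    with pytest.raises(ValueError):
        two_sample_test([1.0, 1.0], [2.0, 2.0])
    with pytest.raises(ValueError):
        two_sample_test([1.0], [1.0, 2.0])
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 100)
    b = rng.normal(3, 1, 100)
    _, p = two_sample_test(a, b)
    assert p < 1e-3


def test_sigma_profile_recovery(ideal, topo):
    top = topo("Ac-(GPO)3-NH2")
    prof = NoiseProfile(sigma_core=0.2, sigma_terminal=0.6, ramp_length=3, seed=37)
    traj = simulate_trajectory(ideal("Ac-(GPO)3-NH2"), top, 2000, prof)
    est = per_residue_rms(traj)
    for _, row in est.iterrows():
        true = prof.sigma(int(row["resnum"]), top.L)
        assert row["sigma_est"] == pytest.approx(true, rel=0.10)


def test_trajectory_pdb_roundtrip(tmp_path, ideal, topo):
    from cmphelix import read_trajectory, write_trajectory

    top = topo("Ac-(GPO)1-NH2")
    traj = simulate_trajectory(ideal("Ac-(GPO)1-NH2"), top, 3,
                               NoiseProfile(0.2, 0.3, seed=41))
    path = tmp_path / "traj.pdb"
    write_trajectory(traj, path)
    back = read_trajectory(path)
    assert back.n_frames == 3
    assert back.frames.shape[1] == traj.frames.shape[1]
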