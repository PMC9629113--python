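"""B-factor statistics, missing-residue accounting, H-bond detection."""

import numpy as np
import pandas as pd
import pytest

from cmphelix import (
    NoiseProfile,
    StructureModel,
    count_missing_terminal,
    detect_hbonds,
    normalize_bfactors,
    parse_cmp,
    read_structure,
    synthesize_bfactors,
    terminal_deviation,
    TripleHelixTopology,
)
from cmphelix.structures import ATOM_COLUMNS


def make_structure(rows):
    return StructureModel(atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS))


def atom(chain, resnum, resname, name, element, x, y, z, b=20.0, occ=1.0):
    return (chain, resnum, resname, name, element, x, y, z, b, occ)


def test_uniform_b_normalizes_to_one():
    s = make_structure([atom("A", i, "GLY", "CA", "C", i * 3.0, 0, 0) for i in range(1, 6)])
    p = normalize_bfactors(s)
    assert np.allclose(p.atoms["b_norm"], 1.0)
    assert p.atoms["b_norm"].mean() == pytest.approx(1.0, abs=1e-12)


def test_single_atom_normalizes_to_one():
    s = make_structure([atom("A", 1, "GLY", "CA", "C", 0, 0, 0, b=37.0)])
    assert normalize_bfactors(s).atoms["b_norm"].iloc[0] == 1.0


def test_all_zero_b_raises():
    s = make_structure([atom("A", 1, "GLY", "CA", "C", 0, 0, 0, b=0.0)])
    with pytest.raises(ValueError, match="normalization undefined"):
        normalize_bfactors(s)


def test_hydrogens_waters_zero_occupancy_excluded():
    rows = [
        atom("A", 1, "GLY", "CA", "C", 0, 0, 0, b=10.0),
        atom("A", 1, "GLY", "H", "H", 1, 0, 0, b=99.0),
        atom("A", 2, "HOH", "O", "O", 9, 9, 9, b=99.0),
        atom("A", 1, "GLY", "N", "N", 2, 0, 0, b=30.0, occ=0.0),
    ]
    p = normalize_bfactors(make_structure(rows))
    assert p.mean_b == 10.0
    assert len(p.atoms) == 1


def test_normalization_mean_is_one_for_random_fields(ideal, topo):
    rng = np.random.default_rng(0)
    model = ideal("Ac-(GPO)5-NH2")
    atoms = model.atoms.copy()
    atoms["bfactor"] = rng.uniform(5, 80, size=len(atoms))
    p = normalize_bfactors(StructureModel(atoms=atoms))
    assert p.atoms["b_norm"].mean() == pytest.approx(1.0, abs=1e-12)


def test_loose_chain_field_c_exceeds_n(ideal, topo):
    top = topo("Ac-(POG)7-NH2")
    prof = NoiseProfile(0.3, 0.6, loose_chain=(2, "C"))
    model = synthesize_bfactors(ideal("Ac-(POG)7-NH2"), top, prof)
    p = normalize_bfactors(model)
    dev_c = terminal_deviation(p, top, "C")
    dev_n = terminal_deviation(p, top, "N")
    assert dev_c.value > dev_n.value


def test_raw_mode_deviation(ideal, topo):
    top = topo("Ac-(GPO)7-NH2")
    prof = NoiseProfile(0.3, 0.6)
    model = synthesize_bfactors(ideal("Ac-(GPO)7-NH2"), top, prof)
    p = normalize_bfactors(model)
    raw = terminal_deviation(p, top, "C", mode="raw")
    norm = terminal_deviation(p, top, "C", mode="normalized")
    assert raw.value == pytest.approx(norm.value * p.mean_b, rel=1e-9)


def test_terminal_deviation_undefined_when_unresolved(ideal, topo):
    top = topo("Ac-(GPO)7-NH2")
    model = ideal("Ac-(GPO)7-NH2")
    atoms = model.atoms[model.atoms["resnum"] < top.L - 2]
    p = normalize_bfactors(StructureModel(atoms=atoms.copy()))
    dev = terminal_deviation(p, top, "C")
    assert dev.value is None
    assert dev.n_missing == 9


def test_count_missing_terminal(ideal, topo):
    top = topo("Ac-(GPO)7-NH2")
    model = ideal("Ac-(GPO)7-NH2")
    assert count_missing_terminal(model, top) == (0, 0)
    a = model.atoms
    one_gone = StructureModel(atoms=a[~((a["chain"] == "B") & (a["resnum"] == 21))].copy())
    assert count_missing_terminal(one_gone, top) == (0, 1)
    two_gone = StructureModel(
        atoms=a[~(a["chain"].isin(["B", "C"]) & (a["resnum"] == 21))].copy()
    )
    assert count_missing_terminal(two_gone, top) == (0, 2)


def test_count_missing_needs_declared_sequence():
    s = make_structure([atom("A", 1, "GLY", "CA", "C", 0, 0, 0)])
    with pytest.raises(ValueError, match="topology"):
        count_missing_terminal(s)


def test_count_missing_from_seqres(tmp_path, ideal, topo):
    from cmphelix import write_pdb

    top = topo("Ac-(GPO)7-NH2")
    model = ideal("Ac-(GPO)7-NH2")
    a = model.atoms
    truncated = StructureModel(
        atoms=a[~((a["chain"] == "C") & (a["resnum"] == 21))].copy(),
        seqres=model.seqres, name="trunc",
    )
    path = tmp_path / "trunc.pdb"
    write_pdb(truncated, path)
    back = read_structure(path)
    assert back.seqres is not None
    assert count_missing_terminal(back) == (0, 1)


ALTLOC_PDB = """\
ATOM      1  N  AGLY A   1       0.000   0.000   0.000  0.60 10.00           N
ATOM      2  N  BGLY A   1       0.500   0.000   0.000  0.40 12.00           N
ATOM      3  CA  GLY A   1       1.500   0.000   0.000  1.00 11.00           C
ATOM      4  CA APRO A   2       3.000   0.000   0.000  0.50 11.00           C
ATOM      5  CA BPRO A   2       3.400   0.000   0.000  0.50 13.00           C
END
"""


def test_altloc_one_atom_per_site(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    s = read_structure(path)
    n_atoms = s.atoms[s.atoms["atom"] == "N"]
    assert len(n_atoms) == 1
    assert n_atoms["occupancy"].iloc[0] == pytest.approx(0.60)  # highest occupancy kept
    ca2 = s.atoms[(s.atoms["resnum"] == 2) & (s.atoms["atom"] == "CA")]
    assert len(ca2) == 1
    assert ca2["x"].iloc[0] == pytest.approx(3.0)  # tie broken alphabetically


def test_unparseable_file_raises(tmp_path):
    bad = tmp_path / "bad.cif"
    bad.write_text("this is not a structure\n")
    with pytest.raises(ValueError):
        read_structure(bad)


def test_two_atoms_beyond_cutoff_not_detected():
    rows = [
        atom("A", 1, "GLY", "N", "N", 0, 0, 0),
        atom("B", 1, "PRO", "O", "O", 4.0, 0, 0),
    ]
    assert detect_hbonds(make_structure(rows), d_max=3.5) == []


def brute_force_hbonds(structure, d_max=3.5, angle_min=120.0, proxy_angle_min=90.0):
    """O(n^2) reference scan with the same donor/acceptor and angle rules."""
    a = structure.atoms.reset_index(drop=True)
    xyz = structure.coords
    last = a.groupby("chain")["resnum"].transform("max")
    donors = a[((a["atom"] == "N") & (a["resname"] == "GLY")) | (a["atom"] == "NT")]
    acceptors = a[(a["atom"] == "O") & ((a["resname"] == "PRO") | (a["resnum"] == last))]
    found = set()
    for di in donors.index:
        for ai in acceptors.index:
            if (a.at[di, "chain"], a.at[di, "resnum"]) == (a.at[ai, "chain"], a.at[ai, "resnum"]):
                continue
            d = np.linalg.norm(xyz[di] - xyz[ai])
            if d > d_max:
                continue
            res = a[(a["chain"] == a.at[di, "chain"]) & (a["resnum"] == a.at[di, "resnum"])]
            if a.at[di, "atom"] == "NT":
                hs = res[res["atom"].isin(["HT1", "HT2"])]
            else:
                hs = res[res["atom"] == "H"]
            if len(hs):
                ok = False
                for hi in hs.index:
                    v1, v2 = xyz[di] - xyz[hi], xyz[ai] - xyz[hi]
                    ang = np.degrees(
                        np.arccos(np.clip(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1))
                    )
                    ok = ok or ang >= angle_min
                if not ok:
                    continue
            else:
                ca = res[res["atom"] == "CA"]
                if len(ca):
                    ci = ca.index[0]
                    v1, v2 = xyz[ci] - xyz[di], xyz[ai] - xyz[di]
                    ang = np.degrees(
                        np.arccos(np.clip(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1))
                    )
                    if ang < proxy_angle_min:
                        continue
            found.add((a.at[di, "chain"], int(a.at[di, "resnum"]), a.at[di, "atom"],
                       a.at[ai, "chain"], int(a.at[ai, "resnum"])))
    return found


@pytest.mark.parametrize("formula", ["Ac-(GPO)7-NH2", "Ac-(POG)7-NH2", "Ac-G(POG)7-NH2"])
def test_detector_equals_brute_force_on_ideal_builds(formula, ideal):
    model = ideal(formula)
    got = {(b.donor_chain, b.donor_resnum, b.donor_atom,
            b.acceptor_chain, b.acceptor_resnum) for b in detect_hbonds(model)}
    assert got == brute_force_hbonds(model)


def test_detector_equals_brute_force_on_noisy_frame(ideal, topo):
    from cmphelix import simulate_trajectory

    top = topo("Ac-(GPO)7-NH2")
    traj = simulate_trajectory(ideal("Ac-(GPO)7-NH2"), top, 3,
                               NoiseProfile(0.3, 0.6, seed=13))
    frame = traj.frame(2)
    got = {(b.donor_chain, b.donor_resnum, b.donor_atom,
            b.acceptor_chain, b.acceptor_resnum) for b in detect_hbonds(frame)}
    assert got == brute_force_hbonds(frame)


def test_terminal_amide_bonds_to_partner_carbonyl(ideal):
    bonds = detect_hbonds(ideal("Ac-(GPO)7-NH2"))
    nt = [b for b in bonds if b.donor_atom == "NT"]
    assert len(nt) == 3
    assert all(b.interchain for b in nt)


def test_heavy_atom_proxy_angle_when_h_absent():
    # donor N with CA behind it, acceptor in front: proxy angle ~180 -> bond
    rows = [
        atom("A", 1, "GLY", "N", "N", 0, 0, 0),
        atom("A", 1, "GLY", "CA", "C", -1.5, 0, 0),
        atom("B", 1, "PRO", "O", "O", 3.0, 0, 0),
    ]
    bonds = detect_hbonds(make_structure(rows))
    assert len(bonds) == 1 and bonds[0].angle == pytest.approx(180.0)
    # acceptor on the CA side: proxy angle 0 -> rejected
    rows[2] = atom("B", 1, "PRO", "O", "O", -3.0, 0, 0)
    assert detect_hbonds(make_structure(rows)) == []
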