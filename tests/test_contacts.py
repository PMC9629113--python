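"""Rule-model contact enumeration, classification and ranking."""

import pytest

from cmphelix import (
    TripleHelixTopology,
    build_contact_map,
    classify_contacts,
    enumerate_contacts,
    parse_cmp,
    rank_charge_impact,
    rank_stability,
)
from cmphelix.contacts import contact_map_to_dot, contact_map_to_tsv


def brute_force_gly_donor_pairs(seq):
    """Independent enumeration of the pairing rule: every Gly at p < L whose
    successor is Pro donates to (partner chain, p+1); a terminal Gly/Sar
    tethers the partner chain's terminal residue."""
    out = set()
    L = len(seq.residues)
    for c in (1, 2, 3):
        partner = c % 3 + 1
        for p in range(1, L + 1):
            if seq.residues[p - 1] not in "GZ":
                continue
            if p < L and seq.residues[p] == "P":
                out.add((c, p, partner, p + 1))
            elif p == L:
                out.add((c, L, partner, L))
    return out


@pytest.mark.parametrize("form", ["GPO", "POG", "OGP"])
@pytest.mark.parametrize("n", [1, 2, 5, 7, 10])
def test_donor_conservation_vs_brute_force(form, n):
    seq = parse_cmp(f"Ac-({form}){n}-NH2")
    cmap = enumerate_contacts(TripleHelixTopology(seq))
    got = {
        (c.donor_chain, c.donor_pos, c.acceptor_chain, c.acceptor_pos)
        for c in cmap.contacts
        if c.donor_group in ("Gly_NH", "Sar_N")
    }
    assert got == brute_force_gly_donor_pairs(seq)


def test_single_repeat_trimer_hand_enumeration():
    # (GPO)1 trimer, L=3: one Gly per chain at p=1 donating to Pro p=2 of the
    # partner chain (3 contacts), plus 3 terminal-amide slots on Hyp.
    cmap = build_contact_map(TripleHelixTopology(parse_cmp("Ac-(GPO)1-NH2")))
    assert len(cmap.contacts) == 6
    # first-position Gly donates weakly; Hyp-amide cap contacts are stable
    assert cmap.n_stable == 3 and cmap.n_weak == 3 and cmap.n_absent == 0


def test_terminal_amide_slots_on_gpo():
    cmap = enumerate_contacts(TripleHelixTopology(parse_cmp("Ac-(GPO)7-NH2")))
    caps = [c for c in cmap.contacts if c.donor_group == "terminal_amide_NH2"]
    assert len(caps) == 3
    assert all(c.region == "C_terminal" and c.donor_pos == 21 for c in caps)


def test_ogp_missing_donor_slots():
    cmap = build_contact_map(TripleHelixTopology(parse_cmp("Ac-(OGP)7-NH2")))
    slots = [c for c in cmap.contacts if c.donor_group is None]
    assert len(slots) == 3
    assert all(c.contact_class == "absent" for c in slots)


def test_stable_gap_is_three_terminal_amide_contacts(topo):
    m2 = build_contact_map(topo("Ac-(GPO)7-NH2", "CMP2"))
    m1 = build_contact_map(topo("Ac-(POG)7-NH2", "CMP1"))
    assert m2.n_stable - m1.n_stable == 3
    caps = [c for c in m2.contacts if c.donor_group == "terminal_amide_NH2"]
    assert sum(c.contact_class == "stable" for c in caps) == 3


def test_ester_cap_contacts_absent(topo):
    m2e = build_contact_map(topo("Ac-(GPO)7-OCH3", "CMP2E"))
    caps = [c for c in m2e.contacts if c.donor_group == "terminal_amide_NH2"]
    assert caps and all(c.contact_class == "absent" for c in caps)


def test_all_sar_chain_every_contact_absent():
    cmap = build_contact_map(TripleHelixTopology(parse_cmp("Ac-(ZZZ)3-NH2")))
    assert cmap.contacts and all(c.contact_class == "absent" for c in cmap.contacts)


def test_sar_substitution_removes_single_donor():
    ref = build_contact_map(TripleHelixTopology(parse_cmp("Ac-G(POG)7-NH2")))
    sar = build_contact_map(TripleHelixTopology(parse_cmp("Ac-Z(POG)7-NH2")))
    assert sar.n_absent - ref.n_absent == 3  # one donor per chain lost


def test_rank_amide_series_gpo_first(topo):
    maps = [
        build_contact_map(topo(f"Ac-({t})7-NH2", t)) for t in ("GPO", "POG", "OGP")
    ]
    order = rank_stability(maps)
    assert order[0] == ["GPO"]
    assert order == [["GPO"], ["OGP"], ["POG"]]


def test_rank_carboxylate_series(topo):
    maps = [
        build_contact_map(topo(f"Ac-({t})7-OH", t)) for t in ("GPO", "OGP", "POG")
    ]
    assert rank_stability(maps) == [["GPO"], ["OGP"], ["POG"]]


def test_rank_identical_sequences_tie(topo):
    m = build_contact_map(topo("Ac-(GPO)7-NH2", "a"))
    m2 = build_contact_map(topo("Ac-(GPO)7-NH2", "a"))
    groups = rank_stability([m, m2])
    assert len(groups) == 1 and len(groups[0]) == 2


def test_rank_unequal_lengths_error(topo):
    m7 = build_contact_map(topo("Ac-(GPO)7-NH2"))
    m8 = build_contact_map(topo("Ac-(GPO)8-NH2"))
    with pytest.raises(ValueError):
        rank_stability([m7, m8])


def test_charge_impact_orderings(topo):
    nh2 = {t: build_contact_map(topo(f"Ac-({t})7-NH2", t)) for t in ("GPO", "POG", "OGP")}
    oh = {t: build_contact_map(topo(f"Ac-({t})7-OH", t)) for t in ("GPO", "POG", "OGP")}
    h = {t: build_contact_map(topo(f"H-({t})7-NH2", t)) for t in ("GPO", "POG", "OGP")}
    c_impact = [x[0] for x in rank_charge_impact([(nh2[t], oh[t]) for t in nh2])]
    n_impact = [x[0] for x in rank_charge_impact([(nh2[t], h[t]) for t in nh2])]
    assert c_impact == ["GPO", "OGP", "POG"]
    assert n_impact == ["POG", "GPO", "OGP"]


@pytest.mark.parametrize("form", ["GPO", "POG", "OGP"])
def test_appending_triplet_never_decreases_stable(form):
    for n in range(2, 7):
        a = build_contact_map(TripleHelixTopology(parse_cmp(f"Ac-({form}){n}-NH2")))
        seq_plus = parse_cmp(f"Ac-({form}){n}-NH2").residues + "GPO"
        from cmphelix.sequence import CMPSequence

        b = build_contact_map(
            TripleHelixTopology(CMPSequence(residues=seq_plus, c_cap="amide"))
        )
        assert b.n_stable >= a.n_stable


@pytest.mark.parametrize("form", ["GPO", "POG", "OGP"])
def test_amide_to_ester_never_increases_stable(form):
    amide = build_contact_map(TripleHelixTopology(parse_cmp(f"Ac-({form})7-NH2")))
    ester = build_contact_map(TripleHelixTopology(parse_cmp(f"Ac-({form})7-OCH3")))
    assert ester.n_stable <= amide.n_stable


def test_terminal_pairs_match_reported_indices(topo):
    m1 = build_contact_map(topo("Ac-(POG)7-NH2", "CMP1"))
    assert (42, 63) in m1.pairs()
    m2 = build_contact_map(topo("Ac-(GPO)7-NH2", "CMP2"))
    assert {(21, 42), (42, 63), (63, 21)} <= set(m2.pairs())


def test_exports(topo):
    cmap = build_contact_map(topo("Ac-(GPO)2-NH2"))
    tsv = contact_map_to_tsv(cmap)
    assert tsv.count("\n") == len(cmap.contacts) + 1
    dot = contact_map_to_dot(cmap)
    assert dot.startswith("graph") and "--" in dot
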