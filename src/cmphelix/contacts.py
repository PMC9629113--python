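"""Rule-based interchain H-bond contact map of a CMP homotrimer.

The canonical collagen interchain hydrogen bond is donated by a Gly amide
N-H and accepted by the carbonyl O of the Pro that follows it in sequence,
on the adjacent chain.  Because every repeat form (GPO, POG, OGP) is the
same cyclic ...G-P-O... sequence read in a different frame, a single pairing
rule covers all three: the Gly at position p of chain c donates to the
carbonyl of position p+1 of chain c+1 (cyclic, 3 -> 1).  Under the
one-residue stagger the 3 -> 1 partner is the chain-1 residue one triplet
down the superhelix, which is exactly position p+1 of chain 1.

Contacts are discrete objects classified ``stable`` / ``weak`` / ``absent``
by an ordered rule set calibrated against the ordinal melting-temperature
evidence (no per-bond energies are claimed):

* a Gly-donated contact is stable by default;
* Sar in the donor position, or a donor group that chemically lacks the
  amide hydrogen (ester / carboxylate cap), makes the contact absent;
* a Gly at chain position 1 donates only weakly (an appended N-terminal
  Gly raises Tm by only ~2 C);
* a contact accepting at the chain-terminal carbonyl is weak (terminal
  fraying: the flexible chain end interferes);
* the terminal-amide cap contact is stable on a Hyp-ended chain (the
  Hyp-CONH2...Pro-CO geometry seen in GPO-type crystals), weak on a
  Pro-ended chain, absent for ester or carboxylate caps;
* terminal charges downgrade contacts near the charged end (see
  :func:`classify_contacts`).

Absent contacts are retained in the map: they document bonds that *cannot*
form.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

from .sequence import CMPSequence, TripleHelixTopology, global_index

__all__ = [
    "HBondContact",
    "ContactMap",
    "enumerate_contacts",
    "classify_contacts",
    "build_contact_map",
    "stability_score",
    "rank_stability",
    "rank_charge_impact",
    "contact_map_to_tsv",
    "contact_map_to_dot",
]

ContactClass = Literal["stable", "weak", "absent"]

_CLASS_LEVEL = {"stable": 2, "weak": 1, "absent": 0}
_LEVEL_CLASS = {v: k for k, v in _CLASS_LEVEL.items()}


@dataclass(frozen=True)
class HBondContact:
    """One enumerated donor -> acceptor slot between adjacent chains."""

    donor_chain: int
    donor_pos: int | None  # None for the missing-Gly slot of a Pro-ended chain
    donor_group: str | None  # "Gly_NH", "terminal_amide_NH2", "Sar_N", None
    acceptor_chain: int
    acceptor_pos: int
    acceptor_group: str  # "Pro_CO" or "terminal_CO"
    region: Literal["internal", "N_terminal", "C_terminal"]
    contact_class: ContactClass = "stable"

    def downgraded(self, levels: int = 1) -> "HBondContact":
        lvl = max(0, _CLASS_LEVEL[self.contact_class] - levels)
        return replace(self, contact_class=_LEVEL_CLASS[lvl])


@dataclass(frozen=True)
class ContactMap:
    """All enumerated contacts of one homotrimer topology."""

    topology: TripleHelixTopology
    contacts: tuple[HBondContact, ...]
    label: str = ""

    @property
    def counts(self) -> Counter:
        return Counter(c.contact_class for c in self.contacts)

    @property
    def n_stable(self) -> int:
        return self.counts["stable"]

    @property
    def n_weak(self) -> int:
        return self.counts["weak"]

    @property
    def n_absent(self) -> int:
        return self.counts["absent"]

    def pairs(self, classes: Sequence[str] = ("stable", "weak")) -> list[tuple[int, int]]:
        """Global residue-index pairs (donor, acceptor) of selected classes.

        The cap donor rides on the terminal residue of its chain, so the
        C-terminal-most contacts come out as pairs of terminal residues —
        e.g. (21, 42) for the chain-1 -> chain-2 cap contact at L=21.
        """
        out = []
        for c in self.contacts:
            if c.contact_class not in classes or c.donor_pos is None:
                continue
            out.append(
                (
                    global_index(self.topology, c.donor_chain, c.donor_pos),
                    global_index(self.topology, c.acceptor_chain, c.acceptor_pos),
                )
            )
        return out


def _region(pos: int, L: int) -> str:
    if pos <= 3:
        return "N_terminal"
    if pos >= L - 2:
        return "C_terminal"
    return "internal"


def enumerate_contacts(topology: TripleHelixTopology) -> ContactMap:
    """Enumerate every interchain donor -> acceptor slot of the trimer.

    Donor slots are every Gly (or Sar, documenting the lost donor) with an
    adjacent-chain partner, the terminal amide NH2 of each chain when the
    C-terminal residue is Hyp or Pro, and — for Pro-ended (OGP-type)
    chains — the slot of the Gly that the repeat would place after the
    final Pro, recorded with no available donor.
    """
    seq = topology.sequence
    L = seq.L
    contacts: list[HBondContact] = []
    for c in (1, 2, 3):
        partner = c % 3 + 1
        for p in range(1, L + 1):
            res = seq.residue(p)
            if res not in ("G", "Z"):
                continue
            group = "Gly_NH" if res == "G" else "Sar_N"
            if p < L:
                if seq.residue(p + 1) != "P":
                    continue  # no adjacent-chain Pro acceptor for this Gly
                contacts.append(
                    HBondContact(
                        donor_chain=c,
                        donor_pos=p,
                        donor_group=group,
                        acceptor_chain=partner,
                        acceptor_pos=p + 1,
                        acceptor_group="Pro_CO",
                        region=_region(p, L),
                    )
                )
            else:
                # chain-terminal Gly: tethers the two chain ends via the
                # partner chain's terminal carbonyl
                contacts.append(
                    HBondContact(
                        donor_chain=c,
                        donor_pos=L,
                        donor_group=group,
                        acceptor_chain=partner,
                        acceptor_pos=L,
                        acceptor_group="terminal_CO",
                        region="C_terminal",
                    )
                )
        last = seq.residue(L)
        if last in ("O", "P"):
            # terminal amide NH2 donor slot (cap rides on residue L)
            contacts.append(
                HBondContact(
                    donor_chain=c,
                    donor_pos=L,
                    donor_group="terminal_amide_NH2",
                    acceptor_chain=partner,
                    acceptor_pos=L,
                    acceptor_group="terminal_CO",
                    region="C_terminal",
                )
            )
        if last == "P":
            # OGP-type end: the repeat's next Gly does not exist
            contacts.append(
                HBondContact(
                    donor_chain=c,
                    donor_pos=None,
                    donor_group=None,
                    acceptor_chain=partner,
                    acceptor_pos=L,
                    acceptor_group="terminal_CO",
                    region="C_terminal",
                    contact_class="absent",
                )
            )
    return ContactMap(topology=topology, contacts=tuple(contacts), label=seq.name)


def classify_contacts(cmap: ContactMap, seq: CMPSequence | None = None) -> ContactMap:
    """Assign stable/weak/absent classes with the calibrated rule set."""
    seq = seq or cmap.topology.sequence
    L = seq.L
    last = seq.residue(L)
    first = seq.residues[0]
    first_gly = min(seq.gly_positions(), default=None)
    out: list[HBondContact] = []
    for c in cmap.contacts:
        if c.donor_group is None or c.donor_group == "Sar_N":
            out.append(replace(c, contact_class="absent"))
            continue
        if c.donor_group == "terminal_amide_NH2":
            if seq.c_cap != "amide":
                cls = "absent"  # ester / carboxylate: no amide hydrogens
            elif last == "O":
                cls = "stable"  # Hyp-CONH2...CO geometry of GPO-type ends
            else:
                cls = "weak"  # Pro-amide: weaker, no ring hydroxyl
            out.append(replace(c, contact_class=cls))
            continue
        # Gly_NH donors
        cls = "stable"
        if c.donor_pos == 1:
            cls = "weak"  # N-terminal Gly donates only weakly
        if c.acceptor_pos == L:
            cls = "weak"  # accepting at the frayed chain terminus
        contact = replace(c, contact_class=cls)
        if seq.c_cap == "carboxylate":
            # terminal negative charge perturbs the C-end contacts
            if last in ("G", "Z") and c.donor_pos == L - 3:
                contact = contact.downgraded()
            if last == "P" and c.acceptor_pos == L:
                contact = contact.downgraded()
        if seq.n_cap == "free_amine" and c.donor_pos == first_gly:
            # protonated N-terminus at pH 7.4: charge repulsion, graded by
            # the residue bearing the charge
            levels = {"P": 2, "G": 1}.get(first, 0)
            contact = contact.downgraded(levels)
        out.append(contact)
    return ContactMap(topology=cmap.topology, contacts=tuple(out), label=cmap.label)


def build_contact_map(topology: TripleHelixTopology) -> ContactMap:
    """Enumerate and classify in one step."""
    return classify_contacts(enumerate_contacts(topology))


def stability_score(cmap: ContactMap, weak_weight: float = 0.4) -> float:
    """Scalar ordinal score: stable counts 1, weak counts ``weak_weight``.

    Purely ordinal — used for ranking, not as an energy.
    """
    return cmap.n_stable + weak_weight * cmap.n_weak


def rank_stability(maps: Sequence[ContactMap]) -> list[list[str]]:
    """Order contact maps by (stable count, weak count), best first.

    A weak bond beats no bond, so among equal stable counts more weak
    contacts rank higher.  Ties are reported as tie groups (inner lists).
    Sequences of unequal length cannot be ranked against each other.
    """
    if len(maps) < 2:
        raise ValueError("need at least two contact maps to rank")
    lengths = {m.topology.L for m in maps}
    if len(lengths) > 1:
        raise ValueError(f"ranking undefined across chain lengths {sorted(lengths)}")
    keyed = sorted(maps, key=lambda m: (m.n_stable, m.n_weak), reverse=True)
    groups: list[list[str]] = []
    prev = None
    for m in keyed:
        key = (m.n_stable, m.n_weak)
        if key == prev:
            groups[-1].append(m.label)
        else:
            groups.append([m.label])
        prev = key
    return groups


def rank_charge_impact(
    pairs: Sequence[tuple[ContactMap, ContactMap]],
    weak_weight: float = 0.4,
) -> list[tuple[str, float]]:
    """Rank (neutral, charged) map pairs by the score drop the charge causes.

    Reproduces the published orderings of terminal-charge impact: for the
    C-terminal carboxylate GPO > OGP > POG, for the N-terminal ammonium
    POG > GPO > OGP.  Returns (label, impact) sorted by impact, largest
    first.
    """
    out = []
    for neutral, charged in pairs:
        drop = stability_score(neutral, weak_weight) - stability_score(charged, weak_weight)
        out.append((charged.label or neutral.label, drop))
    return sorted(out, key=lambda t: -t[1])


def contact_map_to_tsv(cmap: ContactMap) -> str:
    """TSV export: one line per contact."""
    lines = [
        "donor_chain\tdonor_index\tacceptor_chain\tacceptor_index\tdonor_group\tregion\tclass"
    ]
    for c in cmap.contacts:
        d_idx = (
            global_index(cmap.topology, c.donor_chain, c.donor_pos)
            if c.donor_pos is not None
            else ""
        )
        a_idx = global_index(cmap.topology, c.acceptor_chain, c.acceptor_pos)
        lines.append(
            f"{c.donor_chain}\t{d_idx}\t{c.acceptor_chain}\t{a_idx}\t"
            f"{c.donor_group or 'none'}\t{c.region}\t{c.contact_class}"
        )
    return "\n".join(lines) + "\n"


def contact_map_to_dot(cmap: ContactMap) -> str:
    """DOT-style diagram of the contact map, for documentation."""
    style = {"stable": "solid", "weak": "dashed", "absent": "dotted"}
    lines = [f'graph "{cmap.label or "contact map"}" {{']
    for c in cmap.contacts:
        if c.donor_pos is None:
            continue
        d = f"c{c.donor_chain}r{c.donor_pos}"
        a = f"c{c.acceptor_chain}r{c.acceptor_pos}"
        lines.append(f'  {d} -- {a} [style={style[c.contact_class]}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
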