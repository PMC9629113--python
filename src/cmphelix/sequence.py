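"""Collagen-mimetic peptide (CMP) sequences and triple-helix topology.

A CMP is a short Gly-X-Y peptide, here restricted to the Gly (G), Pro (P),
4-hydroxyproline (Hyp, O) and sarcosine (Sar, Z) alphabet, written in the
field's formula notation, e.g. ``Ac-(POG)7-NH2`` or ``Ac-G(POG)7-NH2``.
Three identical chains associate into a homotrimeric triple helix with a
one-residue axial stagger; residues are numbered 1-based per chain and
globally by concatenating chains 1, 2, 3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import ceil
from typing import Literal, Sequence

__all__ = [
    "CMPSequence",
    "TripleHelixTopology",
    "RegionSelection",
    "ParseError",
    "parse_cmp",
    "format_cmp",
    "global_index",
    "chain_position",
    "select_region",
    "terminal_repeat_class",
]

#: single-letter residue alphabet
RESIDUES = ("G", "P", "O", "Z")

RESIDUE_NAMES = {"G": "Gly", "P": "Pro", "O": "Hyp", "Z": "Sar"}

#: three-letter PDB-style residue names used when writing structures
RESIDUE_PDB = {"G": "GLY", "P": "PRO", "O": "HYP", "Z": "SAR"}

#: repeat form implied by the residue opening the dominant triplet frame
FORM_BY_LEAD = {"G": "GPO", "P": "POG", "O": "OGP"}

N_CAPS = {"Ac": "acetyl", "H": "free_amine"}
C_CAPS = {"NH2": "amide", "OH": "carboxylate", "OCH3": "ester"}
N_CAP_TOKEN = {v: k for k, v in N_CAPS.items()}
C_CAP_TOKEN = {v: k for k, v in C_CAPS.items()}


class ParseError(ValueError):
    """Raised when a CMP formula string does not match the grammar."""


@dataclass(frozen=True)
class CMPSequence:
    """A parsed CMP chain.

    Parameters
    ----------
    name:
        Free-form label (defaults to the canonical formula).
    residues:
        Expanded single-letter residue string over ``G/P/O/Z``.
    repeat_form:
        ``"GPO"``, ``"POG"``, ``"OGP"`` or ``"irregular"``, determined by the
        residue class at position 1 of the dominant triplet frame.
    n_repeats:
        Number of complete triplets in the dominant frame.
    n_cap, c_cap:
        Terminal chemistry; the free N-terminal amine is a cap state
        (protonated at the registry's default pH 7.4), not a residue.
    """

    residues: str
    n_cap: Literal["acetyl", "free_amine"] = "acetyl"
    c_cap: Literal["amide", "carboxylate", "ester"] = "amide"
    name: str = ""
    # pieces preserved for exact round-tripping of the formula
    _prefix: str = ""
    _triplet: str = ""
    _count: int = 0
    _suffix: str = ""
    repeat_form: str = field(init=False)
    n_repeats: int = field(init=False)
    frame_offset: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.residues) < 3:
            raise ParseError(
                f"chain length must be >= 3, got {len(self.residues)}"
            )
        bad = set(self.residues) - set(RESIDUES)
        if bad:
            raise ParseError(f"unknown residue letter(s): {sorted(bad)}")
        form, n_rep, offset = _dominant_frame(self.residues)
        object.__setattr__(self, "repeat_form", form)
        object.__setattr__(self, "n_repeats", n_rep)
        object.__setattr__(self, "frame_offset", offset)
        if not self.name:
            object.__setattr__(self, "name", format_cmp(self))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def L(self) -> int:
        return len(self.residues)

    def gly_positions(self) -> list[int]:
        """1-based positions of Gly residues (Sar excluded: no amide H)."""
        return [i + 1 for i, r in enumerate(self.residues) if r == "G"]

    def residue(self, position: int) -> str:
        """Single-letter residue at a 1-based position."""
        if not 1 <= position <= self.L:
            raise IndexError(f"position {position} outside 1..{self.L}")
        return self.residues[position - 1]


def _dominant_frame(residues: str) -> tuple[str, int, int]:
    """Pick the triplet frame best matching a cyclic G-P-O repeat.

    Sar (Z) substitutes for any residue when scoring, since it appears as a
    point substitution in otherwise regular hosts.  Returns
    ``(repeat_form, n_repeats, frame_offset)`` with ``frame_offset`` the
    0-based index where the first complete triplet starts; ties go to the
    smallest offset.
    """
    L = len(residues)
    cyc = "GPO"
    best = (-1, 0, 0)  # (score, -offset placeholder handled by order)
    for off in range(3):
        n_trip = (L - off) // 3
        if n_trip < 1:
            continue
        lead = residues[off]
        if lead == "Z":
            # infer the intended lead from the following residue
            nxt = residues[off + 1] if off + 1 < L else "P"
            idx = (cyc.index(nxt) - 1) % 3 if nxt in cyc else 0
            lead_eff = cyc[idx]
        elif lead in cyc:
            lead_eff = lead
        else:
            continue
        k = cyc.index(lead_eff)
        score = 0
        for i in range(off, off + 3 * n_trip):
            want = cyc[(k + (i - off)) % 3]
            got = residues[i]
            if got == want or got == "Z":
                score += 1
        if score > best[0]:
            best = (score, off, n_trip)
    score, off, n_trip = best
    if score < 0 or score < 0.8 * 3 * n_trip:
        return "irregular", 0, 0
    lead = residues[off]
    if lead == "Z":
        nxt = residues[off + 1] if off + 1 < len(residues) else "P"
        lead = cyc[(cyc.index(nxt) - 1) % 3] if nxt in cyc else "G"
    return FORM_BY_LEAD[lead], n_trip, off


_FORMULA_RE = re.compile(
    r"^(?P<ncap>Ac|H)-"
    r"(?P<prefix>(?:Sar|[GPOZ])*)"
    r"\((?P<triplet>(?:Sar|[GPOZ]){3})\)(?P<count>\d+)"
    r"(?P<suffix>(?:Sar|[GPOZ])*)"
    r"-(?P<ccap>NH2|OH|OCH3)$"
)


def _expand(tokens: str) -> str:
    """Expand residue tokens (``Sar`` or single letters) to single letters."""
    return tokens.replace("Sar", "Z")


def parse_cmp(formula: str, name: str = "") -> CMPSequence:
    """Parse a CMP formula string such as ``Ac-(POG)7-NH2``.

    Grammar: ``CAP "-" [prefix] "(" triplet ")" count [suffix] "-" CAP`` with
    N-cap in ``{Ac, H}`` and C-cap in ``{NH2, OH, OCH3}``; residue tokens are
    the single letters G/P/O/Z or the token ``Sar``.

    Raises
    ------
    ParseError
        Naming the offending token when the formula is malformed.
    """
    s = formula.strip()
    m = _FORMULA_RE.match(s)
    if m is None:
        # produce a pointed error message
        if "-" not in s:
            raise ParseError(f"malformed formula {formula!r}: missing cap separators '-'")
        head = s.split("-", 1)[0]
        if head not in N_CAPS:
            raise ParseError(f"malformed formula {formula!r}: unknown N-cap token {head!r}")
        tail = s.rsplit("-", 1)[-1]
        if tail not in C_CAPS:
            raise ParseError(f"malformed formula {formula!r}: unknown C-cap token {tail!r}")
        body = s[len(head) + 1 : len(s) - len(tail) - 1]
        bad = re.sub(r"Sar|[GPOZ()\d]", "", body)
        if bad:
            raise ParseError(
                f"malformed formula {formula!r}: unknown residue letter {bad[0]!r}"
            )
        raise ParseError(f"malformed formula {formula!r}: does not match grammar")
    prefix = _expand(m["prefix"])
    triplet = _expand(m["triplet"])
    suffix = _expand(m["suffix"])
    count = int(m["count"])
    if count < 1:
        raise ParseError(f"malformed formula {formula!r}: repeat count must be >= 1")
    residues = prefix + triplet * count + suffix
    return CMPSequence(
        residues=residues,
        n_cap=N_CAPS[m["ncap"]],
        c_cap=C_CAPS[m["ccap"]],
        name=name,
        _prefix=prefix,
        _triplet=triplet,
        _count=count,
        _suffix=suffix,
    )


def format_cmp(seq: CMPSequence) -> str:
    """Canonical formula string; inverse of :func:`parse_cmp`."""
    if seq._triplet and seq._count:
        body = f"{seq._prefix}({seq._triplet}){seq._count}{seq._suffix}"
    else:
        # sequence constructed directly from residues: factor greedily
        form, n_rep, off = _dominant_frame(seq.residues)
        if form != "irregular" and n_rep >= 1:
            trip = seq.residues[off : off + 3]
            body = f"{seq.residues[:off]}({trip}){n_rep}{seq.residues[off + 3 * n_rep:]}"
        else:
            body = f"({seq.residues})1" if len(seq.residues) == 3 else seq.residues
    return f"{N_CAP_TOKEN[seq.n_cap]}-{body}-{C_CAP_TOKEN[seq.c_cap]}"


@dataclass(frozen=True)
class TripleHelixTopology:
    """Homotrimeric triple helix: three identical chains, 1-residue stagger.

    Chain 1 is the leading chain; global residue numbering concatenates
    chains in order 1, 2, 3, so ``global = (chain-1)*L + position``.
    """

    sequence: CMPSequence
    stagger: int = 1

    def __post_init__(self) -> None:
        if self.stagger < 0 or self.stagger >= self.L:
            raise ValueError(
                f"stagger {self.stagger} inconsistent with chain length {self.L}"
            )

    @property
    def L(self) -> int:
        return self.sequence.L

    @property
    def chains(self) -> tuple[CMPSequence, CMPSequence, CMPSequence]:
        return (self.sequence, self.sequence, self.sequence)

    def same_chain_topology(self, other: "TripleHelixTopology") -> bool:
        """True when residues and stagger match (caps may differ)."""
        return (
            self.sequence.residues == other.sequence.residues
            and self.stagger == other.stagger
        )


def global_index(topology: TripleHelixTopology, chain: int, position: int) -> int:
    """Concatenated 1..3L residue index of ``(chain, position)``.

    Examples: for L=21, chain 2 position 21 -> 42; for L=22, chain 3
    position 22 -> 66 (the terminal residues the trajectory heat maps
    point at).
    """
    L = topology.L
    if not 1 <= chain <= 3:
        raise IndexError(f"chain {chain} outside 1..3")
    if not 1 <= position <= L:
        raise IndexError(f"position {position} outside 1..{L}")
    return (chain - 1) * L + position


def chain_position(topology: TripleHelixTopology, index: int) -> tuple[int, int]:
    """Inverse of :func:`global_index`."""
    L = topology.L
    if not 1 <= index <= 3 * L:
        raise IndexError(f"global index {index} outside 1..{3 * L}")
    return (index - 1) // L + 1, (index - 1) % L + 1


@dataclass(frozen=True)
class RegionSelection:
    """A per-chain triplet window applied to all three chains."""

    region: Literal["N_terminal", "central", "C_terminal"]
    start: int
    end: int

    def positions(self) -> range:
        return range(self.start, self.end + 1)


def select_region(topology: TripleHelixTopology, region: str) -> RegionSelection:
    """Triplet windows used by the per-region trajectory statistics.

    ``N_terminal`` is residues (1, 3) and ``C_terminal`` (L-2, L) of each
    chain.  ``central`` is the triplet of the dominant frame containing
    residue ``ceil(L/2)``; this reproduces (10, 12) for both the L=21 pure
    repeats and the L=22 CMP-3 sequence.
    """
    L = topology.L
    if L < 9:
        raise ValueError(f"regions undefined for L={L} < 9 (windows would overlap)")
    if region == "N_terminal":
        return RegionSelection("N_terminal", 1, 3)
    if region == "C_terminal":
        return RegionSelection("C_terminal", L - 2, L)
    if region == "central":
        mid = ceil(L / 2)
        off = topology.sequence.frame_offset  # 0-based start of first triplet
        # triplet index containing `mid` within the frame
        k = (mid - 1 - off) // 3
        start = off + 3 * k + 1
        end = start + 2
        if start < 1 or end > L:  # mid fell outside the framed repeats
            start = mid - 1
            end = mid + 1
        return RegionSelection("central", start, end)
    raise ValueError(f"unknown region {region!r}")


@dataclass(frozen=True)
class TerminalClass:
    """Identity of a chain terminus: residue and its triplet form."""

    end: Literal["N", "C"]
    residue: str  # three-letter-ish name, e.g. "Hyp"
    letter: str
    form: str

    @property
    def label(self) -> str:
        return f"{self.residue}-terminal"


def terminal_repeat_class(seq: CMPSequence, end: str) -> TerminalClass:
    """Classify a chain end by its terminal residue.

    The C-end of a GPO-form chain is Hyp-terminal, of a POG form
    Gly-terminal, of an OGP form Pro-terminal; symmetrically for N.
    """
    if end not in ("N", "C"):
        raise ValueError(f"end must be 'N' or 'C', got {end!r}")
    letter = seq.residues[0] if end == "N" else seq.residues[-1]
    return TerminalClass(
        end=end,
        residue=RESIDUE_NAMES[letter],
        letter=letter,
        form=seq.repeat_form,
    )
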