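"""Crystal-structure flexibility analysis.

B-factor normalization and terminal-triplet statistics, unresolved-residue
accounting, and geometric detection of interchain hydrogen bonds.  B-factor
statistics exclude hydrogens, waters and zero-occupancy atoms; per-structure
normalization divides by the mean B of the included atoms, so elevated
terminal flexibility can be compared across structures refined at different
overall temperatures/resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sequence import TripleHelixTopology
from .structures import StructureModel

__all__ = [
    "BFactorProfile",
    "TerminalDeviation",
    "GeometricHBond",
    "normalize_bfactors",
    "terminal_deviation",
    "count_missing_terminal",
    "detect_hbonds",
]


@dataclass(frozen=True)
class BFactorProfile:
    """Normalized B-factors of one structure.

    ``atoms`` is the included (heavy, non-water, occupied) atom table with
    an extra ``b_norm`` column; ``per_residue`` holds the mean normalized B
    per (chain, resnum).  The mean of ``b_norm`` is 1 by construction.
    """

    atoms: pd.DataFrame
    per_residue: pd.DataFrame
    mean_b: float
    name: str = ""


@dataclass(frozen=True)
class TerminalDeviation:
    """Terminal-triplet B-factor deviation statistic.

    ``value`` is the mean normalized B over all resolved atoms of the
    terminal triplet of all three chains, minus 1 (or, in raw mode, the
    raw mean minus the structure mean).  ``value`` is None when no
    terminal-triplet atoms are resolved.  ``n_missing`` counts declared
    terminal residues absent from the coordinates at this end.
    """

    end: Literal["N", "C"]
    value: float | None
    n_missing: int
    n_atoms: int
    mode: Literal["normalized", "raw"] = "normalized"


def normalize_bfactors(structure: StructureModel) -> BFactorProfile:
    """Per-atom B divided by the structure's mean B (included atoms only)."""
    mask = structure.heavy_mask()
    atoms = structure.atoms[mask].copy()
    if atoms.empty:
        raise ValueError("no heavy, occupied, non-water atoms for B statistics")
    mean_b = float(atoms["bfactor"].mean())
    if mean_b == 0:
        raise ValueError("all-zero B-factor field: normalization undefined")
    atoms["b_norm"] = atoms["bfactor"] / mean_b
    per_res = (
        atoms.groupby(["chain", "resnum"], sort=True)["b_norm"]
        .mean()
        .reset_index()
        .rename(columns={"b_norm": "b_norm_mean"})
    )
    return BFactorProfile(atoms=atoms, per_residue=per_res, mean_b=mean_b,
                          name=structure.name)


def _terminal_positions(topology: TripleHelixTopology, end: str) -> range:
    L = topology.L
    return range(1, 4) if end == "N" else range(L - 2, L + 1)


def terminal_deviation(
    profile: BFactorProfile,
    topology: TripleHelixTopology,
    end: Literal["N", "C"],
    mode: Literal["normalized", "raw"] = "normalized",
) -> TerminalDeviation:
    """Deviation of the terminal amino-acid triplet from the structure mean.

    The terminal triplet is the last (or first) three residues of each
    chain by author numbering.  Chains with unresolved terminal residues
    contribute only their resolved atoms; the unresolved count is reported
    alongside.  When nothing at all is resolved the statistic is undefined
    (None), not a number.
    """
    if end not in ("N", "C"):
        raise ValueError(f"end must be 'N' or 'C', got {end!r}")
    pos = set(_terminal_positions(topology, end))
    sel = profile.atoms[profile.atoms["resnum"].isin(pos)]
    n_missing = _missing_one_end(profile.atoms, topology, end)
    if sel.empty:
        return TerminalDeviation(end=end, value=None, n_missing=n_missing,
                                 n_atoms=0, mode=mode)
    if mode == "normalized":
        value = float(sel["b_norm"].mean() - 1.0)
    elif mode == "raw":
        value = float(sel["bfactor"].mean() - profile.mean_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TerminalDeviation(end=end, value=value, n_missing=n_missing,
                             n_atoms=len(sel), mode=mode)


def _missing_one_end(atoms: pd.DataFrame, topology: TripleHelixTopology,
                     end: str) -> int:
    L = topology.L
    total = 0
    for chain, sub in atoms.groupby("chain"):
        present = set(int(r) for r in sub["resnum"])
        if not present:
            continue
        if end == "N":
            total += min(present) - 1
        else:
            total += L - max(present)
    return total


def count_missing_terminal(
    structure: StructureModel, topology: TripleHelixTopology | None = None
) -> tuple[int, int]:
    """Unresolved terminal residues (n_missing_N, n_missing_C), summed
    over chains.

    The declared per-chain length comes from the topology, or from SEQRES
    when the structure carries one; with neither an error instructs the
    caller to supply a topology.
    """
    if topology is not None:
        L_by_chain = {ch: topology.L for ch in structure.chains}
    elif structure.seqres:
        L_by_chain = {ch: len(seq) for ch, seq in structure.seqres.items()}
    else:
        raise ValueError(
            "no declared sequence: supply a topology or a structure with SEQRES"
        )
    n_n = n_c = 0
    for chain, sub in structure.atoms.groupby("chain"):
        L = L_by_chain.get(chain)
        if L is None:
            continue
        present = set(int(r) for r in sub["resnum"])
        n_n += min(present) - 1
        n_c += L - max(present)
    return n_n, n_c


@dataclass(frozen=True)
class GeometricHBond:
    """A detected donor N -> acceptor O pair."""

    donor_chain: str
    donor_resnum: int
    donor_atom: str
    acceptor_chain: str
    acceptor_resnum: int
    acceptor_atom: str
    d_NO: float
    angle: float | None
    interchain: bool


# residues treated as X-position acceptors in the default mode
_XPOS_ACCEPTORS = {"PRO"}
_DONOR_RESIDUES = {"GLY"}  # Sar excluded: N-methylated, no amide hydrogen


class DetectorContext:
    """Precomputed donor/acceptor indexing for repeated (per-frame) detection."""

    def __init__(self, structure: StructureModel,
                 acceptor_mode: Literal["xpos+terminal", "all"] = "xpos+terminal"):
        a = structure.atoms.reset_index(drop=True)
        self.atoms = a
        donors = a[((a["atom"] == "N") & (a["resname"].isin(_DONOR_RESIDUES)))
                   | (a["atom"] == "NT")]
        if acceptor_mode == "all":
            acceptors = a[a["atom"] == "O"]
        elif acceptor_mode == "xpos+terminal":
            last = a.groupby("chain")["resnum"].transform("max")
            acceptors = a[(a["atom"] == "O")
                          & (a["resname"].isin(_XPOS_ACCEPTORS) | (a["resnum"] == last))]
        else:
            raise ValueError(f"unknown acceptor_mode {acceptor_mode!r}")
        self.donor_idx = donors.index.to_numpy()
        self.acc_idx = acceptors.index.to_numpy()
        # per-donor hydrogens (list of index arrays) and CA fallback
        res_groups = a.groupby(["chain", "resnum"]).groups
        self.h_idx: list[np.ndarray] = []
        self.ca_idx: list[int] = []
        for di in self.donor_idx:
            key = (a.at[di, "chain"], a.at[di, "resnum"])
            members = np.asarray(list(res_groups[key]))
            names = a.loc[members, "atom"]
            if a.at[di, "atom"] == "NT":
                hsel = members[names.isin(["HT1", "HT2"]).to_numpy()]
            else:
                hsel = members[(names == "H").to_numpy()]
            self.h_idx.append(hsel)
            casel = members[(names == "CA").to_numpy()]
            self.ca_idx.append(int(casel[0]) if len(casel) else -1)


def detect_hbonds(
    structure: StructureModel,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    proxy_angle_min: float = 90.0,
    acceptor_mode: Literal["xpos+terminal", "all"] = "xpos+terminal",
    coords: np.ndarray | None = None,
    context: DetectorContext | None = None,
) -> list[GeometricHBond]:
    """Geometric interchain/intrachain hydrogen-bond detection.

    Donors: backbone N of Gly plus the terminal amide N (``NT``) of the
    C-cap (Sar excluded: no amide hydrogen).  Acceptors: backbone carbonyl
    O of X-position (Pro) residues plus the chain-terminal carbonyls
    (default), or every backbone O in survey mode.  A pair is a bond when
    d(N...O) <= ``d_max`` and the N-H...O angle at H is >= ``angle_min``
    (best amide H); when the donor carries no hydrogen a CA-N...O
    heavy-atom proxy angle >= ``proxy_angle_min`` is used instead.  Output
    is deterministically ordered by donor then acceptor.
    """
    ctx = context or DetectorContext(structure, acceptor_mode)
    a = ctx.atoms
    xyz = structure.coords if coords is None else np.asarray(coords, dtype=float)
    if len(ctx.donor_idx) == 0 or len(ctx.acc_idx) == 0:
        return []
    acc_xyz = xyz[ctx.acc_idx]
    tree = cKDTree(acc_xyz)
    out: list[GeometricHBond] = []
    for k, di in enumerate(ctx.donor_idx):
        dpos = xyz[di]
        d_chain, d_res, d_atom = a.at[di, "chain"], int(a.at[di, "resnum"]), a.at[di, "atom"]
        hsel = ctx.h_idx[k]
        for j in tree.query_ball_point(dpos, d_max):
            ai = ctx.acc_idx[j]
            a_chain, a_res = a.at[ai, "chain"], int(a.at[ai, "resnum"])
            if a_chain == d_chain and a_res == d_res:
                continue
            apos = acc_xyz[j]
            d = float(np.linalg.norm(dpos - apos))
            angle = None
            if len(hsel):
                best = -1.0
                for hi in hsel:
                    hpos = xyz[hi]
                    v1, v2 = dpos - hpos, apos - hpos
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    best = max(best, float(np.rad2deg(np.arccos(np.clip(cosang, -1, 1)))))
                angle = best
                if angle < angle_min:
                    continue
            elif ctx.ca_idx[k] >= 0:
                cpos = xyz[ctx.ca_idx[k]]
                v1, v2 = cpos - dpos, apos - dpos
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.rad2deg(np.arccos(np.clip(cosang, -1, 1))))
                if angle < proxy_angle_min:
                    continue
            out.append(
                GeometricHBond(
                    donor_chain=str(d_chain),
                    donor_resnum=d_res,
                    donor_atom=str(d_atom),
                    acceptor_chain=str(a_chain),
                    acceptor_resnum=a_res,
                    acceptor_atom=str(a.at[ai, "atom"]),
                    d_NO=d,
                    angle=angle,
                    interchain=bool(a_chain != d_chain),
                )
            )
    out.sort(key=lambda b: (b.donor_chain, b.donor_resnum, b.donor_atom,
                            b.acceptor_chain, b.acceptor_resnum))
    return out
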