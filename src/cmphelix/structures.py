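"""Structure and trajectory containers plus PDB/mmCIF input and output.

Atoms live in a pandas DataFrame (one row per atom).  Files are read and
written through gemmi; trajectories are multi-model PDB files sharing one
atom list across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = ["StructureModel", "Trajectory", "read_structure", "write_pdb",
           "read_trajectory", "write_trajectory"]

ATOM_COLUMNS = [
    "chain", "resnum", "resname", "atom", "element",
    "x", "y", "z", "bfactor", "occupancy",
]

_WATERS = {"HOH", "WAT", "DOD"}


@dataclass
class StructureModel:
    """Atoms of one structural model.

    ``seqres`` optionally carries the declared per-chain sequences
    (chain id -> list of residue names) for missing-residue accounting.
    """

    atoms: pd.DataFrame
    seqres: dict[str, list[str]] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns {missing}")
        xyz = self.coords
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = np.asarray(xyz, dtype=float)
        return StructureModel(atoms=atoms, seqres=self.seqres, name=self.name)

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    def heavy_mask(self, include_zero_occupancy: bool = False) -> np.ndarray:
        """Atoms entering B-factor statistics: no H/D, no waters,
        no zero-occupancy atoms."""
        a = self.atoms
        m = ~a["element"].isin(["H", "D"]) & ~a["resname"].isin(_WATERS)
        if not include_zero_occupancy:
            m &= a["occupancy"] > 0
        return m.to_numpy()

    def n_residues(self, chain: str) -> int:
        sub = self.atoms[self.atoms["chain"] == chain]
        return sub["resnum"].nunique()


@dataclass
class Trajectory:
    """Frames over a fixed atom list.

    ``frames`` has shape (n_frames, n_atoms, 3); ``frame_interval_ns`` is
    carried as metadata only.
    """

    template: StructureModel
    frames: np.ndarray
    frame_interval_ns: float = 0.1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.template.atoms):
            raise ValueError("frame atom count does not match the template")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame(self, i: int) -> StructureModel:
        return self.template.with_coords(self.frames[i])


def _structure_to_frame(st: gemmi.Structure, model: gemmi.Model) -> pd.DataFrame:
    rows = []
    for chain in model:
        for res in chain:
            # altloc policy: keep one atom per site — highest occupancy,
            # ties broken alphabetically by altloc
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                    continue
                key_new = (atom.occ, -ord(atom.altloc or "z"))
                key_old = (prev.occ, -ord(prev.altloc or "z"))
                if key_new > key_old:
                    by_name[atom.name] = atom
            for atom in by_name.values():
                rows.append(
                    (
                        chain.name,
                        res.seqid.num,
                        res.name,
                        atom.name,
                        atom.element.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.b_iso,
                        atom.occ,
                    )
                )
    return pd.DataFrame(rows, columns=ATOM_COLUMNS)


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Model 1 only; altlocs resolved to one atom per site (highest occupancy,
    then alphabetical).  ``fmt`` may be ``"PDB"`` or ``"mmCIF"``; by default
    it is inferred from the extension.
    """
    path = Path(path)
    try:
        if fmt is not None:
            f = {"PDB": gemmi.CoorFormat.Pdb, "MMCIF": gemmi.CoorFormat.Mmcif}[
                fmt.upper()
            ]
            st = gemmi.read_structure(str(path), format=f)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, KeyError) as exc:
        raise ValueError(f"cannot parse {path} as a structure file: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    st.setup_entities()
    frame = _structure_to_frame(st, st[0])
    if frame.empty:
        raise ValueError(f"{path}: no atoms in model 1")
    for ch, n in frame.groupby("chain").size().items():
        if n == 0:
            raise ValueError(f"{path}: empty chain {ch}")
    raw = _read_seqres(path) if path.suffix.lower() in (".pdb", ".ent") else None
    return StructureModel(atoms=frame, seqres=raw, name=path.stem)


def _read_seqres(path: Path) -> dict[str, list[str]] | None:
    seqres: dict[str, list[str]] = {}
    try:
        text = path.read_text()
    except OSError:
        return None
    for line in text.splitlines():
        if line.startswith("SEQRES"):
            chain = line[11].strip()
            seqres.setdefault(chain, []).extend(line[19:].split())
    return seqres or None


def _to_gemmi(model_sets: list[tuple[StructureModel, np.ndarray | None]],
              name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name or "cmphelix"
    for i, (sm, xyz) in enumerate(model_sets, start=1):
        model = gemmi.Model(i)
        coords = sm.coords if xyz is None else xyz
        for chain_id in sm.chains:
            chain = gemmi.Chain(chain_id)
            sub = sm.atoms[sm.atoms["chain"] == chain_id]
            for resnum, res_rows in sub.groupby("resnum", sort=True):
                res = gemmi.Residue()
                res.seqid = gemmi.SeqId(int(resnum), " ")
                res.name = str(res_rows["resname"].iloc[0])
                for idx, row in res_rows.iterrows():
                    atom = gemmi.Atom()
                    atom.name = row["atom"]
                    atom.element = gemmi.Element(row["element"])
                    x, y, z = coords[sm.atoms.index.get_loc(idx)]
                    atom.pos = gemmi.Position(float(x), float(y), float(z))
                    atom.b_iso = float(row["bfactor"])
                    atom.occ = float(row["occupancy"])
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    return st


def _seqres_records(seqres: dict[str, list[str]]) -> str:
    lines = []
    for chain, residues in seqres.items():
        for i in range(0, len(residues), 13):
            ser = i // 13 + 1
            names = " ".join(f"{r:>3s}" for r in residues[i : i + 13])
            lines.append(f"SEQRES {ser:>3d} {chain:1s} {len(residues):>4d}  {names}")
    return "\n".join(lines) + "\n"


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write ATOM records (occupancy and B-factor fields included) plus
    SEQRES when the model declares per-chain sequences."""
    st = _to_gemmi([(structure, None)], structure.name)
    st.write_pdb(str(path))
    if structure.seqres:
        path = Path(path)
        body = path.read_text()
        path.write_text(_seqres_records(structure.seqres) + body)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB."""
    sets = [(traj.template, traj.frames[i]) for i in range(traj.n_frames)]
    st = _to_gemmi(sets, traj.template.name)
    st.write_pdb(str(path))


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-model PDB as a trajectory (constant atom list)."""
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    frames = []
    template = None
    for model in st:
        frame = _structure_to_frame(st, model)
        if template is None:
            template = StructureModel(atoms=frame, name=path.stem)
        elif len(frame) != len(template.atoms):
            raise ValueError(f"{path}: atom count varies across models")
        frames.append(frame[["x", "y", "z"]].to_numpy(dtype=float))
    return Trajectory(template=template, frames=np.stack(frames))
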