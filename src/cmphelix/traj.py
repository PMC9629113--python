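"""Trajectory post-processing: per-region RMSD / Rg, H-bond occupancy maps,
missing-contact reporting, and the two-sample comparison test.

RMSD measures the mean displacement of the region's atoms from the initial
conformation (frame 0); Rg the region's instantaneous size (unweighted RMS
distance from the centroid, all heavy atoms).  Occupancy maps accumulate
geometric H-bond detections per residue pair over frames; per-frame series
are treated as independent samples by the Welch t-test (a documented
simplification).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactMap
from .flex import DetectorContext, detect_hbonds
from .helix import CHAIN_IDS
from .sequence import RegionSelection, TripleHelixTopology, global_index
from .structures import StructureModel, Trajectory

__all__ = [
    "RegionSeries",
    "OccupancyMap",
    "region_series",
    "region_rmsd",
    "region_rg",
    "occupancy_map",
    "missing_contacts",
    "two_sample_test",
    "per_residue_rms",
]


@dataclass(frozen=True)
class RegionSeries:
    """Per-frame RMSD and Rg for one region (all three chains)."""

    region: str
    rmsd: np.ndarray
    rg: np.ndarray

    @property
    def rmsd_mean(self) -> float:
        return float(np.mean(self.rmsd))

    @property
    def rmsd_sd(self) -> float:
        return float(np.std(self.rmsd, ddof=1))

    @property
    def rg_mean(self) -> float:
        return float(np.mean(self.rg))

    @property
    def rg_sd(self) -> float:
        return float(np.std(self.rg, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.rmsd)), "rmsd_A": self.rmsd, "rg_A": self.rg}
        )


def _region_atom_mask(template: StructureModel, selection: RegionSelection) -> np.ndarray:
    a = template.atoms
    mask = (
        (a["resnum"] >= selection.start)
        & (a["resnum"] <= selection.end)
        & ~a["element"].isin(["H", "D"])
    ).to_numpy()
    if not mask.any():
        raise ValueError(f"selection {selection} matches no atoms")
    return mask


def _kabsch(mobile: np.ndarray, ref: np.ndarray, fit_mask: np.ndarray) -> np.ndarray:
    """Superpose ``mobile`` onto ``ref`` using the masked atoms; returns the
    transformed full coordinate set."""
    m, r = mobile[fit_mask], ref[fit_mask]
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    H = (m - mc).T @ (r - rc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return (mobile - mc) @ R.T + rc


def region_series(
    traj: Trajectory,
    selection: RegionSelection,
    superpose: Literal["none", "central-region", "all-atom"] = "none",
    central: RegionSelection | None = None,
) -> RegionSeries:
    """Per-frame RMSD (vs frame 0) and Rg of a region.

    ``superpose`` removes rigid-body motion before the RMSD: ``none``
    (deviation from the initial conformation, read literally),
    ``central-region`` (whole trimer fitted on the central triplet), or
    ``all-atom``.  Frame 0 has RMSD 0 by definition.
    """
    mask = _region_atom_mask(traj.template, selection)
    if superpose == "central-region":
        if central is None:
            raise ValueError("central-region superposition needs the central selection")
        fit_mask = _region_atom_mask(traj.template, central)
    elif superpose == "all-atom":
        fit_mask = ~traj.template.atoms["element"].isin(["H", "D"]).to_numpy()
    elif superpose == "none":
        fit_mask = None
    else:
        raise ValueError(f"unknown superposition policy {superpose!r}")

    ref = traj.frames[0]
    n = traj.n_frames
    rmsd = np.empty(n)
    rg = np.empty(n)
    for i in range(n):
        frame = traj.frames[i]
        if fit_mask is not None and i > 0:
            frame = _kabsch(frame, ref, fit_mask)
        sub = frame[mask]
        rmsd[i] = np.sqrt(np.mean(np.sum((sub - ref[mask]) ** 2, axis=1)))
        cen = sub.mean(axis=0)
        rg[i] = np.sqrt(np.mean(np.sum((sub - cen) ** 2, axis=1)))
    return RegionSeries(region=selection.region, rmsd=rmsd, rg=rg)


def region_rmsd(traj, selection, superpose="none", central=None) -> RegionSeries:
    return region_series(traj, selection, superpose, central)


def region_rg(traj, selection) -> RegionSeries:
    return region_series(traj, selection, "none")


@dataclass(frozen=True)
class OccupancyMap:
    """Time-averaged H-bond count between every global residue pair.

    Symmetric (3L x 3L) matrix, zero diagonal; entry (i-1, j-1) is the mean
    number of detected bonds per frame between global residues i and j.
    """

    matrix: np.ndarray
    topology: TripleHelixTopology
    n_frames: int

    def occupancy(self, i: int, j: int) -> float:
        return float(self.matrix[i - 1, j - 1])

    def to_frame(self) -> pd.DataFrame:
        n = self.matrix.shape[0]
        return pd.DataFrame(
            self.matrix,
            index=pd.RangeIndex(1, n + 1, name="residue_i"),
            columns=pd.RangeIndex(1, n + 1),
        )


def occupancy_map(
    traj: Trajectory,
    topology: TripleHelixTopology,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    acceptor_mode: str = "xpos+terminal",
) -> OccupancyMap:
    """Run the geometric detector on every frame and accumulate per-pair
    counts (cap donors are attributed to their chain's terminal residue)."""
    L = topology.L
    size = 3 * L
    mat = np.zeros((size, size))
    ctx = DetectorContext(traj.template, acceptor_mode)
    chain_no = {cid: i + 1 for i, cid in enumerate(CHAIN_IDS)}
    for f in range(traj.n_frames):
        bonds = detect_hbonds(
            traj.template, d_max=d_max, angle_min=angle_min,
            coords=traj.frames[f], context=ctx,
        )
        for b in bonds:
            i = global_index(topology, chain_no[b.donor_chain], b.donor_resnum)
            j = global_index(topology, chain_no[b.acceptor_chain], b.acceptor_resnum)
            mat[i - 1, j - 1] += 1
            mat[j - 1, i - 1] += 1
    mat /= traj.n_frames
    return OccupancyMap(matrix=mat, topology=topology, n_frames=traj.n_frames)


def missing_contacts(
    omap: OccupancyMap,
    expected: ContactMap,
    threshold: float = 0.3,
    classes: Sequence[str] = ("stable", "weak"),
    reference: StructureModel | None = None,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[tuple[int, int]]:
    """Expected contacts whose time-averaged occupancy falls below
    ``threshold``, as ordered global-index pairs.

    ``reference`` (typically the un-loosened ideal build) restricts the
    check to contacts the reference geometry actually realizes, so contacts
    that are rule-expected but geometrically out of reach at the chain ends
    do not appear as spurious losses.
    """
    if not omap.topology.same_chain_topology(expected.topology):
        raise ValueError("occupancy map and expected contact map topologies differ")
    realized: set[tuple[int, int]] | None = None
    if reference is not None:
        chain_no = {cid: i + 1 for i, cid in enumerate(CHAIN_IDS)}
        realized = set()
        for b in detect_hbonds(reference, d_max=d_max, angle_min=angle_min):
            i = global_index(omap.topology, chain_no[b.donor_chain], b.donor_resnum)
            j = global_index(omap.topology, chain_no[b.acceptor_chain], b.acceptor_resnum)
            realized.add((i, j))
            realized.add((j, i))
    out = []
    for pair in expected.pairs(classes=classes):
        if realized is not None and pair not in realized:
            continue
        if omap.occupancy(*pair) < threshold:
            out.append(pair)
    return sorted(set(out))


def two_sample_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both samples: t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def per_residue_rms(traj: Trajectory, reference: np.ndarray | None = None) -> pd.DataFrame:
    """Per-residue RMS displacement about the reference (default: the
    time-mean coordinates), reported per coordinate (3-D RMS divided by
    sqrt(3)) — recovers the generator's sigma ramp."""
    ref = traj.frames.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    disp2 = np.sum((traj.frames - ref[None]) ** 2, axis=2)  # (frames, atoms)
    a = traj.template.atoms
    df = pd.DataFrame(
        {
            "chain": a["chain"].to_numpy(),
            "resnum": a["resnum"].to_numpy(),
            "msd": disp2.mean(axis=0),
        }
    )
    out = df.groupby(["chain", "resnum"], sort=True)["msd"].mean().reset_index()
    out["sigma_est"] = np.sqrt(out["msd"] / 3.0)
    return out
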