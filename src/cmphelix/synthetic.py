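"""Synthetic data generators: every input the analysis stages consume.

The generators emulate the study's three data sources without any physics:

* crystal-like structures — the ideal helix of :mod:`cmphelix.helix` with a
  synthetic B-factor field whose thermal noise is amplified toward the
  chain termini (terminal fraying);
* relaxation trajectories — independent Gaussian displacements about the
  ideal coordinates with the same terminal ramp, plus an optional "loose
  chain" mode that rigidly detaches one chain's terminal triplet so its
  interchain H-bonds vanish;
* instrument curves — noiseless or noisy two-state CD unfolding sigmoids
  (whose steepest point is exactly the requested Tm) and two-state DSC
  excess-heat-capacity peaks normalized so the baseline-subtracted
  integral equals the requested enthalpy exactly.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .helix import CHAIN_IDS, HelixParams, build_ideal_helix
from .melting import DSCThermogram, MeltingCurve
from .sequence import TripleHelixTopology
from .structures import StructureModel, Trajectory

__all__ = [
    "NoiseProfile",
    "build_ideal_helix",
    "HelixParams",
    "synthesize_bfactors",
    "simulate_trajectory",
    "gen_melting_curve",
    "gen_dsc",
    "DEFAULT_GRID",
]

#: default CD-melt temperature grid: 4-90 C in 0.5 C steps
DEFAULT_GRID = (4.0, 90.0, 0.5)

B_FROM_SIGMA = 8.0 * np.pi**2 / 3.0  # isotropic B = c * sigma^2


@dataclass(frozen=True)
class NoiseProfile:
    """Per-residue thermal-noise model.

    ``sigma_core``/``sigma_terminal`` are per-coordinate Gaussian standard
    deviations (A); the terminal amplification ramps linearly over
    ``ramp_length`` residues from each chain end.  ``loose_chain`` —
    ``(chain, "C")`` or ``(chain, "N")`` — rigidly displaces that chain's
    terminal triplet (the partially loose third chain seen in relaxed
    structures).
    """

    sigma_core: float = 0.25
    sigma_terminal: float = 0.8
    ramp_length: int = 3
    loose_chain: tuple[int, Literal["N", "C"]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.sigma_core <= self.sigma_terminal:
            raise ValueError("require sigma_terminal >= sigma_core >= 0")
        if self.ramp_length < 1:
            raise ValueError("ramp_length must be >= 1")
        if self.loose_chain is not None:
            c, end = self.loose_chain
            if c not in (1, 2, 3) or end not in ("N", "C"):
                raise ValueError(f"bad loose_chain {self.loose_chain}")

    def sigma(self, position: int, L: int) -> float:
        """Per-coordinate sigma for a residue at 1-based ``position``."""
        d = min(position - 1, L - position)
        f = max(0.0, (self.ramp_length - d) / self.ramp_length)
        return self.sigma_core + (self.sigma_terminal - self.sigma_core) * f


def _per_atom_sigma(structure: StructureModel, topology: TripleHelixTopology,
                    profile: NoiseProfile) -> np.ndarray:
    L = topology.L
    resnums = structure.atoms["resnum"].to_numpy()
    sig = np.array([profile.sigma(int(p), L) for p in resnums])
    return sig


def _loose_mask(structure: StructureModel, topology: TripleHelixTopology,
                profile: NoiseProfile) -> np.ndarray | None:
    if profile.loose_chain is None:
        return None
    chain, end = profile.loose_chain
    L = topology.L
    lo, hi = (1, 3) if end == "N" else (L - 2, L)
    a = structure.atoms
    return (
        (a["chain"] == CHAIN_IDS[chain - 1])
        & (a["resnum"] >= lo)
        & (a["resnum"] <= hi)
    ).to_numpy()


def synthesize_bfactors(
    structure: StructureModel,
    topology: TripleHelixTopology,
    profile: NoiseProfile,
    loose_scale: float = 2.0,
) -> StructureModel:
    """Assign B = (8 pi^2 / 3) sigma^2 from the noise ramp (deterministic).

    Residues of a designated loose terminal triplet get their sigma scaled
    by ``loose_scale`` so that chain's terminal B exceeds its partners'.
    """
    sig = _per_atom_sigma(structure, topology, profile)
    mask = _loose_mask(structure, topology, profile)
    if mask is not None:
        sig = np.where(mask, loose_scale * sig, sig)
    atoms = structure.atoms.copy()
    atoms["bfactor"] = B_FROM_SIGMA * sig**2
    return StructureModel(atoms=atoms, seqres=structure.seqres, name=structure.name)


def _rigid_detach(xyz: np.ndarray, mask: np.ndarray, translation: float = 6.0,
                  angle_deg: float = 40.0) -> np.ndarray:
    """Translate the masked atoms radially outward and rotate them in place."""
    out = xyz.copy()
    sub = out[mask]
    cen = sub.mean(axis=0)
    radial = np.array([cen[0], cen[1], 0.0])
    nrm = np.linalg.norm(radial)
    u = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    sub = (sub - cen) @ rot.T + cen + translation * u
    out[mask] = sub
    return out


def simulate_trajectory(
    structure: StructureModel,
    topology: TripleHelixTopology,
    n_frames: int,
    profile: NoiseProfile,
    frame_interval_ns: float = 0.1,
    loose_scale: float = 2.0,
) -> Trajectory:
    """Statistical stand-in for an equilibrium MD trajectory.

    Each frame adds independent per-coordinate Gaussian displacements with
    the profile's per-residue sigma to the input coordinates.  In loose
    mode the designated terminal triplet is rigidly displaced (>= 4 A
    translation plus a rotation) in every frame, so its interchain H-bond
    occupancy vanishes, and its sigma is scaled by ``loose_scale`` (a
    detached end fluctuates more).  Seeded and reproducible; this emulates
    thermal fluctuation statistics, not dynamics.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(profile.seed)
    base = structure.coords
    mask = _loose_mask(structure, topology, profile)
    sig = _per_atom_sigma(structure, topology, profile)
    if mask is not None:
        base = _rigid_detach(base, mask)
        # a detached triplet also fluctuates more than a bonded one
        sig = np.where(mask, loose_scale * sig, sig)
    noise = rng.normal(size=(n_frames, *base.shape)) * sig[None, :, None]
    noise[0] = 0.0  # frame 0 is the initial conformation (RMSD reference)
    frames = base[None, :, :] + noise
    return Trajectory(template=structure, frames=frames,
                      frame_interval_ns=frame_interval_ns)


def _grid(grid: tuple[float, float, float]) -> np.ndarray:
    tmin, tmax, step = grid
    if step <= 0 or tmax <= tmin:
        raise ValueError(f"bad temperature grid {grid}")
    n = int(round((tmax - tmin) / step)) + 1
    return tmin + step * np.arange(n)


def gen_melting_curve(
    Tm: float,
    width: float = 2.0,
    baselines: tuple[float, float] = (3.0, 0.0),
    grid: tuple[float, float, float] = DEFAULT_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
    name: str = "",
) -> MeltingCurve:
    """Two-state CD unfolding sigmoid.

    MRE(T) = thetaF + (thetaU - thetaF) / (1 + exp((Tm - T)/width)) plus
    optional Gaussian noise.  The noiseless curve's derivative extremum is
    analytically exactly at Tm.  The logistic (unimolecular-like) form is
    used because Tm is defined operationally as the steepest point; no
    concentration dependence is modelled.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    T = _grid(grid)
    if not (T[0] < Tm < T[-1]):
        raise ValueError(f"Tm={Tm} outside grid [{T[0]}, {T[-1]}]")
    theta_f, theta_u = baselines
    sig = theta_f + (theta_u - theta_f) / (1.0 + np.exp((Tm - T) / width))
    if noise_sd > 0:
        sig = sig + np.random.default_rng(seed).normal(scale=noise_sd, size=sig.shape)
    return MeltingCurve(T=T, signal=sig, name=name)


def gen_dsc(
    Tm: float,
    dH: float,
    width: float = 2.0,
    baseline: tuple[float, float] = (0.0, 0.0),
    grid: tuple[float, float, float] = DEFAULT_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
    name: str = "",
) -> DSCThermogram:
    """Two-state DSC excess-heat-capacity peak.

    The peak is dH * dF/dT with F the two-state folded fraction, rescaled
    analytically so the on-grid baseline-free integral equals dH exactly;
    ``baseline`` adds (intercept, slope) in kcal mol^-1 C^-1.  width below
    0.1 C is rejected (the peak would fall between grid points).
    """
    if width < 0.1:
        raise ValueError("width must be >= 0.1 C (degenerate peak)")
    if dH < 0:
        raise ValueError("unfolding endotherm requires dH >= 0")
    T = _grid(grid)
    if not (T[0] < Tm < T[-1]):
        raise ValueError(f"Tm={Tm} outside grid [{T[0]}, {T[-1]}]")
    frac = 1.0 / (1.0 + np.exp((Tm - T) / width))
    dfdt = frac * (1.0 - frac) / width
    norm = float(frac[-1] - frac[0])  # analytic integral of dF/dT over the grid
    peak = dH * dfdt / norm
    b0, b1 = baseline
    cp = peak + b0 + b1 * (T - T[0])
    if noise_sd > 0:
        cp = cp + np.random.default_rng(seed).normal(scale=noise_sd, size=cp.shape)
    return DSCThermogram(T=T, Cp_excess=cp, name=name)
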