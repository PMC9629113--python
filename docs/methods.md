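# Methods

`cmphelix` re-implements, as a tested pipeline over synthetic data, the
computational analyses used to compare the three terminal-repeat forms of
collagen-mimetic peptide (CMP) triple helices — (GPO)n, (POG)n and (OGP)n —
and the chemistry of their chain ends. This note records the models, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic generators do and do not emulate.

## Sequence model and numbering

A CMP chain is a string over G (Gly), P (Pro), O (4-hydroxyproline, Hyp)
and Z (sarcosine, Sar — N-methylated, no amide hydrogen), with an N-cap
(acetyl or free amine) and a C-cap (amide, carboxylate or ester). The
repeat form is read off the dominant triplet frame (the frame offset that
best matches the cyclic ...G-P-O... pattern, ties to the smallest offset);
Z matches any position when scoring, since Sar appears as a point
substitution. The free N-terminal amine is a cap state (protonated at the
registry's default pH 7.4), not a residue.

The homotrimer is numbered 1-based per chain; global numbering
concatenates chains 1, 2, 3, so `global = (chain-1)*L + position`. Region
windows are per-chain triplets applied to all three chains: N-terminal
(1, 3), C-terminal (L-2, L), and central = the frame-aligned triplet
containing residue ceil(L/2). The central rule yields (10, 12) for both
L = 21 and L = 22, and the C-terminal rule (19, 21) / (20, 22), matching
the windows used in the trajectory analyses being reproduced.

## Rule-based contact map

The canonical interchain hydrogen bond is Gly N-H -> Pro C=O. Because P
immediately follows G in every repeat form, one pairing rule covers all
three: Gly at position p of chain c donates to the carbonyl of position
p+1 on chain c+1 (cyclic 3 -> 1). Under the one-residue stagger the 3 -> 1
partner is the chain-1 residue one triplet down the superhelix, which is
exactly position p+1 of chain 1, so the uniform rule and the wrap
convention coincide. A chain-terminal Gly (POG-type end) instead tethers
the partner chain's terminal carbonyl; when the chain ends in Hyp or Pro
the C-terminal amide cap contributes one extra donor per chain; a
Pro-ended chain (OGP type) additionally carries a donor-less slot
documenting the Gly the repeat would have placed next. Contacts that
cannot form are kept in the map with class `absent`.

Classes are ordinal (`stable` > `weak` > `absent`), assigned by rules
calibrated against the ordinal melting-temperature evidence — no per-bond
energy is claimed:

1. a Gly-donated contact is stable by default; Sar donors and
   hydrogen-deficient caps (ester, carboxylate) are absent;
2. a Gly at chain position 1 donates only weakly (an appended N-terminal
   Gly adds only ~2 C of stability);
3. a contact accepting at the chain-terminal carbonyl is weak (terminal
   fraying interferes);
4. the amide-cap contact is stable on a Hyp-ended chain — the
   Hyp-CONH2...Pro-CO geometry seen in GPO-type crystal termini — and weak
   on a Pro-ended chain (a C-terminal Hyp adds ~12 C, a Pro ~7-8 C);
5. a C-terminal carboxylate removes the cap donor; on a POG-type end the
   charge amplifies terminal fraying one triplet inward (the contact
   donated by the Gly at L-3 drops one class); on an OGP-type end the
   contact accepting at the charged carboxylate drops one class;
6. a free N-terminal amine penalizes the first Gly contact of each chain
   by two classes when the chain starts with Pro (the charge sits directly
   on a donor-adjacent backbone), one when it starts with Gly (the charge
   is on the donor itself), none when Hyp leads.

With these rules the amide-capped heptamers give stable counts GPO 21,
OGP 18, POG 18, so the GPO-vs-POG stable gap is exactly the three terminal
amide contacts — consistent with the ~7 kcal/mol calorimetric enthalpy gap
at ~2 kcal/mol per bond. Ranking is lexicographic by (stable, weak): a
weak bond beats no bond, which is required for the observed OGP > POG
ordering (ordering by *fewer* weak contacts would invert it). The scalar
score used for charge-impact comparisons weights weak contacts 0.4; any
weight in (0, 0.5) reproduces the published impact orderings (carboxylate:
GPO > OGP > POG; ammonium: POG > GPO > OGP), so the value is not tuned.

## Ideal helix builder

The builder is a coarse-grained pseudo-backbone, not a stereochemically
refined model. Residue (c, p) occupies level `l = 3(p-1) + (c-1)` of an
interleaved screw lattice (rotation tau, rise h per level); one screw
operation maps chain 1 -> 2 -> 3 -> 1-shifted, so the zero-noise build is
exactly screw-symmetric (caps excepted). Defaults: rise 2.87 A per
residue, 7/2 symmetry (720/21 degrees per residue), C-alpha radius 2.6 A.
Atom offsets within each residue's local frame are calibration constants
chosen so that

* the designed donor -> acceptor relations (level offsets +4 for chains 1
  and 2, +1 for the trailing chain and the chain-terminal contacts) sit at
  N...O = 2.90 A with donor angles of 125 degrees;
* every other donor/acceptor pair is at least 3.66 A apart;
* no two atoms of different residues come closer than ~1.8 A.

The builder's self-check enforces the 2.6-3.3 A window on every internal
Gly N...Pro O contact and a 1.5 A clash floor, and raises otherwise.
Amide hydrogens are generated only where chemistry provides them (Gly and
the amide cap; Pro/Hyp/Sar have none) along the bisector of the two
designed acceptor directions, which is constant in the local frame and so
preserves the screw symmetry exactly. Cap nitrogens are placed explicitly
2.9 A from their acceptor carbonyls; the trailing chain's cap reaches down
to the leading chain's terminal carbonyl (level offset -2), which breaks
strict screw symmetry for cap atoms only.

Two geometric facts follow and are documented rather than hidden: the
trailing chain's terminal Gly contact (level offset -2) is out of
hydrogen-bond reach in the ideal build, and the trailing chain's last Gly
can additionally reach the leading chain's terminal carbonyl. Analyses
that compare trajectory occupancy against the rule map therefore take the
ideal build as the geometric reference: only contacts the reference
realizes can be reported missing. The builder represents sterics and
topology, not electrostatics, so charge-based `absent` classes
(carboxylate, free amine) are invisible to the geometric detector; the
rule-geometry equivalence checks run on the acetyl/amide, ester and
Sar-substituted peptides, where absence is steric.

## Geometric H-bond detection

Donors: backbone N of Gly plus the cap N; Sar is excluded. Acceptors
(default): carbonyl O of X-position (Pro) residues plus the chain-terminal
carbonyls; survey mode accepts every backbone O. Criteria: d(N...O) <=
3.5 A and N-H...O angle at H >= 120 degrees (best hydrogen); with no
hydrogen a CA-N...O proxy angle >= 90 degrees is used. All cutoffs are
config-exposed; the defaults are standard crystallographic practice. The
implementation uses a k-d tree; the test suite holds it equal to an
exhaustive O(n^2) scan on every structure it touches.

## B-factor statistics

B statistics exclude hydrogens, waters and zero-occupancy atoms; altlocs
are resolved to one atom per site (highest occupancy, then alphabetical).
Per-atom B is normalized by the structure mean (profile mean exactly 1),
making terminal flexibility comparable across structures. The terminal
deviation is the mean normalized B over the terminal triplet of all three
chains minus 1, computed on normalized B by default with a raw-B mode
exposed (the two differ only by the factor mean-B). Chains with
unresolved terminal residues contribute their resolved atoms, and the
unresolved count is reported alongside; a fully unresolved terminus yields
an undefined marker (None), not a number.

## Synthetic generators — what they emulate

* **B-factor fields**: B = (8 pi^2 / 3) sigma^2 with a per-residue sigma
  ramping linearly from `sigma_core` (default 0.25 A) to `sigma_terminal`
  (default 0.8 A) over the last `ramp_length` = 3 residues of each end —
  terminal fraying. A loose-chain mode doubles sigma on one chain's
  terminal triplet.
* **Trajectories**: independent per-frame Gaussian displacements with the
  same ramp; frame 0 is the unperturbed initial conformation. The loose
  mode rigidly displaces the designated terminal triplet (6 A radially
  plus a 40-degree rotation, every frame) so its H-bond occupancy
  vanishes, and doubles its sigma (a detached end fluctuates more). The
  trajectory analyses use a calmer profile (0.12/0.25 A) chosen so that
  intact bonds keep occupancy well above the 0.3 missing threshold while
  the detached triplet sits at zero; frames are independent samples, not
  dynamics — time correlation, anharmonicity and concerted motions of real
  MD are not emulated, which is why per-frame series feeding the t-test
  overstate the effective sample size (documented limitation).
* **Melting curves**: MRE(T) = thetaF + (thetaU - thetaF) /
  (1 + exp((Tm - T)/width)), defaults thetaF = 3, thetaU = 0 (the 225 nm
  scale, 10^3 deg cm^2 dmol^-1), width 2 C, grid 4-90 C in 0.5 C steps.
  The logistic's steepest point is exactly Tm, matching the operational Tm
  definition; the concentration-dependent trimolecular model is
  deliberately not used.
* **DSC peaks**: dH * dF/dT normalized analytically so the on-grid
  integral equals dH exactly, plus an optional linear baseline; widths
  below 0.1 C are rejected.

Passing tests on these generators show the *analysis* stages are correct
and self-consistent; they say nothing about force fields, instrument
response or real crystal disorder.

## Tm extraction and DSC integration

Tm is the steepest point of the transition: Savitzky-Golay smoothing
(centred local quadratic, default 7 points ~ 3 C — wide enough to suppress
instrument-scale noise without biasing a 1-5 C transition; the window
should be widened for noisier curves), central-difference derivative,
extremum of |dS/dT| (orientation-agnostic: unfolding lowers the 225 nm
MRE), and quadratic refinement over the three points around the grid
maximum. A transition is declared only when the peak exceeds three times
the derivative's robust (MAD-based) baseline spread; flat curves return
`detected = False`, not an exception. The extraction is exactly invariant
under affine transforms of the signal. On noiseless generator curves the
bias is below a fifth of the grid step across widths 1-5 C and Tm 35-70 C.
An independent cross-check fits the full two-state sigmoid with linear
folded/unfolded baselines and reports the van't Hoff enthalpy
R Tm_K^2 / width. A repeated-seed study at noise sd 0.5 (1/6 of the
default amplitude) puts the fit's RMS Tm error at ~0.65 C and the
derivative extractor's at ~1.5 C; the noisy-recovery tests assert these
study-derived bounds, and sub-0.5 C accuracy should only be expected at
realistic (several-fold lower) noise.

DSC enthalpy is the trapezoid integral after subtracting a line through
the means of the first and last 10 points (`linear-endpoints`), with a
truncation flag when the corrected signal still carries more than 5% of
the peak at either grid edge. The synthetic pair used for the enthalpy-
difference analysis assigns 20 kcal/mol to the POG-amide heptamer (a
typical CMP unfolding scale) and adds the reported 7.2 kcal/mol difference;
only the difference is compared.

## Reproduction pipeline and problem sizes

`cmphelix repro` (or `analysis/05_full_repro.py`) runs registry ->
topologies -> contact maps -> ideal builds -> trajectories -> structure
and trajectory analyses -> melting/DSC, writing a JSON-lines report in
which deterministic fields are byte-identical across runs with the same
config. Default problem sizes — 120-150 frames per trajectory, five
melting curves on a 173-point grid, heptamer-scale structures (~280
atoms) — were chosen so the full report builds in a few seconds while
keeping every statistical margin wide (the C-terminal RMSD contrast tests
at p ~ 1e-80); the sigma-recovery property uses 2000 frames on a
(GPO)3 trimer.

## Known limitations

* The helix builder's covalent geometry is schematic (bond lengths between
  consecutive residues are not physical); only the H-bond network and
  clash-freedom are calibrated.
* Contact classes are ordinal calibrations to the published Tm orderings,
  not energies; they should not be summed into free energies.
* Trajectory frames are independent; no kinetics, no solvent, no force
  field.
* Heating-rate effects on Tm are carried as metadata only.
* The registry ships only main-text Tm values; variants without reported
  values (and the two extension peptides without reported formulas) carry
  nulls and are excluded from curve-based analyses.
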