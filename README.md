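# cmphelix

Analysis pipeline for the **terminal repeats of collagen-mimetic peptide
(CMP) triple helices**. A CMP is a short (Gly-X-Y)n peptide — typically
Gly-Pro-Hyp — that folds into a collagen triple helix held together by
interchain Gly N-H...Pro C=O hydrogen bonds. The same peptide composition
can be written with three different terminal repeats, (GPO)n, (POG)n and
(OGP)n, and these ends are *not* interchangeable: the GPO form ends in
Hyp-CONH2, which can donate an extra set of C-terminal interchain H-bonds,
while the POG form ends in a flexible Gly that frays. This package models
that chemistry and reproduces the quantitative signatures that follow from
it:

* a **rule-based contact map** of interchain H-bonds per terminal form and
  cap chemistry (amide / ester / carboxylate / free amine / Sar), with
  stability rankings and terminal-charge impact orderings;
* an **ideal triple-helix builder** (three chains on a screw lattice,
  one-residue stagger) plus a geometric H-bond detector
  (d(N...O) <= 3.5 A, donor angle >= 120 deg) that realizes exactly the
  contacts the rule model predicts;
* **crystal-style flexibility statistics**: per-structure normalized
  B-factors (B / mean B), terminal-triplet deviations, unresolved-residue
  counts;
* **trajectory analysis**: per-region RMSD and radius of gyration,
  Welch's t-test, time-averaged H-bond occupancy maps and missing-contact
  reporting over global residue indices;
* **thermal stability**: Tm as the steepest point of the two-state
  unfolding curve (Savitzky-Golay smoothing + derivative + quadratic
  refinement, cross-checked by a two-state fit), delta-Tm tables, and DSC
  enthalpy by baseline-subtracted trapezoid integration;
* **synthetic generators** for every input (structures with fraying
  termini, loose-chain trajectories, CD and DSC curves), so the whole
  pipeline is testable offline.

The study peptides and their reported melting temperatures ship as a small
registry (`cmphelix.registry`): Ac-(POG)7-NH2 45 C, Ac-(GPO)7-NH2 55 C,
Ac-G(POG)7-NH2 47 C, Ac-(POG)8-NH2 56 C, Ac-(GPO)8-NH2 64 C.

## Worked example

```python
from cmphelix import (TripleHelixTopology, parse_cmp, build_contact_map,
                      build_ideal_helix, detect_hbonds,
                      gen_melting_curve, extract_tm)

cmp2 = TripleHelixTopology(parse_cmp("Ac-(GPO)7-NH2", name="CMP2"))
cmp1 = TripleHelixTopology(parse_cmp("Ac-(POG)7-NH2", name="CMP1"))

m2, m1 = build_contact_map(cmp2), build_contact_map(cmp1)
print(m2.n_stable, m1.n_stable, m2.n_stable - m1.n_stable)
# 21 18 3        <- the three terminal Hyp-amide contacts

bonds = detect_hbonds(build_ideal_helix(cmp2))
print(sum(b.donor_atom == "NT" for b in bonds))
# 3              <- the same three bonds found geometrically

tm = extract_tm(gen_melting_curve(55.0, name="CMP2"))
print(round(tm.Tm, 1))
# 55.0           <- steepest point of the synthetic unfolding curve
```

The stable-contact gap of exactly 3 mirrors the measured unfolding
enthalpy gap (~7 kcal/mol, i.e. about three H-bonds at ~2 kcal/mol each)
between the GPO- and POG-capped heptamers.

The numbered scripts under `analysis/` run the full study narrative —
contact maps and rankings (`01`), B-factor flexibility (`02`), trajectory
dynamics and missing H-bonds at the reported residue pairs 42/63, 44/66 and
21/42 (`03`), melting and DSC (`04`), and the one-command report (`05`) —
writing their tables under `results/`. The same stages are exposed as a
CLI (`cmphelix build | contacts | simulate-traj | analyze-structure |
analyze-traj | melt | dsc | rank | repro`).

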