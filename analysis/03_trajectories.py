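"""Synthetic-trajectory analysis: per-region dynamics and H-bond occupancy.

Simulates equilibrium-fluctuation trajectories for the four C-terminal
variants (the GPO-amide helix tight; the others with a loose third chain at
the C-terminus), computes per-region RMSD/Rg, tests the C-terminal contrast
with Welch's t-test, and reads the missing interchain H-bonds off the
occupancy maps — recovering the reported residue pairs 42/63 (POG-amide),
44/66 (the L=22 variant) and 21/42 (the ester cap).
"""

from pathlib import Path

import pandas as pd

from cmphelix import (
    NoiseProfile,
    TripleHelixTopology,
    build_ideal_helix,
    missing_contacts,
    occupancy_map,
    parse_cmp,
    select_region,
    simulate_trajectory,
    two_sample_test,
)
from cmphelix.contacts import build_contact_map
from cmphelix.traj import region_series

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_FRAMES = 150
NOISE = dict(sigma_core=0.12, sigma_terminal=0.25)

runs = {
    "CMP2": ("Ac-(GPO)7-NH2", None),
    "CMP1": ("Ac-(POG)7-NH2", (2, "C")),
    "CMP3": ("Ac-G(POG)7-NH2", (2, "C")),
    "CMP2E": ("Ac-(GPO)7-OCH3", (1, "C")),
}

series_rows = []
cterm = {}
top2 = TripleHelixTopology(parse_cmp("Ac-(GPO)7-NH2", name="CMP2"))
ideal2 = build_ideal_helix(top2)
for k, (name, (formula, loose)) in enumerate(runs.items()):
    top = TripleHelixTopology(parse_cmp(formula, name=name))
    ideal = build_ideal_helix(top)
    prof = NoiseProfile(**NOISE, loose_chain=loose, seed=101 * k)
    traj = simulate_trajectory(ideal, top, N_FRAMES, prof)
    for region in ("N_terminal", "central", "C_terminal"):
        s = region_series(traj, select_region(top, region))
        series_rows.append({"name": name, "region": region,
                            "rmsd_mean_A": round(s.rmsd_mean, 3),
                            "rg_mean_A": round(s.rg_mean, 3)})
        if region == "C_terminal":
            cterm[name] = s
    om = occupancy_map(traj, top)
    om.to_frame().to_csv(OUT / f"occupancy_{name}.tsv", sep="\t")
    if name == "CMP2E":
        # compare against the amide-capped reference: which of its bonds
        # does the ester variant lack?
        miss = missing_contacts(om, build_contact_map(top2), reference=ideal2)
    else:
        miss = missing_contacts(om, build_contact_map(top), reference=ideal)
    print(f"{name}: missing interchain H-bond pairs {miss}")

table = pd.DataFrame(series_rows)
table.to_csv(OUT / "region_series.csv", index=False)
print("\n" + table.pivot(index="name", columns="region",
                         values="rmsd_mean_A").to_string())

t, p = two_sample_test(cterm["CMP1"].rmsd[1:], cterm["CMP2"].rmsd[1:])
print(f"\nC-terminal RMSD, loose POG-amide vs tight GPO-amide: "
      f"t = {t:.1f}, p = {p:.2e} (tight is lower)")
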