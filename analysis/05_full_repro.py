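"""One-command reproduction: run every stage and write the JSON-lines report.

Equivalent to ``cmphelix repro``; all pass/fail entries land in
``results/repro_report.jsonl``.
"""

from pathlib import Path

from cmphelix.pipeline import RunConfig, run_repro

outdir = Path(__file__).resolve().parents[1] / "results"
report = run_repro(RunConfig(seed=0, outdir=str(outdir)))
checks = [e for e in report if "pass" in e]
n_ok = sum(e["pass"] for e in checks)
print(f"{n_ok}/{len(checks)} checks passed; report at {outdir/'repro_report.jsonl'}")
for e in report:
    if e.get("pass") is False:
        print("FAILED:", e)
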