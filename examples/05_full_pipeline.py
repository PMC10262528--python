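"""Run the whole study end to end on synthetic trials.

Simulates two MCI trials and one dementia trial, runs catalog -> FI ->
distribution -> outcome models -> meta-analysis, and prints the descriptive
table plus the pooled associations.
"""

import tempfile
from pathlib import Path

import frailtykit as fk

workdir = Path(tempfile.mkdtemp())
trials = []
for name, preset_name, n, seed in [
    ("mci1", "mci", 987, 1),
    ("mci2", "mci", 1064, 2),
    ("dementia", "dementia", 408, 3),
]:
    config = fk.preset(preset_name, n=n, seed=seed)
    baseline, outcomes, truth = fk.generate_trial(config)
    d = fk.write_trial(workdir / name, baseline, outcomes, truth)
    trials.append(fk.TrialSpec(name=name, baseline=d / "baseline.csv",
                               outcomes=d / "outcomes.csv",
                               follow_up_days=config.follow_up_days))

report = fk.run_pipeline(fk.RunConfig(
    trials=tuple(trials),
    catalog_path=fk.default_catalog_path(),
    out_dir=workdir / "report",
))

print((workdir / "report" / "table2.txt").read_text())
for key, pooled in report["meta"].items():
    lo, hi = pooled.effect_ci95
    print(f"{key:<40} {pooled.effect:.2f} [{lo:.2f}, {hi:.2f}]")
print(f"\nfull report bundle written to {workdir / 'report'}")

# The descriptive rows mirror a published-style Table: MCI trials centre
# near FI 0.14, the dementia trial near 0.24 (0.29 with cognitive deficits),
# and the pooled SAE association recovers the generating IRR of 1.6 within
# sampling error at these trial sizes.
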