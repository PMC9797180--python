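#!/usr/bin/env python
"""Full synthetic study: two 5-patient phantom cohorts end to end.

Each synthetic patient is a five-tissue CT phantom with a lung nodule.
The nodule ROI is translocated shape-preserved into adipose, heart, lung
and muscle; all 123 features are extracted from the five placements;
per-patient CV and tumor-vs-tissue CCC feed the uniqueness rules per
cohort and combined.  Because the phantom tissues are stationary textures
with distinct means, mean-sensitive features separate tissues strongly
while level-normalized and orientation-statistics features do not — the
same mechanism the screening is designed to expose.

Writes the per-patient feature tables, CV/CCC matrices, placement log and
uniqueness report under results/phantom_study/.
"""
import json
from pathlib import Path

from featuniq.phantom import PhantomSpec
from featuniq.pipeline import RunConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "phantom_study"


def main() -> None:
    config = RunConfig(
        cohorts={"A": 5, "B": 5},
        phantom_spec=PhantomSpec(shape=(24, 80, 80), nodule_diameter_mm=10.0),
        master_seed=1,
    )
    report = run_pipeline(config, OUT)
    summary = report.summary()
    print("Phantom study (two cohorts x 5 patients, seed 1):")
    print(json.dumps(summary, indent=2))
    print("\nCombined nonunique features on the phantoms:")
    for cat, feat in sorted(report.nonunique):
        print(f"  {cat}: {feat}")
    print(f"\nArtifacts under {OUT}")


if __name__ == "__main__":
    main()
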