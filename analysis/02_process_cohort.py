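#!/usr/bin/env python
"""Run the device-to-analysis-table pipeline on a cohort directory.

Reads the inputs written by 01_simulate_cohort.py (or any directory in
the same layout with real exports), cleans the traces, classifies
intensity from heart-rate reserve, labels indoor/outdoor exposure,
detects stops/trips and outdoor walking, merges nearest-station weather,
fits the nine random-intercept models, and writes everything (daily
summaries, trips, analysis table, model tables, descriptive report,
run manifest) under --out.
"""

import argparse
import json
from pathlib import Path

from wearpa import pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", type=str, default="scratch/cohort")
    ap.add_argument("--out", type=str, default="results/pipeline")
    args = ap.parse_args()

    out = pipeline.run_pipeline(pipeline.PipelineConfig(args.indir, args.out))
    manifest = json.loads((out / "manifest.json").read_text())
    stages = manifest["stages"]
    c, inc = stages["clean"], stages["inclusion"]
    print(f"fixes: {c['fixes_in']} in, {c['fixes_removed']} removed by cleaning")
    print(
        f"days: {inc['days_in']} in, {inc['days_short']} under 9 h, "
        f"{inc['days_lost_with_participants']} lost with excluded participants, "
        f"{inc['days_out']} analysed"
    )
    print(f"guideline attainment: {manifest['guideline_attainment']}")
    print(f"outputs under {out}")


if __name__ == "__main__":
    main()
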