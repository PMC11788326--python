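#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes the full device-level inputs — per-participant GPS/heart-rate
traces (CSV dialect), daily wearable summaries, the participant roster,
two weather stations spanning freeze-thaw and tropical-night regimes and
the village building footprints — plus the ground-truth record, under
--out (default scratch/cohort).  Downstream scripts read this directory.
"""

import argparse
from pathlib import Path

from wearpa import synthetic


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=str, default="scratch/cohort")
    ap.add_argument("--participants", type=int, default=40)
    ap.add_argument("--days", type=int, default=10)
    args = ap.parse_args()

    cfg = synthetic.SimConfig(seed=args.seed, n_participants=args.participants, n_days=args.days)
    paths, truth = synthetic.simulate_cohort(cfg, Path(args.out))
    n_days = len(truth["days"])
    print(f"wrote cohort for {args.participants} participants, {n_days} participant-days")
    print(f"planted effects: {truth['planted_effects']}")
    print(f"inputs under {args.out}; ground truth in {paths['ground_truth']}")


if __name__ == "__main__":
    main()
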