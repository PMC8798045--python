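#!/usr/bin/env python
"""Severing-protection statistic on mixed coated/non-coated populations.

Simulates per-microtubule tubulin intensity timecourses in three fields of
view (controls sever stochastically, probe-coated microtubules are fully
protected), finds the per-field time at which the control mean first stays
below 20% of baseline for two consecutive frames, and reports the coated
population's intensity at that time (inverse-variance weighted, 3-scaled-MAD
outliers removed).
"""
import argparse
from pathlib import Path

from mtkymo import simgen
from mtkymo.lattice import severing_timecourse

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

records = simgen.simulate_severing_records(rng_seed=args.seed)
table = severing_timecourse(records, threshold=0.2, baseline=(0.0, 60.0))

args.out.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out / "severing_timecourse.csv", index=False)

print(table.round(3).to_string(index=False))
ratio = (table["coated_mean"] / table["control_mean"]).mean()
print(f"\ncoated/control intensity ratio at threshold time: {ratio:.1f}x "
      f"(protection holds when coated microtubules keep ~100% intensity)")
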