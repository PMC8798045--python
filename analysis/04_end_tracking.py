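#!/usr/bin/env python
"""End-velocity windows and end-region probe intensity on a rendered kymograph.

Renders a two-channel kymograph of a growing microtubule whose probe
occupancy at the end region rises over time (a progressive end-accumulation
scenario), then runs the 2-min window velocity fits and the 5/3/5-pixel
end-intensity measurement, and checks that measured intensity tracks the
generating occupancy.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mtkymo import simgen
from mtkymo.config import SimConfig
from mtkymo.containers import DIMER_NM
from mtkymo.endtrack import (
    attach_segment_intensity,
    classify_segments,
    end_intensity,
    fit_segment_velocities,
    segments_table,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

cfg = SimConfig(rng_seed=args.seed, f_c=0.0, psf_sigma=1.0)
traj = simgen.simulate_dynamic_instability(cfg, duration=900.0, n=1)[0]
n_frames = traj.times.size
n_sites = int(round((traj.positions.max() + 2000 + 160 * 15) / DIMER_NM))
rng = np.random.default_rng(args.seed + 1)
occ = np.zeros((n_frames, n_sites), dtype=bool)
truth = np.minimum(0.9, 0.1 + 0.8 * np.arange(n_frames) / n_frames)
for f in range(n_frames):
    p_end = int(traj.positions[f] / DIMER_NM)
    lo = max(0, p_end - 60)
    occ[f, lo:p_end] = rng.uniform(size=p_end - lo) < truth[f]
kymo = simgen.render_kymograph(traj, occ, cfg.replace(noise_sd=90.0))

segs = classify_segments(fit_segment_velocities(traj))
intensity = end_intensity(kymo, traj, seed_offset_nm=2000.0)
attach_segment_intensity(segs, intensity)
table = segments_table(segs)

args.out.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out / "endtrack_segments.csv", index=False)
intensity.to_csv(args.out / "endtrack_intensity.csv", index=False)

r = np.corrcoef(intensity["intensity"], truth[intensity["frame"]])[0, 1]
print(table.to_string(index=False))
print(f"\nmean window velocity {table.velocity.mean():.2f} nm/s (generating 7.6); "
      f"end intensity vs true occupancy r = {r:.3f} over {len(intensity)} frames")
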