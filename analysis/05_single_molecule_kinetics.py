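#!/usr/bin/env python
"""Single-molecule dwell times and association rates, control vs spiking.

Control: 5 nM fully labeled probe on stabilized lattices, independent
binding (12 s mean residence).  Spiking: 5 nM labeled in 1 uM unlabeled
background with cooperative kinetics; events pooled over six fields of view.
Reports per-interval dwell means, association rates, and the rank-sum
comparison between conditions.
"""
import argparse
import json
from pathlib import Path

from mtkymo import simgen, singlemol
from mtkymo.config import control_binding_config, spiking_binding_config

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

ctrl = control_binding_config(args.seed)
ev_c = simgen.simulate_binding(ctrl, mt_length=100.0, duration=600.0)
c1 = singlemol.dwell_times(ev_c, interval=(0.0, 300.0))
c2 = singlemol.dwell_times(ev_c, interval=(300.0, 600.0))
n_c = sum(1 for e in ev_c if e.t_on < 300.0)
rate_c, rate_c_se = singlemol.association_rate(n_c, 300.0, 100.0, ctrl.conc)

spike = spiking_binding_config(args.seed + 1)
ev_s = simgen.simulate_binding_experiment(
    spike, n_fields=6, mt_length_per_field=25.0, duration=1200.0, condition="spiking"
)
s1 = singlemol.dwell_times(ev_s, interval=(0.0, 300.0))
s2 = singlemol.dwell_times(ev_s, interval=(300.0, 600.0))
n_s = sum(1 for e in ev_s if e.t_on < 300.0)
rate_s, rate_s_se = singlemol.association_rate(n_s, 300.0, 150.0, 5.0)

_, p_cond = singlemol.compare_conditions(s2.durations, c1.durations)
_, p_time = singlemol.compare_conditions(s2.durations, s1.durations)

payload = {
    "control": {"dwell_0_5min_s": c1.mean, "n1": c1.n,
                "dwell_5_10min_s": c2.mean, "n2": c2.n,
                "association_rate": rate_c, "association_rate_se": rate_c_se},
    "spiking": {"dwell_0_5min_s": s1.mean, "n1": s1.n,
                "dwell_5_10min_s": s2.mean, "n2": s2.n,
                "association_rate_per_labeled_nM": rate_s},
    "ranksum_p_spiking_late_vs_control": p_cond,
    "ranksum_p_spiking_late_vs_early": p_time,
}
args.out.mkdir(parents=True, exist_ok=True)
(args.out / "singlemol_summary.json").write_text(json.dumps(payload, indent=1))

print(f"control dwell: {c1.mean:.1f} +- {c1.se:.1f} s (N={c1.n}) then "
      f"{c2.mean:.1f} +- {c2.se:.1f} s (N={c2.n}); "
      f"association rate {rate_c*1e3:.2f}e-3 /um/nM/s")
print(f"spiking dwell: {s1.mean:.1f} +- {s1.se:.1f} s (N={s1.n}) then "
      f"{s2.mean:.1f} +- {s2.se:.1f} s (N={s2.n})")
print(f"rank-sum spiking-late vs control p = {p_cond:.2e}; vs spiking-early p = {p_time:.2e}")
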