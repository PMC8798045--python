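# mtkymo

Quantitative analysis of in vitro microtubule TIRF experiments from
kymographs and traced images: dynamic-instability parameters, templated
nucleation, end-velocity/end-intensity tracking, single-molecule binding
kinetics and cooperativity, curvature–intensity regression, and microtubule
damage/severing intensity statistics — together with a synthetic-data
simulator that generates every input with known ground truth, so each
measurement stage can be validated by parameter recovery.

It is written for people who quantify reconstitution experiments with
microtubule-associated proteins (MAPs): the workflows mirror how such assays
are scored by hand from kymographs, but every rule is explicit, scripted and
tested.

## What it computes

**Dynamic instability** (`mtkymo.dynamics`). From phase-annotated end
trajectories (marked vertices, or automatic piecewise-linear segmentation):

- growth/shrinkage speeds `v_g`, `v_s` as duration/length-weighted phase
  slopes ± weighted SE;
- catastrophe frequency `f_c = n_cat / Σ t_growth` and rescue per shrinkage
  length `n_res / Σ L_shrink`, each with counting error `√n` over the same
  denominator;
- dynamicity `(Σ L_grown + Σ L_lost) / t_observation`, error
  `pixel_size · N / T` with `N` the number of marked points;
- inverse-variance weighted means to pool replicates
  (`w_i = 1/SE_i²`, combined SE `1/√Σw`).

**Templated nucleation** (`mtkymo.nucleation`). A seed nucleates if any
extension exceeds 3 px (480 nm) within 15 min; the fraction–concentration
curve is fitted with the Hill-type sigmoid `y(x) = x^s / (C^s + x^s)` (`C` =
half-max concentration, `s` = steepness), with a parametric binomial
bootstrap for the 95% CIs and the `√N/total` counting error per condition
(`1/total` when `N = 0`).

**End tracking** (`mtkymo.endtrack`). Ordinary-least-squares end velocity
over consecutive 2-min windows; leading negative-velocity windows are
eliminated, windows below −2.5 nm/s are classified as shrinking; probe
intensity at the end is the mean over a 5-px lattice window ending at the
tracked end minus the mean over a 5-px solution window 3 px beyond it.

**Single molecules** (`mtkymo.singlemol`). Dwell times per 5-min interval
(mean ± SE, censoring policy explicit), right-continuous ECDFs, association
rates in events µm⁻¹ nM⁻¹ s⁻¹, and two-sided Wilcoxon rank-sum condition
comparisons.

**Curvature** (`mtkymo.curvature`). Unsigned curvature κ = 1/R from the
circumcircle of three boxcar-smoothed trace neighbors; samples pooled into
0.1 µm⁻¹ bins with 3-scaled-MAD outlier rejection; OLS of bin-mean intensity
on bin-center curvature with slope CI and p-value.

**Lattice intensities** (`mtkymo.lattice`). Masked field intensity (Otsu
mask from the tubulin channel), seed-vs-GDP-lattice Welch comparison,
stretch-direction profiles (20-px linescans normalized to the initiation
point), damage-site linescans, rolling-ball background subtraction, and the
severing-protection statistic: the per-field time at which control tubulin
intensity first stays below 20% of baseline for two consecutive frames, and
the coated population's intensity at that time.

**Simulator** (`mtkymo.simgen`). Two-state (growth/shrink) end trajectories
with exponential waiting times and a seed boundary; a Gillespie model of
(optionally cooperative) single-molecule binding on a 1-D lattice of 8 nm
sites; a two/three-channel kymograph renderer with Gaussian optics; binomial
nucleation counts; damage-site kymographs; severing timecourses. Everything
is reproducible bit-for-bit from `SimConfig.rng_seed`.

## Worked example

The numbered scripts under `analysis/` run each stage on simulated data.
For the dynamic-instability stage:

```bash
python analysis/01_simulate_dynamics.py --seed 0
python analysis/02_dynamic_instability.py --seed 0
```

prints (abridged):

```
        parameter   estimate           se   truth  within_2se
      growth_rate   7.599995 4.799657e-06   7.600        True
      shrink_rate 100.000000 5.641740e-14 100.000        True
 catastrophe_freq   0.003958 6.829017e-05   0.004        True
rescue_per_length   0.189193 6.087183e-03   0.200        True

3359 catastrophes over 848686 s growth; 966 rescues over 5106 um shrinkage;
dynamicity 12.8 nm/s
```

i.e. 500 simulated 30-min trajectories are segmented automatically and the
four generating parameters are recovered within two standard errors; speeds
are exact because noiseless phases are piecewise linear. The nucleation
stage (`analysis/03_nucleation_sigmoid.py`) refits the sigmoid from 50-seed
binomial counts per condition:

```
C = 5.93 uM (95% CI 5.68-6.20), s = 6.08 (95% CI 5.03-7.73) from 400 seeds;
generating values C=5.9, s=6.0
```

and the single-molecule stage (`analysis/05_single_molecule_kinetics.py`)
contrasts independent binding (a ~12 s mean residence in both 5-min
intervals) with the cooperative spiking condition, whose dwell means lengthen
between intervals and differ from the control at p ≪ 0.001 by rank-sum.

A `mtkymo` command-line tool wraps the same stages
(`mtkymo simgen|dynamics|endtrack|nucleation|singlemol|run ...`), and
`mtkymo run --seed 0 --out results/run` executes the configured pipeline end
to end with a provenance record.

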