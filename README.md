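# rollmetrics

Multi-sensor smart-wheelchair mobility analytics: synchronise wheel-IMU,
seat-pressure-mat and GPS streams recorded on independent clocks, derive
frame kinematics and seat centre of pressure (COP), align everything on a
common distance scale, and quantify how strongly an urban route drives a
rider's speed and posture.

The package targets the analysis of instrumented manual-wheelchair runs
over a 789 m suburban course divided into 13 sections (car park, tilted
pavements, downhill streets, a steep lane climb, a final sprint).  It is
written for biomechanics / assistive-technology researchers who need the
full chain from raw sensor CSVs to cohort statistics, and ships a
synthetic-run generator with known ground truth so the entire pipeline is
testable without any field recordings.

## The analysis in brief

- **Clock sync.** Five wheel strikes at each end of a run spike both the
  wheel accelerometer and the mat channels.  The clearest spike per
  pentad gives an anchor pair; two pairs determine the affine slave→master
  map `t_m = m·t_s + Δt_B + b` (skew m, offset Δt_B), anchors exact.
- **Kinematics.** Cambered differential drive: `v = r cosθ·(ω_L+ω_R)/2`,
  yaw rate `r cosθ·(ω_R−ω_L)/(w + 2r sinθ)`, distance by trapezoidal
  integration, with a reference-distance calibration factor.
- **COP.** Piezoresistive cells read through 70 Ω dividers; a 6th-order
  conductance→pressure calibration converts voltages to forces; COP is
  the force-weighted centroid of the cell centres.
- **Synchorisation.** Signals are resampled from time onto a uniform
  distance grid, segmented into the 13 sections, and compared with
  one-way ANOVA + Tukey HSD + Cohen's d; pairs with cohort-mean d ≥ 0.8
  form an effect-size network (weights saturate at d ≥ 2).
- **Route compliance.** Pairwise R² between participants' aligned
  profiles measures route influence; per-participant medians are ranked
  per parameter (speed, COPx, COPy), rank sums ordered, and Kendall's W
  (χ² = m(n−1)W) measures cross-parameter agreement.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
import rollmetrics as rm

# simulate a route-driven participant over the default 13-section course
run = rm.simulate_run(profile=rm.ParticipantProfile("P5", compliance_lambda=0.9),
                      seed=7)
proc = rm.process_run(run)
r = proc.report
print(f"distance {r.total_distance_m:.1f} m, duration {r.duration_s:.0f} s, "
      f"mean speed {r.mean_speed_mps:.2f} m/s")
print(f"clock skew {r.clock_skew:.6f}, sync residual SD {r.sync_residual_sd_s:.3f} s")
print(proc.report.section_table[["section", "v_mean", "copx_mean", "copy_mean"]].head(3))
```

prints

```
distance 789.0 m, duration 673 s, mean speed 1.17 m/s
clock skew 1.000500, sync residual SD 0.000 s
   section    v_mean  copx_mean  copy_mean
0        1  0.830471  -1.517409 -17.508507
1        2  1.029283  -3.927915 -18.592518
2        3  1.247772  -3.695776 -17.918801
```

— the run covered the full course at 1.17 m/s; the planted mat-clock skew
(1.0005) was recovered exactly from the trigger pentads; and the
per-section means sit near the course table values (0.8, 1.02, 1.26 m/s
for sections 1–3) because this participant is 90 % route-driven.

The numbered scripts under `analysis/` run the same chain over a
simulated 7-participant cohort and write the tabular results under
`results/`:

```sh
python analysis/01_simulate_cohort.py     # raw runs -> results/runs/P*/
python analysis/02_process_runs.py        # sync, kinematics, COP, alignment
python analysis/03_section_effects.py     # section stats + effect networks
python analysis/04_route_compliance.py    # R^2, ranks, Kendall's W
```

The final step reports, e.g.:

```
most route-driven: P5 (rank sum 21); most individualistic: P1 (rank sum 4)
Kendall's W = 0.825 (chi2 = 14.86, p = 0.0214)
```

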