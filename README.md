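# suvrdyn

Simulation and estimation tools for measuring the **dynamics of striatal
dopamine increases** from dual-scan [¹¹C]raclopride PET during a
methylphenidate (MP) challenge.

## The problem

Static PET endpoints (binding potential, BP<sub>nd</sub>) quantify *how
much* extracellular dopamine a stimulant releases, but not *how fast*.
Speed matters: intravenous drug delivery produces fast dopamine rises and
strong reward, oral delivery slow rises and little reward. A simple,
model-free handle on the dopamine rise is the time-varying difference in
standardized uptake value ratios between a placebo and a challenge scan,

```
SUVr(t)  = C_T(t) / C_r(t)                 (striatum over cerebellum)
ΔSUVr(t) = SUVr_PL(t) − SUVr_MP(t)
```

which grows as dopamine competes raclopride off D2/3 receptors. This
package provides, for that measurement chain:

- a **mechanistic simulator**: tri-exponential tracer input; one-tissue
  cerebellum reference (`dC_r/dt = K1r·C_p − k2r·C_r`); an LSSRM striatal
  target with a time-varying efflux term `γ·h(t)·C_T` for the
  dopamine–raclopride binding competition; a two-tissue DAT-occupancy model
  for free/bound MP (`dR/dt`, `df_occ/dt`); and the scaled dopamine
  response `dD/dt = β·[f_occ − (1−f_occ)·D]`;
- a **model-free estimator**: a two-parameter gamma cumulative distribution
  `F(t′) = A/Γ(s) ∫₀^{t′} e^{−x} x^{s−1} dx` fitted to ΔSUVr(t), whose
  density mode gives the dopamine-rate time-to-peak, `TTP = s − 1`;
- **Logan reference-region analysis** (DVR, BP<sub>nd</sub> = DVR − 1,
  t\* = 20 min) for static validation;
- **Monte-Carlo experiments** quantifying specificity (occupancy vs
  dopamine dynamics), dose sensitivity, robustness to injection-time jitter
  and physiologic parameter variability, and recovery of the true
  dopamine-rate TTP — with a vectorized fixed-step integrator validated
  against the adaptive reference solver.

No external data are needed; every input is generated by the simulator.

## Worked example

```python
import numpy as np, suvrdyn as sd

grid  = sd.default_grid()                             # 1-min frames, 0-90 min
dense = sd.TimeGrid(np.arange(0.0, 90.0001, 0.01))

# DAT occupancy and dopamine response to the IV bolus at +30 min
traj = sd.simulate_occupancy_da(sd.MPKineticParams(), sd.MPPlasmaParams(),
                                sd.DAParams(), dense)
print(f"peak DAT occupancy: {100*traj.peak_occupancy():.1f}%")
print(f"true dopamine-rate TTP: {sd.true_rate_ttp(traj):.1f} min after the bolus")

# noiseless scan pair -> delta-SUVr -> gamma-CDF fit
ref    = sd.simulate_reference_tac(sd.RacloInputParams(),
                                   sd.ReferenceKineticParams(), dense)
h      = sd.make_h("DA_INCREASE", traj)
tgt_mp = sd.simulate_target_tac(ref, sd.LSSRMParams(), h, dense)
tgt_pl = sd.simulate_target_tac(ref, sd.LSSRMParams(gamma=0.0), None, dense)
to_grid = lambda tc: sd.TimeCourse(grid, tc.interp(grid.times), tc.label)
pair  = sd.SUVrPair(sd.compute_suvr(to_grid(tgt_pl), to_grid(ref)),
                    sd.compute_suvr(to_grid(tgt_mp), to_grid(ref)))
fit   = sd.fit_gamma_cdf(sd.delta_suvr(pair), mp_onset=30.0)
print(f"fitted amplitude A = {fit.amplitude:.2f}, shape s = {fit.shape:.1f}, "
      f"TTP = {fit.ttp:.1f} min (converged={fit.converged})")

logan = sd.logan_ref(to_grid(tgt_pl), to_grid(ref), t_star=20.0)
print(f"placebo Logan DVR = {logan.dvr:.2f}, BPnd = {logan.bp_nd:.2f}")
```

prints

```
peak DAT occupancy: 64.3%
true dopamine-rate TTP: 21.1 min after the bolus
fitted amplitude A = 4.68, shape s = 23.3, TTP = 22.3 min (converged=True)
placebo Logan DVR = 6.92, BPnd = 5.92
```

The canonical IV dose blocks about two thirds of the transporters; the
dopamine-increase rate peaks ~21 min after the bolus, and the gamma-CDF fit
to the noiseless ΔSUVr recovers a time-to-peak close to it. The Logan
BP<sub>nd</sub> of the placebo scan equals the kinetic ratio
`k2/k2a − 1 = 5.92`, tying the dynamic simulation to the standard static
endpoint.

A command-line interface covers the same ground:

```sh
suvrdyn simulate --route IV --noise-cv 0.03 --seed 3 --out pair.tsv
suvrdyn fit pair.tsv --onset 30
suvrdyn experiment --name ttp_recovery --route IV --n 1000 --seed 7 --outdir out/
suvrdyn fixture --scenario IV_PAPER --seed 1 --outdir fixtures/
```

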