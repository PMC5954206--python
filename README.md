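# reappose

**Radial re-apposition pressures for type-B aortic dissection flaps.**

In a Stanford type-B aortic dissection, a torn intimal flap divides the
aorta into a true lumen (TL) and a false lumen (FL). Endovascular repair
uses a balloon or stent to press the flap back against the FL wall so the
aorta regains a single lumen. Sizing such devices needs the *re-apposition
pressure* P_re-app: the radial contact pressure, beyond the static aortic
pressure, at which the flap is fully re-apposed. `reappose` computes it with
a bench-protocol-faithful computational model for porcine thoracic aortas:

* **GOH constitutive model** — Ψ = C10(I1−3) + k1/(2k2) Σ±α [exp(k2E²)−1],
  E = κ(I1−3) + (1−3κ)(I4−1) — with per-pig flap and wall parameter tables
  (mid and distal regions) shipped as data;
* **planar-biaxial parameter estimation** by multi-start Nelder–Mead with a
  seeded synthetic-data generator for round-trip and noise studies;
* an **idealized dissected cross-section** (TL wall / FL wall / intimal
  flap, flap spanning 50–60 % of the circumference) meshed with
  quadrilaterals;
* a **plane-strain finite-strain contact solver** that replays the two-step
  bench protocol: pressurize the vessel (70–140 mmHg), then expand a rigid
  circular member until every flap node lies within 1 % of the flap
  thickness from the FL wall; P_re-app is the average contact pressure on
  the member, in mmHg.

The model and its numerical choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

```python
from reappose import run_sweep, SolverOptions

opts = SolverOptions(member_step_mm=0.3, newton_tol=1e-6,
                     flap_drape_bias_mmhg=0.5)
sweep = run_sweep("mid", "mid_1", options=opts, h=0.6)
for r in sweep.results:
    print(f"p_aorta={r.p_aorta_mmhg:5.0f} mmHg  "
          f"P_re-app={r.radial_pressure_mmhg:6.2f} mmHg  "
          f"diameter={r.final_inner_diameter_mm:5.2f} mm")
```

which prints (pig #1 mid flap, 0.6 mm elements, assumed 18 mm unloaded
inner diameter):

```
p_aorta=   70 mmHg  P_re-app= 50.92 mmHg  diameter=20.82 mm
p_aorta=   80 mmHg  P_re-app= 57.80 mmHg  diameter=21.21 mm
p_aorta=   90 mmHg  P_re-app= 70.38 mmHg  diameter=21.60 mm
p_aorta=  100 mmHg  P_re-app= 74.75 mmHg  diameter=21.99 mm
p_aorta=  110 mmHg  P_re-app= 79.89 mmHg  diameter=22.41 mm
p_aorta=  120 mmHg  P_re-app= 86.64 mmHg  diameter=22.85 mm
p_aorta=  130 mmHg  P_re-app=103.32 mmHg  diameter=23.42 mm
p_aorta=  140 mmHg  P_re-app=126.38 mmHg  diameter=24.06 mm
```

The re-apposition pressure rises monotonically with aortic pressure — the
flap must stretch further to conform to the dilated wall — and the final
diameter grows with it. Absolute magnitudes depend on the assumed unloaded
radius and on the strictness of the full-apposition gap criterion (see the
methods note); the trends are the robust output.

A thin CLI wraps the same functions:

```bash
reappose sweep --region mid --flap-row mid_1 --h 0.6 --out mid1.csv
reappose fit --data biaxial.csv --out params.csv --restarts 8 --seed 0
reappose mesh-convergence --region mid --h 0.3 --out conv.json
```

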