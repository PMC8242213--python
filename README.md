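# cardiorenal

An integrated quantitative-systems-pharmacology model of the heart and
kidney for studying left-ventricular hypertrophy and its regression under
antihypertensive therapy. The package couples three timescales in one
deterministic simulator:

* **beats (seconds)** — one-fiber ventricular mechanics
  (`P = (1/3)(σ_f − 2σ_m,r)·ln(1 + V_w/V_cav)`) driving a seven-compartment
  lumped circulation with diode valves and arterial inertance;
* **homeostasis (hours–days)** — renal hemodynamics, Starling filtration,
  three-segment tubular sodium/water handling, whole-body fluid balance,
  and the neurohormonal feedbacks (renin–angiotensin–aldosterone, ANP,
  vasopressin, tubuloglomerular/myogenic/pressure-natriuresis signals,
  whole-body flow autoregulation);
* **remodeling (months)** — stress-driven myocyte growth: peak systolic
  fiber stress above its setpoint thickens myocytes
  (d(ΔD)/dt = K_d·(σ_f,peak/σ_f,peak,0 − 1), concentric), elevated
  end-diastolic fiber stress lengthens them (eccentric, one-way ratchet),
  and the wall volume and unloaded cavity volume follow the myocyte
  geometry.

Blood volume (set by renal sodium/water excretion) and mean arterial
pressure (set by the circulation) are the two quantities that bind heart
and kidney together. The packaged experiments impose aortic stenosis (an
arterial-resistance ramp), mitral regurgitation (a valve back-leak
threshold ramp), and therapy on a hypertensive virtual patient (losartan
as 92% AT1-receptor blockade; atenolol as a heart-rate reduction plus
renin-secretion inhibition).

Intended users: modelers in cardiovascular/renal physiology and QSP who
want a fast, fully inspectable mechanistic sandbox for cardiorenal
interactions — every feedback is an explicit, documented function.

## Worked example

```python
from cardiorenal import CardiorenalModel, InterventionSchedule, losartan_effects

model = CardiorenalModel()                       # calibrated defaults
state = model.initialize_steady_state()          # coupled baseline
s = model.beat_summary(state)
print(f"{s.SBP:.1f}/{s.DBP:.1f} mmHg, EF {100*s.EF:.1f}%, CO {s.CO:.2f} L/min, "
      f"sigma_peak {s.sigma_f_peak:.2f} kPa, sigma_ED {s.sigma_f_ED:.2f} kPa")

res = model.run_scenario(state.copy(), InterventionSchedule(losartan_effects()),
                         duration_days=42, remodeling="none")
end = res.trajectory.iloc[-1]
print(f"losartan: MAP {s.MAP:.1f} -> {end.MAP:.1f} mmHg, PRC x{end.PRC:.1f}, "
      f"AT1-bound AngII {end.AT1_AngII:.2f}")
```

prints

```
112.6/68.7 mmHg, EF 69.1%, CO 5.00 L/min, sigma_peak 49.20 kPa, sigma_ED 4.23 kPa
losartan: MAP 81.3 -> 68.4 mmHg, PRC x8.0, AT1-bound AngII 0.64
```

The baseline is a normal adult at heart rate 70 (blood pressure 113/69,
ejection fraction 69%, cardiac output 5 L/min, GFR 100 mL/min, blood volume
4.95 L), sitting exactly at the growth setpoints so the heart neither grows
nor shrinks. AT1 blockade triggers the renin rise (compensatory
disinhibition of secretion) while bound AngII still falls — natriuresis and
vasodilation lower mean arterial pressure to a new renal balance point.

From a shell, the same scenarios run as

```bash
cardiorenal simulate --scenario aortic_stenosis_fit --out out/ --plots
cardiorenal simulate --scenario life_losartan --out out_los/
```

writing `trajectory.csv`, `summary.json` and a reproducibility manifest.
Scenario names: `baseline`, `aortic_stenosis_explore` (5×),
`aortic_stenosis_fit` (3×), `mitral_regurg_explore`, `mitral_regurg_fit`,
`life_losartan`, `life_atenolol`, `fig7_renin_only`, `fig7_hr_only`; the
`--remodeling {both,diameter,length,none}` flag selects the active growth
laws.

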