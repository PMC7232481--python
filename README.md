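# digesterkit

Monitoring and modelling toolkit for trace-element-limited anaerobic
digesters: methane-kinetics breakpoint detection as an early-warning
statistic, ideal-CSTR washout of supplemented micronutrients, COD/Buswell
stoichiometric accounting, and longitudinal community statistics on ASV
count tables — plus a seeded synthetic digester generator so the entire
pipeline runs and is testable without any external data.

It is written for bioprocess engineers and microbial ecologists who operate
continuously stirred biogas reactors (CSTRs) and want to detect trace-element
(Co, Ni, Se, W) deficiency *before* volatile fatty acids (VFAs) accumulate
and the process drifts toward failure.

## The models at the core

**Breakpoint regression.** After each daily feeding pulse, cumulative
methane `y(t)` rises steeply while fermentation intermediates are turned
over, then settles onto a shallow residual slope once VFAs are depleted.
digesterkit fits the continuous two-segment model

    y(t) = β₀ + β₁ t + β₂ (t − k)₊

by least squares, profiling the knot `k` over every observed sample time
(vectorised exact scan) with golden-section refinement. The day-by-day
drift of `k` toward the 24-h window edge is the early-warning statistic: in
a trace-element depletion scenario it moves roughly a week before
propionate accumulation becomes measurable.

**CSTR washout.** A perfectly mixed reactor with balanced feed and
withdrawal dilutes a non-reacting solute as

    dC/dt = (C_in − C)/HRT  ⇒  C(t) = C_in + (C(tᵢ) − C_in) e^{−(t−tᵢ)/HRT}

between dosing events; stopping the feed input leaves `e^{−3}` ≈ 5% after
three hydraulic retention times. With HRT 30 d and depletion at day 206,
0.13 nM Ni passes 0.06 nM at day 229 and 0.02 nM at day 257.

**Stoichiometry.** Buswell's formula for CₙHₐO_b gives `n/2 + a/8 − b/4`
mol CH₄ per mol; with 22.414 L/mol and 64 g COD per mol CH₄ this is the
canonical 350 mL CH₄ per g COD at 0 °C, 1 atm.

**Community statistics.** First-order Hill diversity `¹D = exp(H)` and
evenness `¹E = ¹D/⁰D`, Hellinger standardisation, Bray–Curtis
dissimilarities, NMDS (Kruskal stress-1, SMACOF with isotonic regression,
seeded restarts), k-means with Calinski–Harabasz model-order selection, and
Dufrêne–Legendre indicator values (`IndVal = 100·A·B`) with permutation
p-values.

## Worked example

```python
import numpy as np
from digesterkit import TwoSegmentRegression, TEDosingHistory
from digesterkit.washout import DoseEvent, concentration_at, nM_to_ng_per_gCOD

# nickel washout after supplementation stops at day 206 (HRT 30 d)
ni = TEDosingHistory("Ni", 0.13, 30.0, (DoseEvent(206.0, "step", 0.0),))
for day in (206, 229, 257):
    print(f"Ni at day {day}: {concentration_at(ni, day):.2f} nM")
print(f"as fed: {nM_to_ng_per_gCOD(0.13, 'Ni', 51.0):.2f} ng/gCOD")

# breakpoint of one noisy daily methane cycle (5-min samples)
rng = np.random.default_rng(0)
t = np.arange(0.0, 1441.0, 5.0)
y = 1.6 * np.minimum(t, 700.0) + 0.1 * np.clip(t - 700.0, 0.0, None)
y += rng.normal(0.0, 8.0, t.size)
res = TwoSegmentRegression(t, np.maximum.accumulate(y)).fit()
print(res.summary())
```

prints

```
Ni at day 206: 0.13 nM
Ni at day 229: 0.06 nM
Ni at day 257: 0.02 nM
as fed: 0.15 ng/gCOD

Two-segment linear regression
=============================================
observations                              289
knot (min after feeding)               701.90
slope, active segment                  1.6017
slope, residual segment               0.12008
intercept                              1.4354
SSE (two segments)                     8002.1
SSE (single line)                  6.8944e+06
censored                                False
degenerate                              False
```

The washout trajectory says the supplemented nickel fraction halves about
every 21 days once dosing stops; the regression recovers the planted 700-min
transition (701.9 min) and the active/residual production rates (1.60 and
0.12 mL/min) despite the sensor noise.

A full synthetic experiment — four reactors, 350 days, depletion at day
206 — runs from the command line:

```sh
digesterkit run --out out/
```

and reports, per reactor, the breakpoint trend and alarm day, trace-element
milestones, VFA onset days, and community summaries (diversity, NMDS
stress, chosen k, top indicator genera). In the default scenario the
Ni-deprived reactor alarms at day 223, seven days before simulated
propionate accumulation (day 230), while the control reactors never alarm.

## Layout

- `src/digesterkit/gas.py` — normalization to dry normal conditions,
  sensor fusion, smoothing, feeding-cycle segmentation
- `src/digesterkit/breakpoints.py` — two-segment regression, trend, alarm
- `src/digesterkit/washout.py` — CSTR solute balance and unit conversions
- `src/digesterkit/substrate.py` — TE contribution table, Buswell/COD, VFA
  conversions, COD balance
- `src/digesterkit/community.py` — Hill numbers, Hellinger, Bray–Curtis,
  NMDS, k-means/CH, IndVal, ANOVA, ASV table container
- `src/digesterkit/synthetic.py` — seeded synthetic experiment generator
  with an exactly-closing COD ledger
- `src/digesterkit/pipeline.py`, `cli.py` — orchestration and the
  `digesterkit` command

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and the limitations of the synthetic data.
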