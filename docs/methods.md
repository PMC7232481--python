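# Methods

This note documents the models behind `digesterkit`, the defaults they
ship with, and what the synthetic experiment generator does and does not
emulate.

## Gas normalization and sensor fusion

Displacement gas meters report volume at their own temperature and
pressure; all volumes in this package are re-expressed at dry normal
conditions, T0 = 273.15 K and p0 = 1013.25 hPa, by the ideal-gas scaling
`V_n = V * ((p - p_w*saturated)/p0) * (T0/T)`.  The water-vapour partial
pressure `p_w` is subtracted only for streams flagged water-saturated and
comes from the Magnus formula `p_w = 6.1094 * exp(17.625*T/(T+243.04))` hPa,
accurate to well under 1% between 0 and 60 degC; any formula of that
accuracy would serve, and the choice is recorded here and visible in
`gas.magnus_svp`.

The CH4 fraction stream is aligned to the flow grid by linear
interpolation; extrapolation outside the sensor's time range is an error
rather than a guess.  Smoothing is a centred moving average (default 15
min) with truncated windows at the edges; truncation keeps the output grid
equal to the input grid at the cost of exact global-mean preservation (the
edge effect is O(window/n) and is only material for very short series).

Feeding cycles are half-open intervals `[feed, next feed)` capped at 1440
min, so every sample belongs to exactly one cycle.  Cycles with an internal
gap above 30 min are flagged incomplete and excluded from breakpoint
trending, which avoids spurious knots at gap boundaries.

## Two-segment breakpoint regression

Cumulative methane after a feeding pulse is modelled as a continuous
two-piece linear function `y = b0 + b1*t + b2*(t-k)+`.  Cumulative volume
(rather than the rate) is fitted because the two-line intersection is then
well-posed and noise is integrated instead of differentiated; the rate
representation is kept for display.  For a fixed knot the problem is
linear, so the knot is profiled out: an exact SSE scan over every observed
sample time (excluding 3 samples per edge so both segments keep support),
vectorised with prefix sums, followed by golden-section refinement between
the two neighbouring grid points.  Refinement is only accepted on a strict
SSE improvement, so exactly-recoverable knots on noiseless piecewise-linear
data stay exact.  Ties in the scan break to the earliest knot, which is the
conservative choice for an early-warning statistic.

A fit is *degenerate* when the two-segment SSE improves on the single-line
SSE by less than 1% (no knot structure to report), and *censored* when the
best knot presses against the candidate-window edge; censored cycles enter
the trend at the 1440-min cap, encoding "drifted out of the 24-h window"
without extrapolating.

The day-by-day trend is summarised by a trailing-window (default 7 days)
least-squares slope of knot versus day.  The alarm fires on the first day
the slope exceeds 15 min/day for 3 consecutive entries, or the knot exceeds
1200 min.  Both thresholds are configuration values with no prescribed
source; 15 min/day sits roughly 3 sigma above the day-to-day slope noise of
a stable reactor in the synthetic experiments, and 1200 min (20 h) flags a
breakpoint about to leave the daily window.

Confidence intervals for the knot and multi-knot model selection are out of
scope by design.

## Ideal-CSTR trace-element washout

A continuously stirred reactor with balanced feed and withdrawal dilutes a
non-reacting solute as `dC/dt = (C_in - C)/HRT`, solved in closed form
between dosing events; step events change `C_in`, pulse events add to `C`
instantaneously.  After supplementation stops, `exp(-3) = 4.98%` of the
supplemented fraction remains after 3 HRTs — the classical >95% reduction.
Daily discrete feeding differs from this continuous-dilution approximation
by under 2% at HRT 30 d.  A fixed-step adaptive ODE integration of the same
balance is kept solely as a cross-check (`washout._numeric_reference`); the
closed form is the implementation.

Conversions use IUPAC molar masses (Co 58.933, Ni 58.693, Se 78.971,
W 183.84 g/mol) registered in one place, and a feed COD of OLR x HRT
(1.7 gCOD/L/d x 30 d = 51 g/L).  Note that 0.32 nM Co and 0.08 nM W convert
to 0.37 and 0.29 ng/gCOD with these constants, one unit in the last digit
away from the commonly quoted 0.36 and 0.28 — consistent with those
figures having been rounded from unrounded concentrations; the Ni and Se
conversions (0.15 and 0.11 ng/gCOD) reproduce exactly.

Substrate-matrix TE contributions are tracked separately from the
supplemented (ionic) fraction and never added to washout trajectories,
mirroring how such calculations report "the supplemented fraction".  The
magnitude of an unrecorded pulse dose can be back-solved from any later
concentration because the balance is linear
(`washout.solve_pulse_magnitude`).

## Substrate accounting

Per-component TE contributions are kept as a component x element table in
ng per litre of substrate; totals round to two significant digits with
round-half-to-even.  Two published totals for this kind of table (Ni 27,000
and W 250 ng/L) cannot be recovered from their own rounded components
(which sum to 26,361 -> 26,000 and 244 -> 240); they were evidently
computed from unrounded measurements, so the package documents them as
irreproducible-from-printed-data and asserts only the Co (580) and Se
(4200) totals.

Buswell stoichiometry for CnHaOb gives `n/2 + a/8 - b/4` mol CH4 per mol,
and with 22.414 L/mol and 64 g COD per mol CH4 the canonical 350 mL CH4 per
g COD at 0 degC, 1 atm.  Nitrogen and sulphur extensions are omitted; the
substrates of interest are carbohydrates, acids, and alcohols.

## Community statistics

Diversity is reported as first-order Hill numbers: `1D = exp(Shannon)` and
evenness `1E = 1D/0D`.  The ratio form of first-order evenness is a
declared choice (several evenness conventions exist); it is dimensionless
in (0, 1] and equals 1 exactly for uniform communities.

The ordination chain is: Hellinger standardisation (per-sample square root
of relative abundances, giving unit-norm rows), Bray-Curtis
dissimilarities, and NMDS minimising Kruskal stress-1 via SMACOF with
isotonic regression of embedded distances on the dissimilarities.  NMDS
runs one warm start from classical (Torgerson) scaling plus 19 random
restarts by default; the reported stress-1 is recomputed from the winning
embedding with a fresh isotonic fit, so the number is
definition-consistent regardless of the optimiser's internal bookkeeping.
Identical seeds give identical embeddings.

K-means operates on the Hellinger-standardised matrix (seeded k-means++,
best of 10 restarts); the number of clusters is the Calinski-Harabasz
argmax over k = 2..k_max.  A CH curve whose maximum is under 1.25x its
minimum is treated as structureless: the result is flagged
`weak_structure` and k falls back to a nominal 2.  An average-linkage
dendrogram of the Bray-Curtis matrix is available for visual comparison
only — no automated decision uses it.  Library sizes are handled as
proportions rather than by rarefying; a switch is not needed because every
consumer of counts normalises per sample.

Indicator taxa follow Dufrene-Legendre: specificity A is a cluster's share
of the across-cluster mean relative abundance, fidelity B its within-
cluster occurrence fraction, indval = 100*A*B, and each taxon's p-value is
the one-sided permutation tail of its maximum indval under label
reshuffling with `p = (1 + exceedances)/(n_perm + 1)` (999 permutations by
default).  Cluster/parameter association uses the classical one-way ANOVA
F test.

## The synthetic experiment generator

The generator exists so the full pipeline runs, and is testable, with no
external data.  It emulates a set of 4-L mesophilic CSTRs at HRT 30 d and
OLR 1.7 gCOD/L/d fed once daily, with supplementation of Co/Ni/Se/W
withdrawn at day 206 of a 350-day horizon and an accidental Se/W overdose
on days 109-110 whose magnitude is back-solved so the supplemented Se/W
fractions pass 0.12/0.13 nM at day 229.

The core is a small COD-conserving pool model at minute resolution: feed
pulses split among an inert fraction (0.29), fast sugars (0.445), slowly
degraded amino acids (0.06), and directly fed acetate (0.085) and
propionate (0.12).  Fermentation (first order, with a 10% biomass yield)
routes COD to acetate/propionate/hydrogen at 0.40/0.30/0.30; syntrophic
propionate and butyrate oxidation split products by COD stoichiometry
(0.571/0.429 and 0.8/0.2 to acetate/H2, 5% yield); methanogenesis takes a
13.75% yield.  These yields put steady-state methane near 53% of the
Buswell potential and biomass near 15% of fed COD.  Consumption capacities
(Monod with small half-saturations) are roughly twice their daily loads
under full supplementation, which places the transition of the daily
methane curve to its residual level near 11-12 h after feeding.

Trace-element limitation multiplies the propionate-oxidation and
hydrogen-disposal capacities by a product of per-element Hill factors
`C^h/(K^h + C^h)` (default h = 6; h = 1 recovers a Monod factor)
evaluated on the supplemented fraction plus a per-element bioavailable
background.  A steep response is required by the observed phenomenology: a
control reactor runs indefinitely at 0.07 nM Se while a depleted reactor
destabilises as its (overdose-elevated) Se passes ~0.05 nM on the way
down, and a Monod factor cannot produce both together with the ~2x
capacity headroom the 12-h breakpoint implies.  Acetoclastic
methanogenesis carries a *partial* TE coupling (`1 - w + w*F`, w = 0.6):
methanogens need the same cofactors, and without this term the early
cascade corner stays fixed while the late corner drifts, making the
fitted single knot hop between corners instead of drifting smoothly.  The
background is non-zero only for Co (9.2 nM, the casein contribution),
encoding the observation that substrate-matrix Co sufficed while matrix
Ni/Se/W were unavailable; all of this is configuration, not hard-coding.

Downstream couplings generate the failure sequence: accumulated propionate
inhibits acetoclastic methanogenesis (KI = 10 mM), high hydrogen diverts a
share of fermentation electrons to butyrate, a piecewise-linear pH proxy
falls with total VFA (7.1 down through 5.7 as VFA passes ~55 mM), and low
pH shuts the methanogens down between pH 6.0 and 5.2.  Hydrogen also
escapes to off-gas with a first-order rate, booked in the ledger.  With
defaults, the Ni-depleted reactor shows propionate accumulation from day
~230 (Ni ~0.06 nM), acetate from ~234, butyrate from ~241, and failure at
~244, with the breakpoint alarm at day ~223 — about one week before
propionate onset — while control reactors never alarm.  The late phase is
deliberately stylised: the real decline stretched over ~110 days, the
synthetic one over ~15, because the model omits the buffering, storage,
and adaptation processes that slow a real collapse.  Event *ordering*, not
pacing, is the modelled claim.

Every COD flux is booked exactly, so the daily balance
(fed = methane + biomass + effluent + H2 off-gas + inventory change)
closes to floating-point precision; a relative imbalance above 1e-6 raises
immediately as a simulator bug.

The sensor layer inverts the normalization to meter conditions (21 degC,
saturated, 1013.25 hPa), models the CH4 fraction as an affine function of
daily activity (0.55 at steady state, falling toward 0.29 at failure), and
adds Gaussian noise (1.5% of mean flow; 0.005 absolute on the fraction),
clipping flows at zero.  VFA profiles are sampled weekly at the pre-feed
trough with 2% multiplicative plus 0.03 mM additive noise.  ASV tables are
Dirichlet-multinomial draws (concentration 300, depth 20,000) around a
13-genus bacterial baseline dominated by a Lachnospiraceae-like group
(~48%) and a Thermovirga-like group (~28%); the composition interpolates
toward a disturbed profile as a function of cumulative VFA exposure
(saturating scale 1200 mM-days), so bacterial communities drift only
after VFA accumulation while a 6-genus archaeal community stays at its
baseline.  Real amplicon data differ in ways the generator does not
attempt: hundreds of rare ASVs, compositional overdispersion beyond
Dirichlet-multinomial, primer and copy-number biases, and taxa appearing
de novo.  Passing community tests therefore demonstrates the statistics,
not ecological realism.

Each day's *residual transition time* — the ground truth for breakpoint
recovery — is logged from the noise-free rate curve as the (mid-step) time
the rate last sits above the residual level plus 15% of the peak-residual
span.  In the idealised `pulse_fermentation` mode (instantaneous
fermentation at feeding), cycles are exactly two-phase and the fitted knot
recovers this time within one sampling interval; under default kinetics
the active phase is curved and the knot tracks the transition within the
width of the final cascade step (tested at 90 min).

## Numerical choices

Explicit Euler at dt = 1 min with per-step flux clamping (no pool goes
negative, shared-pool consumers scale jointly) keeps the bookkeeping exact;
the kinetics are far from stiff at this step size.  Knot scans solve
stacked 3x3 normal equations; golden-section refinement stops at a 1e-10
relative interval.  Rounding for comparisons against printed values uses
two decimals (nM), two significant figures (mg/L, ng/L) and three
(mL/gCOD), always round-half-to-even.  Degenerate inputs — all-zero count
rows, zero-sum pairs in Bray-Curtis, zero within-group variance in ANOVA,
zero within-cluster scatter in CH — are rejected or flagged rather than
silently propagated.

## Known limitations

- The washout model ignores speciation, sulphide precipitation, and
  sorption: it predicts the supplemented ionic fraction, not
  bioavailability.
- The two-segment model reports a single knot; days with several genuine
  rate transitions are summarised by whichever transition dominates the
  SSE.
- The pH proxy is a calibrated map from total VFA, not carbonate
  chemistry, and the simulated failure is faster than a real one.
- Simulator rate constants are not literature values; they are free
  parameters fixed once to reproduce the qualitative event structure of a
  TE-depletion experiment and are all exposed in `SimConfig`.
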