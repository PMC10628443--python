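# Methods

This note records the conventions, algorithms and known limits behind
`lysimetrics`.  Units throughout: weight in g, time in minutes or days,
volumetric soil water content (SWC) in cm³/cm³, VPD in kPa.

## 1. Gravimetric signal extraction

A covered-soil pot–plant system loses weight only through transpiration,
so the interval transpiration rate between consecutive records is

```
rate_raw = (w(t_i) - w(t_{i+1}) + dose_in_interval) / dt
```

**Irrigation handling.**  The default mode (`subtract`) adds the logged
dose back to the interval weight change — an exact inversion of the water
balance whenever dose amounts are trustworthy.  A `mask` mode is provided
for logs with unreliable amounts: intervals overlapping an event, a guard
window around it (default ±6 min, for drainage transients), or showing a
weight gain are excluded.  Masking necessarily discards any real
(nocturnal) transpiration inside the guard window, so only the subtract
mode can reproduce ground truth exactly; the tests assert the guard's
locality in mask mode and exactness in subtract mode.

**Raw vs cleaned rates.**  Daily transpiration sums use `rate_raw`
(unsmoothed, unclipped): the sum telescopes, so total extracted water
equals total weight loss plus logged doses *exactly*, noise included.
Instantaneous quantities (midday rate, conductance) use a cleaned series:
centred rolling median (default width 5) then clipped at zero.  Days with
less than 80% record coverage are flagged invalid and excluded from
downstream averages rather than silently diluted.

**Derived signals.**
- SWC: `(weight - tare - plant_mass_correction) / pot_volume`, clipped to
  [0, 1]; weights more than 25 g below tare raise an error.
- Midday rate/SWC: means within the 15:00–17:00 window, when ambient
  demand is most stable.
- Canopy conductance: daytime mean of `rate / VPD` in g min⁻¹ kPa⁻¹.
  This is a documented operational definition (rate normalised by
  concurrent VPD), not a calibration to any proprietary instrument
  output; only orderings and ratios of conductance should be compared
  across analyses.

## 2. Bilinear water-response model

Midday transpiration rate versus midday SWC is fitted with the continuous
plateau-then-decline model

```
TR(s) = TRmax                          s >= theta_crit
TR(s) = TRmax - b (theta_crit - s)     s <  theta_crit,   b >= 0
```

**Estimator.**  For a fixed breakpoint θ the model is linear in
(TRmax, b), with the closed-form constrained least-squares solution (b
clamped at 0).  The profile over θ is evaluated on a candidate grid
(uniform over the inner 5th–95th percentile plus every interior data
value), then *refined exactly*: for every admissible decline/plateau
partition of the sorted data, the unconstrained three-parameter optimum
(plateau mean, decline OLS line, breakpoint at their intersection) is
computed in closed form and accepted when consistent with the partition.
Within a partition the profile's interior stationary point is exactly
this closed-form optimum, and partition boundaries coincide with data
values — so the candidate set provably contains the global minimiser.
Ties are broken by lowest SSE, then largest θ (earlier stress onset).
Degenerate inputs (all points in one regime, or no resolvable decline)
are returned with an explicit `status` and refused by the derived
quantities.

The test suite contains an *independent* brute-force oracle
(`tests/oracles.py`) implementing the same enumeration with plain
`np.polyfit` formulas; the production fit must match its SSE to ≤ 1e-10
on random instances.  A fine uniform grid alone cannot meet such a bound
(discretisation error ~1e-6), which is why the oracle enumerates
partitions exactly.

**Derived quantities.**
- *Terminal drought point*: the minimum observed SWC and the fitted rate
  there — the physiological state reached at the end of drought.
- *Trapezoid area*: `0.5 (TRmax + TR_term)(theta_crit - SWC_term)`, the
  integral of the declining limb — an index of how much a plant keeps
  transpiring after stress onset; cross-checked by numeric quadrature.
- *Implied slope*: `(TRmax - TR_term)/(theta_crit - SWC_term)` via
  `slope_from_geometry`, a consistency check that a reported parameter
  set describes a single line.  Note: the simulator's default cultivar
  profiles keep their `decline_slope` values as configured even where
  the slope implied by a profile's typical terminal geometry differs;
  the classification semantics (section 4) depend on the configured
  slope assignment, and `slope_from_geometry` exists precisely to make
  such inconsistencies visible.
- *Cumulative transpiration* between the first midday date below
  theta_crit and the terminal day, summed from raw interval rates.

## 3. Synthetic experiments and identifiability

The simulator advances a per-plant water store on the 3-minute grid:
demand = bilinear(SWC) × VPD factor × photoperiod gate × stress
multiplier, capped by the water available above a wilting floor.  Design
choices that matter for inference:

- **VPD forcing**: a sinusoid with configurable mean (default 1.7 kPa)
  and amplitude (0.7 kPa), peaking at 16:00 — the centre of the midday
  window, where the sinusoid's flat extremum keeps the VPD factor nearly
  constant, so pooled midday points lie on a single scaled bilinear
  curve.  The demand's VPD response is normalised so f(mean VPD) = 1;
  consequently extracted *midday* plateau rates are ≈ peak-VPD/mean-VPD
  (~1.4) times the configured `tr_max`.  Breakpoints and relative slopes
  are unaffected; comparisons of fitted TRmax against configured values
  are therefore made as orderings/ratios, not absolutes.
- **Irrigation timing**: nocturnal, 02:00, delivered as discrete 100 g
  pulses and logged per pulse.  The deficit dose computed at 02:00 of
  day *d* equals `deficit_fraction ×` the plant's true transpiration of
  day *d−1* exactly, and the first recovery-morning refill makes recovery
  day 1 fully watered.
- **Recovery carry-over**: a demand multiplier seeded at the bilinear
  reduction factor reached at the end of drought, rising linearly at the
  cultivar's `recovery_rate` per day (capped at 1).  Combined with the
  irrigation timing, the configured `recovery_rate` is by construction
  the true slope of relative transpiration versus time — the quantity the
  rTR regression estimates.
- **Noise**: i.i.d. Gaussian on the weight *records* only; the internal
  water balance is exact, so ground-truth daily transpiration is exact.

**Right-censoring of theta_crit.**  Under the default protocol the
breakpoint of a high-theta cultivar can be structurally unidentifiable
from drought-phase midday data: daily transpiration of ~500–600 g from a
~2100 g plant-available store depletes ~0.12–0.15 SWC between the
nightly dose and the midday window, and the first deficit dose replaces
only 80% of a well-watered day's loss.  The maximum *observable* midday
SWC in the drought phase is therefore ~0.51–0.53 for the two
highest-theta default profiles — below their configured theta_crit
(0.557, 0.579).  No estimator can recover a breakpoint above the range
of its abscissa; the fit lands at the censoring boundary.  The end-to-end
tests assert ±0.01 recovery for the two identifiable default profiles,
boundary behaviour for the censored two, and ±0.01 recovery for a
four-profile variant whose breakpoints lie inside the observable range.
Practical implication: choose the deficit fraction (or a drier
pre-drought target) so that expected midday SWC spans the breakpoint.

## 4. Response metrics

- **rTR**: drought plant's daily transpiration ÷ same-day mean of its
  cultivar's well-watered plants (invalid days excluded; zero-control
  days flagged, never divided).
- **Recovery rate**: OLS slope of rTR on day index over the
  re-irrigation period (day 1 = first re-irrigated day), ≥ 3 points.
- **Phase dTR**: cumulative transpiration over a phase's valid days ÷
  number of valid days.
- **WUE**: harvested mass per kilogram of transpired water (g/kg).
  Gram-per-gram ratios for cereal yield are O(10⁻³); the per-kilogram
  scale is the one practitioners quote, and the unit is labelled
  explicitly to avoid the ambiguity of "g/g".
- **Harvest index**: grain ÷ total above-ground biomass.
- **Classification**: cultivars are split at the median well-watered
  transpiration level and the median decline slope.  High level + steep
  decline → *non_conserving* (spends water, shuts down hard); low + 
  shallow → *conserving*; high + shallow → *dynamic* (behaves like a
  conserver only once drought sets in); otherwise *intermediate*.  The
  definition is relative; with a single cultivar it collapses and the
  code warns and returns *intermediate*.

## 5. Reproducibility

All randomness flows from one `numpy` generator seeded by the config;
the pipeline manifest records the config hash, seed and package version,
and reruns with identical config + seed produce bit-identical CSV
artifacts (asserted in tests).  Acceptance-level checks live in
`tests/test_acceptance.py` (one test per criterion) and
`scripts/acceptance.py` (headline desk-scale values as JSON).
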