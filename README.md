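# defolyr

Reconstruction of past insect defoliation events from seasonal tree-ring
series, for dendroecologists and forest-entomology researchers working with
late-summer/autumn defoliators such as the pine looper *Bupalus piniaria*.

## The problem and the method

A late-season defoliator strips needles after the current annual ring is
essentially complete, so the damage is invisible in that year's ring but
leaves a two-season signature: the **latewood** of the next ring (built from
current photosynthate) collapses in year *t*+1, and the **earlywood** of the
ring after (built from stored reserves) collapses in year *t*+2. The
package's core detector — the **pointer-year method (PYM)** — dates a
defoliation to year *t* when both declines occur synchronously across a
stand. Growth change is measured by the relative growth change

```
RGC_t = 100 · R_t / R_{t−1}   (% of the previous ring; earlywood, latewood or total width)
```

and year *t* is flagged when RGC in latewood at *t*+1 shows at least a
`change.l` % drop in at least `sync.l` % of trees **and** RGC in earlywood at
*t*+2 shows at least a `change.e` % drop in at least `sync.e` % of trees.
Because the signature is tied to the two seasons that follow feeding, PYM
dates events with zero lag — unlike whole-ring methods, which see the delayed
ring-width trough.

Three reference detectors are implemented for comparison:

* **OUTBREAK** — per-tree spline-detrended indices at least `std` standard
  deviations below their mean for `lng` consecutive years, entered abruptly
  (index ratio ≤ `abrupt`), in ≥ 10% of trees;
* **MWM** (moving window) — a strict local minimum of absolute ring width in
  a ±`width`-year window shared by ≥ `perc` of trees;
* **MICA** — FastICA components of the z-scored ring matrix staying below
  `lim` for `lng` years, confirmed by a site-chronology low (below the
  `q`-quantile, within `rng` years).

Around the detectors the package provides Tucson/RWL and seasonal-CSV I/O,
Baillie–Pilcher/spline/double detrending, EPS/SNR chronology confidence and
reliable-span screening, grid-search calibration of detector parameters
against documented outbreak windows, lag-tolerant 2×2 concordance statistics
(accuracy/sensitivity/specificity, Fisher's exact test, Benjamini–Yekutieli
correction), climate-response screening with dummy-variable linear models
(I_t = Σ a_i·W_it + b·O_t + C) compared by linked-bootstrap R²adj and
Friedman's test, superposed epoch analysis, and a synthetic-data generator
with ground truth.

## Worked example

```python
from defolyr import SynthConfig, simulate_site, pym_detect, outbreak_detect
from defolyr.concordance import match_events, fisher_exact

cfg = SynthConfig(site_id="demo", event_years=(1959, 1996), seed=42)
stand, climate, truth = simulate_site(cfg)

pym = pym_detect(stand)
outbreak = outbreak_detect(stand)
print("true defoliation years:", truth["event_years"])
print("pointer-year events:   ", pym.event_years)
print("OUTBREAK events:       ", outbreak.event_years)

table = match_events(pym.event_years, outbreak.event_years, span=stand.span)
print(f"concordance A={table.A} B={table.B} C={table.C} D={table.D}")
print(f"sens={table.sens:.3f} spec={table.spec:.3f} "
      f"Fisher p={fisher_exact(table):.2e}")
```

prints

```
true defoliation years: [1959, 1996]
pointer-year events:    [1959, 1996]
OUTBREAK events:        [1960, 1997]
concordance A=2 B=0 C=0 D=98
sens=1.000 spec=1.000 Fisher p=2.02e-04
```

The pointer-year method recovers both injected defoliation years exactly,
while OUTBREAK fires one year later (the ring-width trough lags the feeding
season); the lag-tolerant matcher still pairs every event (A = 2, no
false negatives or positives) and Fisher's exact test confirms the
association over the 100-year span.

Detectors are scikit-learn-style estimators, so the same run reads

```python
from defolyr import PointerYearDetector
det = PointerYearDetector(change_l=10, sync_l=55, change_e=10, sync_e=55)
det.fit(stand).event_years_     # [1959, 1996]
```

A command line mirrors the library (`defolyr simulate | detect | optimize |
compare | climate`); see `defolyr --help`.

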