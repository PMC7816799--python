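# whalecost

Daily energetic costs of acoustic disturbance for lunge-feeding blue whales
(*Balaenoptera musculus*).

Military mid-frequency active sonar and similar localized noise sources can
interrupt foraging. For a filter-feeding whale, each hour of lost feeding is a
quantifiable energetic cost: a missed lunge is a missed mouthful of krill.
`whalecost` turns multi-day biologging records (hourly positions, lunge counts
and lunge depths) into a daily Monte-Carlo simulation that predicts, for a
hypothetical noise source of given intensity, duration and position, how much
feeding time, how many lunges and how much energy an individual loses in a
day — and whether its daily net energy intake drops or even turns negative.

## Model

The pipeline has four stages.

**Activity model.** Each tag-hour is classified as not feeding (NF, no
lunges), shallow feeding (SF) or deep feeding (DF); the SF/DF split is the
maximum-posterior component of the hour's mean lunge depth under a
two-component Gaussian mixture. Hourly states are modelled as a first-order
Markov chain whose stationary distribution π (πP = π) is the daily activity
budget. Gaps between foraging bouts (maximal NF runs between feeding hours)
are kept as an empirical distribution of patch-finding times, and each
complete feeding day's ranging area is the convex hull (Minimum Convex
Polygon) of its hourly fixes.

**Exposure geometry.** Sound spreads spherically, RL = SL − 20·log₁₀(r), so
iso-level contours are circles around the source. A whale's day is idealized
as a circle of that day's ranging area placed uniformly at random in a
100 km × 100 km region containing the source; the exact two-circle lens
overlap between the daily circle and each received-level annulus gives the
fraction of the day spent in each exposure bin.

**Exposure-response (ER).** Response probability comes either from discrete
step functions anchored at (1, 10, 50, 90, 99)% — context-specific, with deep
feeding near the source (≤ 1 km) the most sensitive context, the ambient
noise floor at 1% and TTS onset at 99% — or from continuous curves over
received-level or distance bins, each bin summarised by a posterior mean and
SD from which a probability is drawn (truncated normal on [0, 1]). Whole bins
conservatively respond at their upper-extreme dose.

**Bioenergetics.** Per lunge, assimilated energy is V(L)·ρ·e_k·ε with
engulfment volume V allometric in body length L and krill density ρ drawn
from a lognormal distribution (geometric mean/SD parameterization).
Expenditure is linear in hours per state; net intake floors the foraging gain
at zero before subtracting maintenance (and optional gestation/lactation
costs).

A simulated day interleaves all four: 6-minute (discrete ER) or 30-minute
(continuous ER) intervals receive an exposure bin and a behavioral state at
random; while the source is active each exposed interval can respond, and a
response costs the interval plus a randomly drawn foraging-bout gap, during
which no further response occurs. Lost feeding hours convert to lost lunges
via the day's state-specific lunge rates, and to lost energy via shared
per-lunge krill draws, so the proportional energy loss is bounded in [0, 1]
and a day with no response reproduces the undisturbed budget exactly.

All the numbers the simulation needs from field data (activity budgets, lunge
rates, gap and area distributions, krill densities, ER anchors, bioenergetic
constants) are either fitted from the input CSV or shipped as editable YAML
fixtures; a synthetic-data generator with the statistical structure of real
deployments makes the whole pipeline runnable and testable out of the box.

## Worked example

```python
import numpy as np
import whalecost as wc
from whalecost.simulate import run_scenarios, summarize

records = wc.generate_deployments(wc.GeneratorParams(), seed=42)
model = wc.ActivityModel.fit(records, seed=0)
print("budget (NF, SF, DF):", np.round(model.pi, 3))
print("mixture means (m):", np.round(model.mixture.means, 1))
print("days:", len(model.days), " mean daily area (km2):", round(model.areas_km2.mean(), 1))

results = run_scenarios(
    model,
    {"sl_db": [210.0], "duration_min": [60.0, 720.0], "position": ["center"],
     "length_m": [22.0], "krill": ["lower"], "er": ["discrete:moderate-median"]},
    reps=500, seed=1,
)
print(summarize(results)[["duration_min", "proportional_loss_mean",
                          "lost_lunges_mean", "frac_no_change", "frac_sign_flip"]])
```

prints

```
budget (NF, SF, DF): [0.588 0.124 0.288]
mixture means (m): [ 35.2 164.2]
days: 162  mean daily area (km2): 300.4
 duration_min  proportional_loss_mean  lost_lunges_mean  frac_no_change  frac_sign_flip
         60.0                0.064959         16.928018           0.688           0.004
        720.0                0.423405         93.005908           0.078           0.034
```

Read: the fitted whales spend ~59% of hours not feeding, ~29% deep feeding;
an hour of feeding is shallow below ~70 m and deep around 160 m. A 210 dB
source at the center of the region active for one hour costs a 22-m whale
6.5% of its daily energy acquisition on average (≈17 lunges), and 69% of
simulated days are entirely unaffected; the same source active for 12 hours
costs 42% of daily acquisition on average, only 8% of days escape unaffected,
and in 3.4% of days the net daily energy intake flips from positive to
negative.

The same pipeline is available from the shell:

```bash
whalecost synth --out run/ --seed 0          # synthetic tag + krill data + fixtures
whalecost fit run/hourly_records.csv --out fit/ --seed 0
whalecost simulate config.yaml --out sim/    # factorial sweep -> results.csv, summary.csv
whalecost summarize sim/results.csv --out summary.csv
```

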