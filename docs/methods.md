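# Methods

## Exposure model

Hourly PM₂.₅ at a monitor is reduced to a daily mean only when at least 18
hourly readings strictly greater than zero are available; zero readings are
treated as invalid instrument hours, not clean air. Heating degree days are
HDD = max(0, 18 °C − (Tmin + Tmax)/2), computed at each meteorological
station and then interpolated like any other daily field (HDD is *not*
recomputed from interpolated temperatures; degree days are nonlinear in
temperature, so the order matters).

Interpolation is inverse distance weighting over stations within a fixed
radius (default 100 km) of each statistical-area centroid, with weights
d^(−p). The exponent p defaults to 2 — the conventional choice; nothing in
the method pins it down — and is configurable. Stations with a missing
daily mean are excluded day by day and the remaining weights renormalised,
so the output is always a convex combination of observed values. A station
within ~1 m of the centroid short-circuits to its own value; in the
vectorised path distances are floored at that epsilon, which bounds the
weight and preserves convexity. All coordinates are planar kilometres:
at sub-state scale the error from ignoring geodesy is far below monitor
noise, and it keeps the synthetic geometry trivial.

## Source attribution

The counterfactual (non-biomass background) for each area is the mean of
its summer (Nov–Feb) daily PM₂.₅ after removing likely fire days: summer
days strictly above the area's 95th percentile of **all** non-missing
historical daily values. Percentiles use linear interpolation between order
statistics (conventions differ; this one is stated because it is asserted
against a brute-force oracle in the tests). The percentile pool and the
threshold percentile are configurable (`historical="summer"`, any
percentile in (50, 100)); the counterfactual is computed once per area over
the full study period.

A day at or below the counterfactual is unpolluted with ΔC = 0; otherwise
ΔC = PM₂.₅ − counterfactual and the day carries exactly one source label.
Winter (May–Aug) polluted days are WHS, summer polluted days LFS. Polluted
days in the transition months are classified by a random forest (500 trees,
fixed seed) trained on the rule-labelled polluted days with features: area
id, year, month, day of month, daily PM₂.₅, daily HDD, day of week, Tmin,
Tmax. Area id, month and day of week are one-hot encoded — month is
categorical because its numeric ordering is meaningless across the year
boundary (December borders January) and a numeric encoding places the
transition months spuriously adjacent to the summer training months.
Held-out accuracy on a stratified 20 % split of the labelled days is
reported alongside the model. An exact 0.5 posterior (possible with an even
forest) breaks toward WHS when the day has any heating demand (HDD > 0),
else LFS.

Two consequences of this design are worth knowing. First, the
polluted/unpolluted boundary sits at the noise scale: a day a few
hundredths of a µg/m³ above the counterfactual counts as polluted with a
negligible ΔC, so *day counts* of polluted days run high while the
attributable mass is essentially unaffected. Second, the percentile rule is
partly circular: the more fire days an area truly has, the higher its own
threshold, and once true fire days approach the ~5 % allowance the rule
starts missing moderate events, which then bias the counterfactual upward.
The rule behaves well only while fire events are sporadic and distinctly
elevated — which is its premise.

## Health impact assessment

Attributable cases: Cases = IR × Pop × (e^{β·ΔC} − 1), computed with
`expm1`. For β·ΔC < 0.01 this agrees with the linearised IR·Pop·β·ΔC to
within 1 % (verified); the exponential form is kept because severe fire
days violate the linearisation.

Exposure windows follow the nature of each source. WHS all-cause mortality
(ages 30+) uses the annual mean of WHS-attributable PM₂.₅ — averaged over
*all* days of the year, zeros included, the standard annual-mean
construction — with the annual incidence rate. Everything else (LFS
mortality all ages, CVD/RSP admissions for both sources, asthma ED visits
by source and age band) uses the day's ΔC with a daily incidence rate equal
to the annual rate divided by days in that calendar year; no seasonal
adjustment of baselines is attempted, which, given that most exposure is in
winter when true baselines are likely higher, biases the burden downward.
Partial calendar years are computed pro-rata over the observed days, with a
warning.

The packaged coefficient table carries β and SE per µg/m³ for nine
outcome × age × source rows; CVD and RSP admissions share one coefficient
across both sources; WHS asthma coefficients exist only for ages 0–17 and
18–64, LFS adds 64+. 95 % CIs substitute β ± 1.96·SE (lower bound floored
at zero) into the case equation — coefficient uncertainty only, no Monte
Carlo. Aggregation over strata sums CI bounds bound-wise, which treats
coefficient uncertainty as perfectly correlated across strata; this is
conservative (wide) and is how the summary tables relate to their
components.

## Cost valuation

Deaths are valued at the VSL (default AUD$ 4.2 M, 2014 prices), admissions
by cost-of-illness, ED visits at a per-case average (AUD$ 705, 2016
prices). The default admission valuation is *bundled*: the per-case
averages (AUD$ 7193 CVD, AUD$ 7280 RSP, 2016 prices) are taken to already
combine direct health-care cost and lost productivity. A *component* mode
(unit cost + mean length of stay × daily salary) is provided for when the
elements are supplied separately. All amounts are inflated to the target
price year (default 2018) by caller-supplied factors; the defaults are 1.0
so that worked examples are exact, and real factors are configuration, not
code.

Indicators: cost per source-day (a calendar day counts once per source when
any area carries that label; an area-day denominator is selectable), cost
per year (total / study years; the averaging period defaults to the
classified date span and can be fixed explicitly), and WHS cost per
woodstove-year using a single state-wide stove count (default 69,317).

## Sensitivity analysis

A discrete scenario grid: fire-day percentile ∈ {75, 90, 95, 99}, winter
∈ {May–Aug, May–Jul, Jun–Jul} (summer fixed at Nov–Feb; transition months
are whatever remains), and transition-month predictions included or
excluded. Excluding predictions drops all transition-month area-days from
the burden and cost computation. The classifier is retrained per scenario
(season definitions change its training labels) with the same seed. The
exposure surface is computed once and shared. Output: per-scenario
indicators plus min/max ranges per source.

## Synthetic data generator

The generator emulates the features the attribution method keys on, with
known ground truth:

* **Background**: constant 1.4 µg/m³ everywhere (the typical unpolluted
  daily mean in such networks).
* **WHS**: active every winter day and, on transition-month days,
  stochastically with probability rising in HDD (logistic around 8 °C-days
  — heaters come on when it is cold); daily mean amplitude 6 µg/m³ at 10
  HDD, scaled linearly in HDD with lognormal (σ = 0.35) day-to-day
  variation; spread over the day by a bimodal profile with a large
  overnight peak and a smaller early-morning peak. Winter area-day means
  land near 8 µg/m³.
* **LFS**: Poisson events per area (1.5 per summer season; half that rate
  over the warm, low-HDD transition days), duration 1–16 days skewed short
  (geometric), event daily-mean magnitude lognormal with median 50 µg/m³
  and σ = 0.7, ±20 % within-event day-to-day variation. Events are
  *sporadic and distinctly elevated* — deliberately so: the percentile
  fire-day rule presumes exactly that, and with frequent or marginal events
  its threshold climbs into the event distribution and the counterfactual
  is no longer recoverable (see above). The heavy tail still produces
  occasional daily means in the hundreds of µg/m³.
* **Temperature**: southern-hemisphere sinusoid (annual mean 12 °C,
  amplitude 5 °C, warmest mid-January) plus domain-shared weather noise and
  a small per-area perturbation, so HDD emerges from the temperature series
  and the degree-day code path is exercised end-to-end. Daily range 8 °C.
* **Noise**: zero-mean Gaussian per hour (σ = 0.3 µg/m³) with the final
  concentration floored at 0.05 µg/m³ so every hour remains a valid (> 0)
  reading. Zero-mean noise keeps the summer mean an (almost) unbiased
  estimate of the background; 1 % of hourly records are dropped to exercise
  the 18-hour validity rule.
* **Geometry and people**: areas on a jittered 40 km grid in four regions;
  each PM monitor within 3 km of its area centroid (emulating a dense
  network where most of the population lives within a few km of a
  monitor); populations lognormal with median ≈ 9.5 k clipped to
  [3,000, 25,000], with age-band shares around 22 % (0–17), 18 % (64+) and
  58 % (30+); woodstoves ≈ population / 7.5. Baseline incidence rates are
  fixed synthetic values of realistic magnitude (e.g. 0.012 deaths per
  person-year among 30+).

Ground truth records, per area-day, the injected smoke total (the true
attributable PM₂.₅, exactly zero on unpolluted days) and the dominant
source. Station values are the assigned area's signal plus background and
noise, so interpolation back to the centroid recovers the area series up to
noise and a small leakage from neighbouring areas.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: physical inversion meteorology (the
diurnal profile is imposed, not emergent), spatially extended fire plumes
(events are per-area, not advected), non-biomass sources (traffic,
industry), instrument drift and station relocations, seasonal baseline
incidence, and real geography or station placement. Recovery results show
the *pipeline* is correct and well-conditioned under its own assumptions,
not that those assumptions hold in any particular airshed.

## Numerical choices and degenerate inputs

* Percentile: linear interpolation between order statistics.
* Pollution cut-off: a day is polluted when PM₂.₅ exceeds the
  counterfactual by more than 1 × 10⁻⁹ µg/m³; the tolerance absorbs float
  drift from interpolation in degenerate (noise-free) inputs and is far
  below any physical concentration.
* IDW coincidence epsilon: 10⁻³ km.
* Fire-day identification requires ≥ 20 non-missing daily values per area;
  the counterfactual requires ≥ 1 valid summer non-fire day; both fail
  loudly naming the area.
* Classifier ties at exactly 0.5 break toward WHS if HDD > 0, else LFS.
* Cases with ΔC = 0 are exactly zero (`expm1`); all case and cost
  arithmetic is plain float — every default monetary value is exactly
  representable, so the worked examples are exact.

## Problem sizes

The test suite validates on a 6-area × 2-year world and parameter recovery
on a 12-area × 3-year world (the acceptance script uses the same); these
sizes give every season and transition month multiple realisations while
keeping the whole suite fast. Forest size is 500 trees in production
defaults, 100–300 in tests and recovery runs — accuracy is insensitive to
this beyond ~100 trees on these data.

## Known limitations

* A day is wholly one source; mixed days and chemical apportionment are out
  of scope.
* Bound-wise CI aggregation overstates interval width when strata are
  independent.
* The counterfactual is a single constant per area; trends or summer-mean
  drift over the study period fold into the attributable mass.
* Transition-month labels are model predictions; their error rate (~5–10 %
  on synthetic data) is invisible in the output tables unless the
  exclude-predicted scenario is consulted.
* Daily baseline rates are annual averages ÷ days-in-year; winter-peaking
  baselines would raise the WHS burden.
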