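# Methods

`shoalnet` reconstructs a proximity-based temporal social network from
high-resolution positional telemetry of a lake fish population, quantifies
how much of the observed co-location is social attraction rather than
shared habitat use, and measures how long social communities persist
("social memory").  Because raw whole-lake telemetry of this kind is not
generally available, the package ships a generative trajectory simulator
with known social structure, so every stage of the inference chain can be
validated against ground truth.

## Contact inference

Raw fixes arrive at burst rate (default one 3-D position per 5 s per fish)
with irregular dropout.  The pipeline:

1. **Resampling.** A 30 s moving median in 15 s increments puts every fish
   on a common, gap-free 15 s grid.  The window is centred on the bin
   start and half-open, `[t-15 s, t+15 s)`; the centring minimises phase
   bias, and the median suppresses single-fix outliers while recovering
   bins whose own burst was lost.  Bins with no fix in the window are
   flagged missing, never dropped.
2. **Pair distances.** Euclidean distance per bin for all N(N-1)/2 pairs,
   3-D (x, y, depth) by default since the positions are 3-D; a 2-D flag
   exists because a planar proximity threshold is also defensible.
3. **Imputation.** Interior missing runs of up to 30 min (inclusive; the
   boundary is tested) are linearly interpolated on the *distance* series
   — not the coordinates — and flagged `imputed`.  Longer runs and
   leading/trailing runs stay missing.
4. **Thresholding.** A bin is link-active iff distance < 10 m (strict)
   and not missing.
5. **Events.** Maximal active runs become candidate events; candidates
   separated by ≤ 5 min are merged (the gap stays inside the event span);
   events supported by a single active bin are removed; events spanning
   < 30 s (fewer than two consecutive bins) are removed.  The order —
   merge, then drop singletons, then minimum duration — is the only one
   under which a lone active bin adjacent to a real event is absorbed
   rather than deleted.  Event duration is the span (end − start)
   including merged gaps by default; an `active` mode counts only active
   bins.  An event takes the diel period and solar day of its start bin;
   events spanning a boundary are not split.

A contact event's two conventions worth noting: the merge bound is
inclusive (a break of exactly 5 min still merges), and gaps between the
surviving events of a pair are therefore always > 5 min.

## Diel and daily structure

A bin is *day* iff solar elevation exceeds 0° at the bin midpoint
(no twilight band, no refraction), computed from the standard NOAA
solar-position equations at the configured latitude/longitude; an override
table of sunrise/sunset times bypasses the model verbatim.  Daily
summaries use the *solar* day (sunrise to sunrise) so a night is a single
unit across midnight.

Per fish, solar day and period: mean temperature T (°C), mean distance
from shore d (m, minimum distance to the shoreline polygon), spatial
Shannon entropy S = −Σ c_m ln c_m over 10 m × 10 m cells (natural log;
cells anchored at the lake bounding-box corner — S depends weakly on the
origin, hence the fixed convention), mean speed v (m/s, per-bin 3-D
displacement over 15 s between consecutive valid bins) and mean depth h
(m).  Per pair: mean event duration τ⁺, mean time between consecutive
events τ⁻, and interaction probability p — among bins where the pair is
*detected* (distance not missing), the fraction lying inside an event.
Population averages are means over fish/pairs with defined values;
undefined values are excluded, never zero-filled.

## Aggregated networks and clustering

A network aggregates the events of one time window (half-open on the
event start) and optionally one diel period; edge weight is the event
count, with total contact seconds carried alongside.  Average local
clustering is computed on the binarized graph, nodes of degree < 2
contributing zero (the Watts–Strogatz convention ambiguity is resolved as
include-as-zero; a flag exposes the alternative).

## Day-shift null model

Each fish's regular trajectory is rotated circularly by an independent
whole-day shift, uniform on {0,…,6} days, inside the analysis window
(which always spans whole days, so time-of-day is preserved; wraps stay
within the month so the seasonal regime is intact).  Values, temperature
and validity flags move together, so every individual's diel rhythm,
habitat preference and detection pattern are untouched while
inter-individual timing is destroyed.  An expected 1/7 of pairs draw
identical shifts and keep their mutual timing, making effect sizes
slightly conservative.  Effect size = statistic(real)/statistic(shuffled)
per window × period for interaction count and clustering; a zero shuffled
value flags the ratio undefined rather than infinite.  One shuffled
replicate is the default; multiple replicates with empirical p-values are
supported (cheap on synthetic data) and marked as an extension in the
output metadata.

A property of *count-based* effect sizes found while validating the
simulator: they are non-monotone in the strength of attraction.  When
cohesion is so strong that group pairs never separate beyond 10 m, gap
merging collapses a pair's whole co-residence into one long event, and
the real event count falls *below* the shuffled count even though social
attraction is maximal.  Count effect sizes measure *episodic, synchronised*
association; total contact time would keep rising.  The validation
experiments therefore operate in the episodic regime (below).

## Timescale analysis (social memory)

For a 28-day month (672 h — the four-week window is exactly 28 days so
that 24 h × 28 = 672 windows of 1 h exist), the event set is aggregated
at every level of a window ladder of divisors of 672 h (default 672, 336,
168, 84, 48, 24, 12, 6, 3, 1; strict halving cannot reach 1 h through
integers).  Per slice, the *excess network* keeps max(0, real − null)
interactions per pair (one-sided: negative excess is no social signal),
and communities are found with the two-level map equation (Infomap, via
python-igraph, RNG seeded per call).  The number of communities with ≥ 3
members is averaged across slices holding at least one excess edge
(empty slices are recorded but excluded; their SEM would be undefined),
together with the mean percentage of realized links.

The social-memory timescale is "the longest aggregation that does not
disintegrate communities".  The default estimator is the argmax of the
mean community count over durations, exact ties breaking toward the
longest.  On realistic curves, however, the count forms a plateau whose
members differ only by slice noise (±0.01–0.1) before dropping at the
mixing knee, and an exact argmax is then decided by noise among the
shortest windows.  `memory_timescale` therefore accepts a plateau
tolerance `rel_tol`: every duration whose mean count stays within
`rel_tol` of the peak counts as intact, and the longest such duration is
returned.  The recovery experiments use `rel_tol = 0.15`, inside the wide
window between plateau noise (≲10% of the peak) and the drop one ladder
step past the knee (≳40%).

## The simulator

Movement is a discrete-time correlated random walk inside the lake
polygon (default: a 25 ha ellipse, 320 m × 250 m, at 52.995° N 13.582° E):
per step, heading diffuses (σ = 0.15 rad·s^-1/2), the fish advances at the
regime- and period-specific cruise speed, and three pulls are added —

* **social attraction**: a fraction `attraction_strength · dt` of the
  vector to the fish's current group centroid (so 1/attraction_strength
  is the cohesion e-folding time);
* **group site fidelity**: a weak pull (default 0.002 s⁻¹) toward the
  group's own littoral anchor, evenly spaced around an inner ring.
  Persistent groups in the study system hold distinct reed sites; without
  spatial separation of groups, freely drifting group centroids meet and
  camp together, cross-group excess links swamp the community signal, and
  no social-memory structure is recoverable by *any* detector.  The
  anchors are part of the social process: with `attraction_strength = 0`
  they are inactive and pairwise positions are independent given the
  habitat field;
* **diel habitat bias**: a radial pull, toward the lake centre by day and
  toward shore by night under the *winter* regime (daytime offshore
  shoaling is a cold-season phenomenon); under the summer regime fish
  hold the littoral zone day and night; the transition regime halves the
  winter daytime pull.

Total displacement is capped at twice the cruise step so the kinematic
bound (≤ 2·v_max·Δt per burst) holds; a step that would leave the polygon
is cancelled and the heading reversed.  Depth relaxes (AR(1), rate
0.005 s⁻¹) toward 5 m during winter days and 1 m otherwise, clipped to
[0.05, 7] m.  Cruise speeds default to 1.0/0.5/0.7 m s⁻¹ by day and
0.35/0.3/0.3 m s⁻¹ by night for winter/summer/transition, bracketing
daily averages of 0.5–1.0 m s⁻¹.  Group membership switches by a
memoryless process: residence times are exponential with mean
`group_switch_timescale`, the new group uniform among the others — the
generative social-memory timescale is therefore exactly the configured
mean residence.

Water temperature is a deterministic stratification field: 4 °C at depth
year-round, surface warming to ~24 °C in mid-summer with an exponential
4 m decay; in winter the column is isothermal to < 0.5 °C.

Detection is Bernoulli per burst at a base yield of 0.4 (the study-scale
average), reduced by 0.15 during summer days, and attenuated near shore
in summer by a logistic factor (half-saturation 15 m from shore, 5 m
width, floor 0.5) mimicking signal loss in reed belts.  Positions are
emitted exactly (no jitter), so containment and kinematic invariants are
bit-exact.

### What the simulator does not emulate

Multilateration error and fix jitter, anoxia-driven habitat exclusion,
individual heterogeneity (personalities, sizes), tag loss and mortality,
true fission–fusion subgroup dynamics, and resource fields that fluctuate
on the scale of days (the null model's core assumption is therefore true
by construction).  Passing tests show the *inference chain* is correct
and statistically calibrated on data of realistic size, sampling and
dropout — not that real carp behave like the generator.

## Validation experiments and problem sizes

* **Null-model validity** (`experiments.null_validity_suite`): 12 fish,
  14 summer days at 15 s cadence, 20 seeds per condition.  With
  `attraction_strength = 0` the interaction-count effect size is
  statistically indistinguishable from 1 (20-seed t-interval); at the
  episodic-shoaling strength 0.03 s⁻¹ it exceeds 1 in essentially every
  seed (observed means ≈ 1.01 vs ≈ 1.11).
* **Social-memory recovery** (`experiments.memory_recovery_suite`):
  28-day months, 18 fish in 3 groups (six members per group keep a
  community recognisable while one member is mid-switch; with 4-member
  groups a single switcher bridges two communities), cohesion 0.015 s⁻¹,
  10 seeds per generative timescale.  Median recovered timescales for
  generative 12/48/168 h are 6/24/84 h — one ladder step below and
  strictly monotone.  The one-step-low bias is a property of the
  estimator on memoryless switching: by W = τ/2 about 40% of fish have
  switched mid-window, which is where the count leaves the plateau.
* The 15 s simulation cadence for these experiments matches the analysis
  grid (the 30 s median filter is then near-identity); the 5 s default
  burst interval remains for emulating raw telemetry.

## Numerical conventions

Windows are half-open `[start, end)` everywhere; timestamps are ISO-8601
UTC; the analysis grid starts at the first fix's midnight and spans whole
days (required by day shifting).  All tabular outputs are CSV with JSON
schema sidecars; the run manifest hashes config, seeds, row counts and
file contents, and is bit-identical across runs with identical seeds.
Degenerate inputs: one fish → no pairs and empty downstream tables; two
fish → clustering undefined (flagged, not zero); empty slices and
undefined ratios are flagged missing rather than filled.
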