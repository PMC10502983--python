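# shoalnet

Proximity-based social network inference and rhythm analysis for
high-resolution fish telemetry.

Whole-lake acoustic telemetry can position every tagged fish in a
population every few seconds for months.  `shoalnet` turns such
positional data into a temporal social network and asks two questions
movement ecologists care about: **how much of the observed co-location is
social attraction** (rather than two fish independently using the same
habitat at the same time), and **how long do social communities persist**
(is there "social memory" that makes the same individuals re-associate)?

The pipeline implements:

* **Contact inference** — resample fixes with a 30 s median filter onto a
  15 s grid; compute all N(N−1)/2 pairwise 3-D distances; linearly impute
  gaps up to 30 min; threshold at 10 m; merge activity runs separated by
  ≤ 5 min; drop singleton and sub-30 s events.  A contact event is
  sustained proximity — the proxy for a social interaction.
* **Behavioural indicators** — per fish, solar day and diel period (day =
  solar elevation > 0°): temperature *T*, distance from shore *d*,
  spatial Shannon entropy *S* = −Σₘ cₘ ln cₘ over 10 m grid cells, speed
  *v*, depth *h*; per pair: mean interaction duration τ⁺, mean time
  between interactions τ⁻, interaction probability *p*.
* **Day-shift null model** — rotate each fish's trajectory by an
  independent whole-day shift (uniform 0–6 d), preserving individual
  habits and time-of-day while breaking inter-individual timing; effect
  size = real/shuffled for interaction counts and average local
  clustering (1 = no social signal; an expected 1/7 of pairs share a
  shift, so effects are slightly conservative).
* **Timescale analysis** — split each 28-day month from one 672 h window
  down to 672 windows of 1 h; weight links by the interactions *in
  excess* of the null model; detect communities with the map equation
  (Infomap); the longest aggregation that does not disintegrate
  communities of ≥ 3 members estimates the social-memory timescale.
* **A trajectory simulator** — group-structured correlated random walks
  in a lake polygon with tunable social attraction, memoryless group
  switching (the generative memory timescale), diel onshore/offshore
  cycling, seasonal regimes and a realistic detection model (~40% yield,
  reed attenuation) — so every stage is validated against ground truth.

See `docs/methods.md` for model details and conventions.

## Worked example

The numbered drivers under `analysis/` run a complete synthetic study —
12 carp, one 28-day summer month, three social groups with 48 h mean
residence — and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_infer_contacts.py
python analysis/03_indicators.py
python analysis/04_null_model.py
python analysis/05_timescales.py
```

Output (abridged):

```
simulated 12 fish for 28 d: 531969 fixes (27% detection yield), 176 group switches
38004 contact events over 66 pairs (26970 day / 11034 night); median duration 270 s
  day: v=0.15 m/s  h=1.01 m  d=39 m  S=4.92  p=0.074  tau+=316 s
night: v=0.13 m/s  h=1.01 m  d=55 m  S=4.23  p=0.213  tau+=963 s
 both: 38004 real vs 12723 shuffled interactions -> effect size 2.99
  day: 26970 real vs 6981 shuffled interactions -> effect size 3.86
night: 11034 real vs 5742 shuffled interactions -> effect size 1.92
memory timescale: argmax 3 h; plateau-tolerant 24 h
```

Reading this: detection dropout (27% yield) still yields a dense contact
record after imputation.  Fish are shore-oriented at night (*d* smaller
by day here because summer fish hold the littoral zone; entropy *S* shows
wider daytime ranging) and interaction probability *p* is higher at night
when groups sit on their sites.  There are ~3× more interactions in the
real data than under the day-shift null — co-location is dominated by
social attraction, not shared habitat.  The community-count curve stays
flat down to 24 h windows and collapses toward one community at
week-scale aggregation: the estimated social memory (24 h, plateau
estimator) sits one ladder step below the generative 48 h group
residence, the estimator's known bias under memoryless switching.

A `shoalnet` CLI wraps the same stages (`shoalnet simulate`,
`infer-contacts`, `indicators`, `nullmodel`, `timescales`, `all`) for use
on exported fix tables (CSV: `fish_id, timestamp, x_m, y_m, depth_m,
temp_c`) with a GeoJSON/WKT lake outline.

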