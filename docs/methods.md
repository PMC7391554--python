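# Methods

This note documents the models, conventions and numerical choices behind
`thermaffin`, in the order data flows through the package.

## Occurrence quality control

Occurrence tables are Darwin-Core-flavoured CSVs (species identifier,
decimal latitude/longitude, depth in metres, event date). Rules:

* **Coordinates.** Latitudes outside [−90, 90] cannot be reinterpreted and
  are rejected, each with a single reason code; longitudes are wrapped into
  [−180, 180) by modular arithmetic, the standard marine convention. Row
  conservation holds for every file: rows in = records out + rejects.
* **Depth.** Negative and missing depths are set to 0 m. Aggregated
  occurrence data use inconsistent sign conventions, and negative values
  can also mark intertidal or missing records, so the surface is the only
  defensible default; an absolute-value reinterpretation is deliberately
  *not* applied. The rule is idempotent.
* **Dates.** ISO full dates, year-month, and bare years parse to
  (month, year); a bare year leaves the month missing. Missing is a value,
  not an error — dateless records remain usable for climatology matching
  and are only excluded from month-year-resolved matching.

## Gridded products and matching

The depth axis is the 27-band World Ocean Atlas discretisation (10 m bands
to 50 m, 25 m to 200 m, 50 m to 300 m, 100 m to 1,500 m, 250 m to
2,000 m). Bands and grid cells are half-open `[lower, upper)` with the
single closure at the top edge (2,000 m depth; northern/eastern grid
boundary), so every point has exactly one home and the convention is
oracle-checkable. Depths beyond 2,000 m have no band: temperature at depth
is then unavailable even where SST/SBT are.

Matching is an exact lookup, never an interpolation: climatology by cell;
the monthly series by cell, month-year and band. Exclusion reasons form a
fixed cascade (`missing_date`, `year_out_of_range`, `outside_grid`,
`land_cell`, then `depth_below_cell_floor` for the at-depth measure only);
grid SBT is the deepest band with data in the cell — i.e. temperature at
2,000 m in deeper seas. There is no nearest-wet-cell fallback: a record on
a coarse cell that is mostly land is an exclusion, as it is against real
coastlines. A record excluded from one product stays eligible for the
other, so per-measure species summaries legitimately use different record
subsets.

"Best" temperature per record is decided by functional group: SST for
birds, mammals, pelagic and reef-associated fish; SBT for benthos,
macroalgae, demersal and benthopelagic fish. Nekton have no established
rule; they default to SST as water-column animals, with a configuration
override (`nekton_best`). Sparse fish habitat labels are merged
(bathydemersal → demersal; pelagic-neritic/oceanic → pelagic).

## Affinity statistics

Per species × measure: mean, min, max, median, sample SD (n−1), median
absolute deviation scaled by 1.4826 (normal consistency), and 5th/95th
quantiles by linear interpolation between order statistics ("type 7", the
default of the major statistical environments). The choices of quantile
rule, MAD scaling and SD denominator are conventions, declared here for
reproducibility; all are checked against independently written formula
oracles in the tests. With no matched records a summary carries counts
only; with one record the SD is absent.

## Thermal-limit aggregation

Where a species reports both LT0 and LT100, LT100 (all individuals dead)
is the upper limit and LT0 rows are dropped. Multiple estimates are
combined by a mean weighted by 1/SD — note, deliberately *not* the
inverse-variance 1/SD² convention, because the source protocol states
inverse-SD weights. If any estimate of a species lacks an SD the species
falls back to the unweighted mean, so no estimate silently receives
infinite or arbitrary weight; an SD of exactly 0 is treated as missing
with a warning. Targeted data corrections (e.g. a limit shown by its
original reference to be a transcription error) are applied from an
explicit edits list — logged, last-wins — never hard-coded.

## Polynomial models, F tests, vertex

`ThermalLimitModel` fits `Tmax = a + b·x + c·x²` by OLS in three nested
forms: pooled; additive (per-group intercepts, shared curvature);
interaction (a separate quadratic per group, one shared error variance —
equivalent to independent per-group fits in the point estimates, which the
tests verify). Internally the predictor is centred (u = x − x̄) for
conditioning; the coefficient map back to the raw basis is linear, so
estimates, covariances and t-based 95% Wald intervals transform exactly.
The raw basis is what makes the vertex −b/(2c) meaningful; it is reported
only when the curvature is concave beyond numerical noise, and flagged
"extrapolated" outside the observed affinity range. Nested forms are
compared by the extra-sum-of-squares F statistic
`((RSS_n − RSS_f)/Δp) / (RSS_f/df_f)`; comparing a model with itself
degenerates to F = 0. A constant response defines R² = 0 (the 0/0 limit).
Interaction fits require ≥3 species per group, enforced with an error
naming the offending group.

## Safety margins

Margin = Tmax − mean affinity (the at-depth measure by default), binned
cold (≤10 °C), moderate (>10 and ≤20 °C), warm (>20 °C) — the boundary
values 10.0 and 20.0 belong to the colder bin, and these closures are used
everywhere. The margins table stores an *exactly consistent* triple: IEEE
rounding means `(tmax − aff) + aff` does not always reproduce `tmax`
bit-for-bit (and when both operand binades are coarser than a small tmax,
no representable margin can), so the margin is nudged by ulps toward an
exact decomposition and, failing that, the stored tmax is the correctly
rounded sum — within ~1e-15 °C of the source value, far below measurement
precision. Group × bin cells are reported only where occupied (absent, not
zero), and sparse groups (birds, mammals, nekton) are excluded from the
margin table by default, configurably.

## Synthetic worlds

The generator emulates the three real data sources so every stage can be
tested offline with known truth:

* **Climatology**: SST = `sst_equator + sst_gradient·|lat|` + cell-level
  Gaussian noise; SBT = SST − `depth_decay` per band down to the cell
  floor, hence SBT ≤ SST by construction. Defaults (28 °C equator,
  −0.45 °C/degree, noise SD 0.5 °C) give a −8…28 °C global ocean.
* **Monthly series**: the same base field + a cosine seasonal cycle
  (half-amplitude 3 °C, peaking in July) + one Normal(0, noise_sd) draw per
  year and cell, − `depth_decay`·band (0.8 °C per band). Noise is
  interannual rather than per-month, so a zero seasonal amplitude makes
  months within a year exactly identical while long-run monthly means
  still carry sampling error (SE = noise_sd/√years). Temperature is
  non-increasing with depth at every wet cell by construction, which is
  why the configuration requires `depth_decay ≥ 0`.
* **Land and bathymetry**: land is laid down as contiguous random
  rectangles (not salt-and-pepper) so coarse-cell "mostly land" match
  failures occur; wet cells are half open-ocean (full 2,000 m column) and
  half uniformly shallower shelves, so depth-below-floor exclusions occur.
* **Occurrences**: species place records among wet cells with probability
  proportional to a Gaussian kernel (width `niche_sd`, default 2 °C) in
  the group's best climatology temperature around the preferred
  temperature. The recorded *true affinity* is the kernel-weighted mean
  cell temperature — the expectation of a matched record's temperature —
  which is the quantity the pipeline's affinity estimate converges to.
  Defects are injected after placement so the spatial truth stays intact;
  default rates mirror large aggregated occurrence archives: 45% missing
  depth, 1% negative depth, 4% missing date, 1% out-of-coverage year.
* **Thermal limits**: `Tmax = a + b·x + c·x² + Normal(0, 1)` per estimate
  with defaults (a, b, c) = (15, 1.2, −0.02), i.e. an optimum at 30 °C;
  1–3 estimates per species with SDs drawn from [0.5, 2] °C and missing
  30% of the time.

Everything is deterministic per seed (seeded generator substreams), and
the truth tables are consumed only by tests — never by the pipeline.

What the generator does *not* emulate: real ocean physics and circulation,
spatial sampling bias toward coasts and well-studied regions, taxonomic
bias, duplicated records, and microhabitat effects (e.g. supra-littoral
species for which air temperature would be more appropriate than SST).
Passing tests therefore demonstrate the correctness of the matching,
summarisation and inference machinery under known truth — not that
affinity estimates from real, biased archives are unbiased.

## Validation study sizes

The replicated validation studies use a 50×50-cell world, 200 species ×
200 occurrences and 100 end-to-end replicates for coefficient recovery
(the deterministic gridded products are built once and shared across
replicates; placement, limit noise and fits re-randomise per replicate),
and 500 simulated datasets of 150 species in 3 groups for the F-test
type-I error. These sizes give binomial/Monte-Carlo noise comfortably
inside the tolerances being checked (e.g. SE ≈ 1 percentage point on a 5%
rejection rate at 500 simulations).

## Known limitations

* No horizontal or temporal interpolation, by design; results inherit the
  grid resolution of the products supplied.
* Metric heterogeneity in Tmax (CTmax vs LT50 etc.) is recorded but not
  modelled; different metrics are treated as exchangeable within species.
* GAM-style smooth fits, mixed models, phylogenetic correction and
  abundance weighting are out of scope.
* NetCDF is the single gridded input format (CF-style coordinates,
  `_FillValue` honoured), read and written through xarray's NetCDF3
  engine; uniform lat/lon spacing is assumed when reconstructing cell
  edges from coordinates.
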