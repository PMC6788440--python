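# Methods

This note documents the models behind elevdiv, the parameter defaults
and why they were chosen, the numerical conventions, and what the
synthetic generator does and does not emulate.

## Survey accounting

The unit of effort is the trap night (one trap operational for one
night).  Per-location trap-night totals are taken from the effort
table rather than recomputed from per-trap set dates, matching the
granularity at which surveys report effort.  Trap success is
100 × captures / trap nights, reported half-up-rounded to one decimal
(the rounding used in published survey tables; unrounded values are
kept alongside).  Camera rates are series per 100 camera nights, two
decimals.  The default filters drop arboreal and pitfall captures
together with their effort — those trap classes are deployed too
unevenly for abundance comparison — and drop recaptured individuals,
so counts are individuals rather than capture events.  Species
identified only to genus (e.g. "Suncus sp.") are legal entries with
endemism status `unknown`.

Accumulation curves spread a location's total effort evenly over the
days spanned by its capture log (all traps assumed set on day 1).
This reproduces the qualitative saturation behaviour; it cannot
represent staggered trap deployment, which would need per-trap set
dates the data model does not carry.

Site identity is (mountain, trapping location); sites are ordered by
mountain and then by nominal elevation, defined as the median capture
elevation of the location's records.  This makes every downstream
table, matrix and tree deterministic.

## Alpha diversity

For counts n_1..n_S with proportions p_i: S = #{n_i > 0},
H' = −Σ p_i ln p_i (natural log, so H_max = ln S; the base is a
parameter but ln is the tested default), D = 1 − Σ p_i² (the
complement form, a diversity rising with evenness; 1/Σp² is available
via `variant="inverse"`), J' = H'/ln S for S ≥ 2.  The survey's source
tooling does not state its Simpson variant or log base; these choices
are recorded here as the package's defaults.  0·ln 0 ≡ 0.  Evenness
for S ≤ 1 raises an explicit error rather than returning 0, because a
silent zero is indistinguishable from a maximally uneven community.

## Mid-domain-effect null model

The domain of a mountain spans its lowest to highest capture
elevation, tiled into half-open 50 m bands (the top elevation belongs
to the last band).  A species' observed range runs from the band of
its lowest capture to the band of its highest; occurrences are
interpolated as continuous in between.  Each null replicate keeps
every species' range size (in bands) and draws a new midpoint:

* **soft boundaries** (default): midpoint band uniform over the whole
  domain; the range extends (size−1)/2 bands each way — for even
  sizes the extra band goes uphill or downhill by a fair coin — and is
  truncated at the domain edges, so a species may realise fewer bands
  than its size near a boundary;
* **hard boundaries**: the midpoint is uniform over placements where
  the full range fits; a range larger than the domain is an error.

Per-band richness is tallied over repetitions (default 5,000) and
summarised by the mean and the 2.5%/97.5% percentiles (linear
interpolation between order statistics).  Observed per-site richness
is classified against the closed envelope interval — a value exactly
on a quantile counts as `within`.  The mapping from trapping-location
richness to band expectations is exposed explicitly
(`compare_observed`) rather than hidden, since a six-site profile maps
onto many 50 m bands.  An exact enumeration of placement probabilities
(`expected_band_occupancy`) provides the closed-form check used by the
tests: under truncation a whole-domain species covers an edge band
with probability ≈ 1/2, not 1, which is the expected behaviour of the
soft rule, and the hard-boundary profile is symmetric about the domain
centre.

## Beta diversity

Pairwise, with a shared species and b, c unique to either site:
β_sim = min(b,c)/(a+min(b,c)), β_sor = (b+c)/(2a+b+c),
β_sne = β_sor − β_sim.  Multi-site, with per-site richness S_i, pooled
richness S_T and b_ij the species of site i absent from j:
β_SIM = Σmin/(Σmin + (ΣS_i − S_T)),
β_SOR = (Σmin + Σmax)/(2(ΣS_i − S_T) + Σmin + Σmax), β_SNE the
difference, where Σmin = Σ_{i<j} min(b_ij, b_ji) and Σmax the
analogous maximum.  Additivity β_sor = β_sim + β_sne holds to 1e-12 in
both forms and is property-tested.  A pair of empty sites has no
defined dissimilarity and is reported as NaN — never 0, which would
silently corrupt clustering input.  Sites with zero species are
excluded from the multi-site partition with a warning.

Clustering uses neighbor-joining (scikit-bio's implementation) on the
pairwise β_sor matrix across all sites of both mountains; the
component fed to the tree is selectable.  Input labels are sorted so
tie-breaking is deterministic.  Negative branch lengths — possible on
non-additive input — are clamped to zero with a warning; the raw
estimates are kept on each node (`raw_length`).  Trees are written as
Newick with branch lengths.

## Endemism and the endemic-removal test

Endemism per site is the proportion of its species (or captures) that
are endemic, computed over classified species only: `unknown`-status
species are excluded from numerator and denominator and can never be
drawn into any resampling pool.  Bootstrap envelopes resample the
site's classified species list with replacement (same size; default
1,000 replicates) — or its capture records, when the resampling unit
is set to captures; the resampling unit is recorded with the result —
and report the 2.5%/97.5% percentiles.

The endemic-removal test computes the multi-site partition on the
non-endemic submatrix of one mountain and compares each component
against a null of `reps` (default 5,000) random species subsets of the
same size drawn without replacement from that mountain's classified
species pool; mountains are tested independently, never pooled, and
null subsets are drawn per mountain from that mountain's own species.
p-values are one-tailed empirical with add-one correction,
p = (#{null ≤ obs} + 1)/(reps + 1) for a decrease (≥ for an increase),
the tail chosen by the sign of the observed departure from the
full-matrix component.  Both fixed-tail probabilities are retained
(`p_lower`, `p_upper`); under a randomised-label null the fixed-tail
p-value is uniform, which the tests verify by Kolmogorov–Smirnov over
200 simulated datasets.  With zero endemic species every null subset
is the full pool and p = 1 by construction.

## Synthetic surveys

The generator emulates a two-mountain trap survey: six trapping
locations per mountain at the fixed nominal elevations of the
motivating design (500–3,200 m and 500–2,400 m), 23 species, 400
ground trap nights per location (40 traps × 10 days), plus a small
arboreal/pitfall side-survey and one genus-level shrew with unknown
endemism to exercise the filters.

Generative model, per species:

* **Range midpoint** from a linearly decreasing density over the
  pooled extent widened half a mean range below the surveyed floor
  (capped at a quarter of the span), with the tilt calibrated so
  expected richness falls by `richness_slope` (default −3.5 species
  per 1,000 m) — away from edges, richness(z) ≈ n·L·f(z) for mean
  range size L, so the target slope fixes f′.
* **Range size** normal, mean 1,400 m, sd 600 m, floor 150 m, with the
  mean shrinking by a factor 1.45→0.55 from domain bottom to top
  (`range_size_elev_gradient = 0.9`): widespread lowland generalists
  versus restricted high-elevation specialists.
* **Endemism** Bernoulli with logit p = −6.0 + 4.0 · midpoint(km):
  ~2% endemic at 500 m, 50% at 1,500 m, 88% at 2,000 m, ~98% above
  2,500 m.  The steepness matches surveys in which the montane
  community above the forest transition consists almost entirely of
  island endemics while lowland species are widespread; together with
  the range-size gradient it produces the strong turnover
  (multi-site β_SIM ≈ 0.5–0.6, β_SOR ≈ 0.65–0.75) that makes the
  endemic-removal decrease detectable.
* **Abundance** geometric dominance weights (ratio 0.85, ranks
  shuffled across species, normalised to mean 1) times a log-normal
  site effect (σ = 0.4); the available pool per species-site is
  Poisson(8 × weight × site effect), and each individual's first
  capture day is geometric with per-night detection 0.12 over the
  session — individuals not caught by the last day go undetected.
  ~6% of caught individuals are re-trapped later and flagged as
  recaptures.  Record elevations jitter uniformly ±120 m around the
  site (transects span elevation), clipped to the mountain extent.

Everything flows from one `numpy.random.Generator`, so configuration
plus seed reproduces the dataset exactly.  The returned truth object
carries ranges, flags, weights and per-site tallies; under the default
preset, filtered capture totals per mountain fall in the calibrated
band 120–700 (observed 163–628 over a 100-seed calibration run).

What the generator does **not** emulate: spatially explicit trap
placement and within-transect autocorrelation, trap saturation and
behavioural trap response (detection is independent per individual and
night), weather- or season-driven detectability, mountain-specific
species pools (ranges apply to both mountains), camera-trap data, and
taxonomic misidentification.  Passing tests therefore demonstrate that
the statistics recover structure from idealised detection-thinned
surveys of this design, not that they are robust to those field
complications.

## Problem sizes and numerical conventions

Resampling defaults are 5,000 repetitions for the MDE null and the
endemic-removal test and 1,000 for bootstrap envelopes.  The test
suite uses reduced sizes chosen for tight Monte-Carlo control at
modest cost: exact-enumeration MDE checks on ≤ 8-band domains at 4,000
replicates (3-standard-error tolerance), p-uniformity over 200
simulated datasets at 149 permutations, envelope coverage over 300
binomial sites at 400 replicates, and parameter recovery over 50 seeds
at 400 permutations.  Percentiles use linear interpolation; empirical
p-values use add-one correction; percentage rounding is half-up.
Every stochastic routine takes an explicit seed and is
seed-deterministic; the pipeline derives per-stage seeds from one
master seed and logs them in its manifest alongside SHA-256 hashes of
every output file.

## Known limitations

* The accumulation-curve effort model assumes constant daily effort.
* Multi-site β on mountains with an empty site silently (but with a
  warning) reduces the site set; comparisons across mountains should
  check `n_sites`.
* The MDE null treats observed range sizes as fixed and error-free;
  detection failure near range edges biases observed ranges short, and
  no correction is attempted.
* Reproduction of the published beta-diversity and species-count
  values requires the survey's deposited capture-level raw data, which
  is not redistributed with the package.
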