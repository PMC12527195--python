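# Methods

This note records the models, conventions, parameter defaults, and design
choices behind `bluffbeach`, in the spirit of a statistical software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Survey aggregation

A site-level metric is the unweighted arithmetic mean over that site's
within-site replicates (quadrats, log-line points, transects, traps), with
the two snorkel seasons pooled into one value. Missing data are explicit
(NaN) and excluded pairwise from means — never imputed as zero. Specific
conventions:

- **Fish densities** (per 100 m²): `count / (transect length × horizontal
  Secchi visibility) × 100`, averaged over transects. "Total fish" is its
  own recorded tally; juvenile salmon, forage fish, and other fish are
  carried as independent counts (schooling forage fish can exceed the total
  tally on other transects, so the columns are not additive).
- **Salmon feeding**: site value = 100 × Σ feeding / Σ observation events;
  undefined (missing) when no events occurred.
- **Overhanging vegetation**: the union length of overhang intervals (no
  double-counting of overlaps) over transect length.
- **Fallen trees** are recorded per log-survey pass and averaged, treating
  repeated passes as repeated censuses with observation noise.
- **Richness metrics** are per-replicate richness (taxa per trap/quadrat,
  native species per vegetation transect), averaged to the site.

## Geomorphology

Relative encroachment `E = MHHW − toe elevation` is signed: positive means
the bluff/armor toe sits below MHHW, truncating the upper beach, which is
why it is the one metric inverted by default in the scale bar. Slope
(toe→MSL) and width (toe→MLLW) use the **first seaward crossing** of the
datum, linearly interpolated within the bracketing profile segment; profiles
with bars may recross, and the first crossing matches the beach-face intent.
Slope is reported as a positive magnitude. Profiles and datums must share a
vertical frame; no datum transformation is performed. Bluff height and
exposure are validated pass-through inputs (derived from imagery upstream).

## Wave hindcast

Sites are assigned a 6 h design wind by facing sector: 20 km/h for S/SW
(169–214° true), 15 km/h for N/NE (349–34°, wrapping through north),
10 km/h otherwise. The deep-water simplified (SMB-type) relations of the
Shore Protection Manual (1984) are used with the wind-stress factor
`U_A = 0.71 U^1.23` (U in m/s — the scenario type carries km/h and converts
internally, so unit mistakes are structural, not conventional), g = 9.81
m/s². If the stated duration is below the minimum duration
`t = 68.8 (gF/U_A²)^(2/3) U_A/g` the duration-equivalent fetch replaces F
(regime `duration_limited`); growth is capped at the fully developed limits
`H_s = 0.2433 U_A²/g`, `T = 8.134 U_A/g`. Alongshore transport capacity is
reported only as the (H_s, T, shoreline angle) triple; no transport formula
is applied.

## Grain size

Distributions are percent-by-class over a descending sieve ladder;
statistics use the Gradistat logarithmic (phi-scale) method: the cumulative
percent-coarser curve is piecewise linear in φ and percentiles are read off
it. "Normalized sorting (unitless)" is interpreted as the Folk & Ward
**geometric** sorting `σ_G = 2^{σ_I} ≥ 1`, the Gradistat convention; whether
the original usage involved any further normalization is not recoverable, so
this interpretation is stated prominently rather than guessed around.
Open-ended extreme classes (one more percent entry than classes) are closed
one φ unit beyond the end bounds. Percent sand uses fixed Wentworth limits
0.0625–2 mm with φ-linear pro-rata credit for straddling classes. A
degenerate zero-spread distribution yields σ_I = 0 with a warning.

## The scale bar

Steps: treatment means per metric (unweighted across a treatment's sites),
min–max scaling of the four means to [0, 1] per metric, orientation
inversion (`s → 1 − s`) for lower-is-better metrics, then the mean of the 30
scaled values per treatment. The default orientation set marks every metric
higher-is-better except relative encroachment; the full inversion set is
configurable per metric (YAML) because reasonable arguments exist for
inverting others (e.g., beach slope), and the headline Protect/Restore
ratio is insensitive to the slope choice (asserted in the test suite). The
standard error is across the 30 scaled metric values (n = 30), matching one
error bar per treatment; an alternative SE across regions is noted but not
default. A metric whose four means tie is scored 0.5 for every treatment,
keeping the denominator at 30 rather than silently dropping the metric.

## Statistics

All permutation machinery is implemented directly (library routines appear
only as independent cross-checks in tests):

- **Bray–Curtis**: `d = Σ|x−y| / Σ(x+y)`; a pair of all-zero samples gets
  d = 0 by convention (0/0 case).
- **PERMANOVA**: `SS_T = Σ_{i<k} d²/N`, `SS_W = Σ_g Σ_{i<k∈g} d²/n_g`,
  pseudo-F = `[(SS_T−SS_W)/(a−1)] / [SS_W/(N−a)]`. Random permutations use
  `p = (1 + #{F* ≥ F}) / (1 + n_perm)`; exact enumeration (n ≤ 9) includes
  the identity in the denominator. Geographic region is handled as
  **permutation strata** (labels shuffle only within regions) — the standard
  nonparametric counterpart of a region random effect. Default 9999
  permutations; the seed is mandatory in the CLI.
- **Assemblage workflow**: taxa below 3% relative abundance in every sample
  are removed first (idempotent filter), then ln(x+1) for fallout
  invertebrates and √x for MLLW covers; samples are individual
  traps/quadrats by default (site totals optional).
- **Chi-squared**: Pearson `Σ(O−E)²/E`, no continuity correction,
  df = (r−1)(c−1).
- **Univariate metric tests**: pairwise |difference of treatment means|
  with region-stratified permutations and Holm adjustment across the six
  pairs (raw p-values are reported alongside). With the 4×5×1 field design,
  a stratified pair has only 2⁵ = 32 relabelings and the two-sided p-grid
  bottoms out at 1/16 — a design limitation, not a software one; the tests
  characterizing type-I error and power therefore use two sites per
  treatment per region.

## Synthetic-data generator

The generator's defaults are the study conditions: 4 treatments × 5 regions
× 1 site; replicate counts follow the field protocol (10 wrack quadrats, 5
log points, 4 snorkel transects × 2 seasons, 7 fallout traps, 10 MLLW
quadrats, 1 vegetation transect); treatment means default to the packaged
survey-average table. Structure:

- **Region random effects**, drawn once per (region, metric) and shared by
  the region's four sites: lognormal multipliers (σ = `region_sd` = 0.15)
  for positive metrics, logit shifts for percentages, additive metres for
  encroachment. True among-region variances are unpublished; 0.15 is an
  order-of-magnitude choice exposed in config.
- **Replicate noise**: logit-normal for bounded percentages (median-, not
  mean-preserving, at nonzero spread), mean-parameterized lognormal
  (CV = `within_cv` = 0.35) for continuous quantities, NB2 counts with
  `var = μ(1+θμ)`, θ = `dispersion` = 0.7 (θ = 0 gives Poisson) — mirroring
  beta/Poisson/negative-binomial model families typical for such data.
- **Assemblages**: per-trap/quadrat richness is drawn directly (floor +
  Bernoulli, so its expectation is exactly the target), the taxa are chosen
  by probability-weighted sampling without replacement (Gumbel top-k) from
  per-treatment composition profiles, each chosen taxon is guaranteed one
  individual, and the remaining total (negative binomial with mean adjusted
  so the density expectation is exact) is allocated multinomially. The
  Restore Low profile is dominated by non-flying arthropods (mites,
  springtails); Protect profiles are insect-dominated and identical for PH
  and PL, so the pairwise PERMANOVA pattern (only PH–PL indistinguishable)
  emerges from composition, not tuning.
- **Profiles** are piecewise-linear and exactly realize the configured
  encroachment, toe–MSL slope, and toe–MLLW width under default datums
  MHHW = 3.0, MSL = 1.5, MLLW = 0.0 m; optional seeded elevation noise.
- **Grain size**: a normal on the φ scale whose sd comes analytically from
  the σ_G target via the Folk & Ward formula and whose mean is solved
  (coarse branch, consistent with mixed coarse beaches) so the sand-window
  mass matches the percent-sand target; discretized on a dyadically refined
  ladder that keeps the Wentworth bounds on-grid. Unattainable pairs (high
  sand demanded of a very poorly sorted target) raise a diagnostic.
- **Waves**: all sites face S/SW with fetch solved by inverting the
  fetch-limited relation to meet the configured wave height — a 6 h event at
  15 or 10 km/h cannot physically reach the 0.45–0.48 m targets, and
  southerly storm winds dominate the region. Jittered targets are clamped
  below the 6 h growth limit (~0.61 m).

What the generator does **not** emulate: spatial autocorrelation along the
shore, temporal (seasonal beyond the two-season split) structure, taxonomic
covariance between assemblages and sediment, and observation error in the
RTK/drone-derived inputs. Passing recovery tests therefore demonstrate the
pipeline's correctness and calibration under the stated noise families, not
field realism of any particular dataset.

## Numerical choices and problem sizes

Percent sums may carry ±0.5 rounding slack and are renormalized internally.
Datum-crossing interpolation is linear; percentile interpolation is linear
in φ. Tie rule for min–max scaling: all-equal → 0.5. The recovery check
runs the noise-free generator (all noise scales zero; counts Poisson) with
enlarged replicate counts (2×10⁵ log points, 5×10⁴ snorkel transects,
5×10³ fallout traps, 500 MLLW quadrats and vegetation transects per site)
so Poisson counting error on the smallest count means (0.1 per point) sits
well inside the 1% recovery tolerance; the residual ~0.4% worst-case error
is the deterministic φ-ladder discretization bias of the sorting statistic.
Null calibration of PERMANOVA uses 1000 simulated datasets (12 samples, 3
groups, 99 permutations each). These sizes keep the full test battery
around a minute on one CPU.

## Known limitations

- The exact constants of the simplified wave method follow the 1984 Shore
  Protection Manual presentation; other presentations differ slightly in
  constants, and per-site fetches of the original campaign are unpublished,
  so surveyed wave heights are emulation targets, not reproductions.
- The feeding-percentage metric and the printed feeding contingency counts
  are internally inconsistent in the source material (28.6% vs 4/10); the
  contingency counts are treated as authoritative for the chi-squared test
  and the percentage column for the scale bar, without reconciliation.
- GLMM/AICc model selection and estimated-marginal-means contrasts are
  intentionally out of scope; the stratified permutation test is this
  package's substitute for univariate treatment contrasts.
- One vegetation transect and one profile per site means several site-level
  metrics have no within-site replication in the default design; their
  uncertainties enter only through region effects.
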