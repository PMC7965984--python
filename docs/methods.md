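# Methods

This note documents the models implemented in `deadwood`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
stand generator does and does not emulate.

## Stem maps

A stem map is an axis-aligned rectangular window (metres) plus one record
per stem: id, planar coordinates, species, status
(`live_planted | live_lcp | snag | fallen | broken | stump`), DBH `d₁.₃`
(cm), height or piece length (m), central diameter `d₁/₂` (cm, mandatory
for broken wood), and decay grade 1–5. Coordinates are treated as
planimetric even when an elevation was surveyed: every statistic here is
two-dimensional. Live stems are classified by species membership — a live
stem of a planted species is `live_planted`, anything else is a
later-coming population (LCP). *Deadwood* means snags + fallen + broken
wood; stumps are harvest residue kept only for loss accounting, and a
stump is the only status allowed to lack a DBH. Stems mapped below the
1 cm census threshold trigger a validation warning, not a rejection,
because synthetic data may legitimately probe below it.

## Volumes and DBH distributions

Standing stems use the form-factor equation
`V = (π/40000) d²₁.₃ (h+3) f` with `f = 0.4` for conifers and `0.2` for
broadleaves; lying wood with a measured central diameter uses the cylinder
`V = (π/40000) d²₁/₂ l`. Fallen wood takes the cylinder form when `d₁/₂`
was recorded and falls back to the form-factor equation on DBH and length
otherwise; both routes are available because field protocols differ on
which diameters get measured on down wood. Regional two-way volume tables
can replace the closed form via `VolumeTable` (a nearest-cell (d, h) → V
lookup loaded from CSV); no specific regional table ships with the
package, so volume outputs are validated by closed-form properties
(positivity, monotonicity, the exact conifer:broadleaf factor of 2), not
against tabulated values.

DBH histograms use half-open classes `[origin + k·w, origin + (k+1)·w)`
with defaults `w = 2 cm`, `origin = 1 cm` (the census threshold); a value
on a boundary belongs to the upper class. Curve fits are nonlinear least
squares of class counts on class midpoints for two families,
`a·exp(−(x−μ)²/2σ²)` and `a·exp(−b·x)`; goodness of fit is the KS test of
the raw values against the fitted shape normalised to a density, and
"fits" means p > 0.05. Caveat, stated deliberately: the classical KS
p-value with parameters estimated from the same sample is conservative
(biased toward large p). We report it anyway because it is the standard
field practice this package mirrors; treat "fits" as "not contradicted",
not as a calibrated test. Degenerate histograms (fewer than three
non-empty classes) and non-convergent optimisations return a flagged
failed fit rather than raising.

## Pair correlation function and CSR envelopes

The pair correlation function `g(r)` is estimated with an Epanechnikov
kernel on pair distances,

    ĝ(r) = Σ_{i≠j} k_h(r − ‖x_i − x_j‖) e_ij / (2π r λ̂² |A|),  λ̂ = n/|A|,

with Stoyan's bandwidth rule `h = 0.15/√λ̂` by default. Two edge
corrections are implemented: Ripley isotropic (the default; the weight is
the reciprocal fraction of the circle of radius `d_ij` centred on `x_i`
that lies inside the rectangle, computed in closed form from the four edge
distances with corner-overlap subtraction) and translation
(`e_ij = |A|/((W−|Δx|)(H−|Δy|))`). The two agree within Monte-Carlo noise
away from the boundary; isotropic was fixed as the default because it is
the common choice for rectangular forest plots.

The r grid runs from the bandwidth (the kernel estimator is unstable as
r → 0) to half the short window side, in 0.25 m steps. Envelopes are
*pointwise*: the null model is CSR conditioned on the observed n (a
binomial process, matching fixed-n envelope practice), `n_sim = 999`
simulations by default, and the bounds at each r are the order statistics
of rank `⌊0.025(n_sim+1)⌋` and `n_sim+1` minus that rank — ranks 25 and
975 of 999. Labels per r: clustered above the envelope, regular below,
random inside; contiguous runs are summarised as scale intervals
("clustered 1–3 m"). Fewer than 39 simulations cannot resolve a 2.5%
tail and triggers a warning. Each envelope call spawns one RNG substream
per simulation, so results are reproducible and independent of evaluation
order. A pointwise 95% envelope labels ≈ 5% of grid points non-random
even for a truly random pattern; interpret isolated excursions
accordingly (no global rank envelope is provided).

## Structure indices

Structure units pair each reference tree with its 4 nearest neighbors;
stems within the buffer (default 5 m) of the plot perimeter serve only as
neighbors. The uniform angle index `W` counts the fraction of the four
consecutive neighbor-azimuth gaps strictly smaller than the standard angle
α₀ = 72°; mingling `M` is the heterospecific fraction; dominance `U` is
the fraction of neighbors with strictly larger DBH, so a high `U` marks a
suppressed reference tree (ties count as "not larger"). Exact
neighbor-distance ties are broken by id order for determinism. The
default neighbor pool is every mapped stem except stumps — deadwood is
scored as it stands among the live matrix — and is configurable (e.g.
live-only). Under CSR the grand mean `W` computed by this implementation
is ≈ 0.49, inside the conventional random-pattern interval 0.475–0.517
used to read observed means; planting lattices push `W` below it.

## Competition and mortality

Competitors of stem i are its Voronoi natural neighbours: the tessellation
is computed over the pre-death stand (live stems plus deadwood at recorded
DBH; stumps excluded — a dead tree's competitive environment is
reconstructed from the only map available), unbounded ridges are extended
far beyond the plot, every ridge is clipped to the window rectangle
(Liang–Barsky), and two stems compete iff their shared clipped edge has
positive length. Cells that are unbounded or reach outside the window are
flagged `edge_affected`; they keep their competitors, since dropping them
would bias stand means, but the flag lets a user exclude them. Degenerate (collinear) configurations are retried once
with a deterministic 10⁻⁶ m jitter and a warning.

Hegyi's index `HCI_i = Σ_j (d_j/d_i)/dist_ij` is summed over those
competitors. It is invariant to rescaling all DBHs and inversely
proportional to rescaling all coordinates; coincident stems are an error
naming both ids.

Mortality is fitted by maximum likelihood (Newton–Raphson, tolerance
1e−8, ≤ 100 iterations, via statsmodels) for
`logit(p) = β₀ + β₁·x` with x = DBH (field use) or x = HCI (generator
recovery). Complete separation and other failures are returned as
flagged non-converged fits. Discrimination is the rank-based
(Mann–Whitney, midranks for ties) AUC with rating bands 0.8–1.0
excellent, 0.6–0.8 good, 0.4–0.6 poor, below fail; a boundary value takes
the upper band.

## Synthetic stand generator

The generator's defaults encode the silvicultural history the analyses
assume: uniform planting at 2,000 stems/ha (square lattice of spacing
√(10⁴/density) ≈ 2.24 m with 0.3 m Gaussian placement jitter — planting
crews deviate at the decimetre scale), species mixed i.i.d. at 6:1,
establishment survival 87%; optional thinning converting 26% of stems
with DBH ≥ 9 cm into stumps, chosen uniformly; Thomas-process LCP
recruitment (Poisson parents, Poisson offspring counts, Gaussian
displacement) reflecting the clustered establishment of colonising
species; and competition-driven mortality, in which each live planted
stem dies with probability `expit(β₀ + β₁·HCI)` so that "competition
kills" is a recoverable ground truth (a DBH-driven mode exists as an
alternative). Dead stems draw a deadwood type from configurable
snag/fallen/broken probabilities — no mechanism distinguishes the three,
because none is established; the split is a free parameter. A small
density-independent LCP mortality (default 2%) produces LCP deadwood that
inherits the clustered pattern of recruitment.

Two factory configurations bundle coherent scenarios. The mixed-stand
factory (120 × 60 m, no thinning, β₀ = −2.3, β₁ = 0.8) loses ≈ 45% of
planted stems at the default geometry, the mortality level reported for
unthinned mixed Chinese fir stands at rotation age; the thinned factory
(100 × 80 m, monoculture, thinning on, β₀ = −3.3, β₁ = 0.5, richer LCP
recruitment, a broken-wood share from felling damage) reproduces the
qualitative contrast: far less deadwood, more and better-mingled LCPs.
DBH is lognormal per group (planted: meanlog 2.5, sdlog 0.35 ≈ 13 cm
median; LCP: meanlog 1.6, sdlog 0.5 ≈ 5 cm) with a truncated-normal
alternative to exercise Gaussian-shaped DBH-class fits; heights follow
`h = 2.0 + 0.6·d + N(0, 0.8)` m floored at 1.5 m — a deliberately crude
allometry, adequate because no implemented statistic depends on height
beyond volume. Broken stems get `d₁/₂ = 0.7·d` and 60% of their height as
length; fallen stems get `d₁/₂ = 0.75·d`.

Each stage draws from its own substream of the master seed
(`SeedSequence.spawn`), so reconfiguring one stage never perturbs the
randomness of another; stems are only relabelled, never deleted, by
mortality and thinning; and under common random numbers increasing β₁
can only add deaths. Note the stage order is plant → size → mortality →
thin → recruit: mortality therefore acts on pre-thinning competition. The
generator emulates *pattern*, not *process over time*: there is no
growth, no senescence, no windthrow, no pests, and deadwood type is
independent of cause. Passing tests on synthetic stands demonstrates that
the estimators recover known structure (clustering, competition effects,
mixing levels) — not that real Chinese fir stands satisfy the generator's
assumptions.

## Pipeline and reference checks

`pipeline.run` sequences the stages (abundance, DBH fits, PCF envelopes
per deadwood group, structure means, HCI table, mortality fits per
grouping: all stems / planted / LCP) from a YAML config, records per-stage
failures without aborting the rest, and writes byte-identical outputs
under a fixed seed. `verify_census_counts` recomputes nine stand-level
proportions from embedded census counts of two reference plots (e.g.
558/2,467 deadwood stems = 22.61%; 536/1,191 planted-fir deaths = 45.0%)
and checks them at two-decimal precision, allowing one unit in the last
printed decimal to absorb truncation-vs-rounding differences.

`scripts/acceptance.py` re-derives the CSR reference point of the uniform
angle index — 20 seeded CSR stands of 2,000 stems in 100 × 80 m, 5 m
buffer — chosen as a desk-scale experiment that exercises the whole
simulate → build-units → index chain; the suite's other statistical
calibrations (envelope coverage, Thomas-cluster detection, logistic
coefficient coverage at n = 2,000 over 100 replicates) run at sizes that
keep the default test run inside a few minutes on one CPU.

## Known limitations

- KS p-values after parameter estimation are conservative (above).
- Envelopes are pointwise, not global; multiple-testing across scales is
  left to the reader.
- Voronoi competitor selection near the boundary depends on the clipping
  rule; `edge_affected` flags, but does not correct, this.
- The generator's mortality ignores size directly (HCI mode), whereas real
  mortality mixes size, competition, and damage; panel-style comparisons
  of planted vs. LCP mortality curves are sensitive to that choice.
- `k = 4` neighbors is configurable but untested for other k; the
  DBH-differentiation index and species-pairwise mingling are out of
  scope.
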