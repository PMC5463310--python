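# Methods

This note documents the models and procedures implemented in
`neighscan`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic data can and
cannot show.

## Synthetic metropolitan area

The generator (`neighscan.synthetic`) emulates the data substrate of a
fine-scale contextual health study in planar metric coordinates (no
geodesy: at metropolitan extent, projection error is negligible
relative to a 250 m grid).

**Census blocks.** A clipped Voronoi tessellation of uniformly random
seeds — it guarantees an exact planar partition of the extent, which
the dasymetric step relies on. Default 36 blocks of ~2000 inhabitants
(the size of a French IRIS census block) over a 6 × 6 km extent; block
populations are Normal(2000, 300), floored at 200. Four analysis strata
(sex × age bands 35–54 / 55–74) take ~46% of each block's population;
the remainder is outside the studied age range.

**Deprivation field.** A latent centre–periphery surface
`d(p) = s·(1 − 2r̂(p))` (most deprived at the centre, range ±s, default
strength s = 1) plus an optional linear tilt. Every socioeconomic
variable is `base + slope·d + Normal(0, σ)` clipped to [0, 100] — all
percentage-type variables use the 0–100 scale throughout the package.
Slopes are signed so that unemployment, precarious jobs, welfare
coverage etc. rise with deprivation while two-car ownership and
graduation rates fall.

**Buildings** are axis-aligned squares (10–24 m sides) clipped to their
block, one per ~60 inhabitants, with 1–7 storeys (taller toward the
deprived core) and height = 3 m × storeys + jitter < 3 m, so the floor
count recovered by `⌊height/3⌋` is exact.

**Amenities** are inhomogeneous Poisson point processes thinned against
the deprivation field, `λ(p) ∝ exp(γ·d̂(p))`. The default couplings are
*positive* (deprived areas better equipped), reproducing the empirical
inverse relation between deprivation and amenity access seen in the
study setting this pipeline was built for; the sign and strength are
per-layer config fields. Parks are discs drawn across the three
size classes (<1, 1–10, >10 ha); stops carry line counts; retail
carries category and lognormal floor space; school grading skews toward
the priority (ZEP) class with deprivation.

**Cases.** Per block and stratum, `count ~ Poisson(N_s · years ·
rate_s/10⁵ · m)` where the multiplier m is the product of planted
circular cluster relative risks containing the block centroid. Planted
clusters are circular multiplicative fields because the circular scan
is the detection target — recovery is then a fair test. Default annual
baseline rates per 100,000 (f 35–54: 200; f 55–74: 1000; m 35–54:
1000; m 55–74: 3000) follow the canonical MI pattern of male and older
strata several-fold higher. Case locations are uniform over the block's
building footprints weighted by habitable area; years are uniform over
the 8-year span (no temporal trend is modelled). Denominators are
mid-period population × years; a person-years switch exists because
registry denominator handling varies between studies (the two coincide
under the generator's static population).

## Grid and dasymetric disaggregation

Cell size defaults to 250 m and can be derived from data:
`choose_cell_size` rounds the mean nearest-neighbour distance of a
point layer to the nearest 50 m (ties round down — a finer grid loses
less information). Cell ids are (row, col) from the lower-left corner
with half-open intervals [x, x+size), so boundary points belong to
exactly one cell.

Zone clipping computes exact vector intersections (no rasterization).
The transfer weight is the habitable-area share; buildings straddling a
cell boundary contribute to each side proportionally to footprint
intersection (the source geometry is silent on this; proportional
splitting is the only mass-conserving choice). Floors are
`⌊height/3⌋`, minimum 1 at height ≥ 3 m: partial floors are not
habitable, and below 3 m the formula is undefined (an error, as is a
populated block with no housing volume, whose denominator would be 0).
Rate-type variables are converted to counts via block population before
splitting and re-expressed against the cell population, which makes
uniform rates exactly invariant. Cells without buildings get population
0, are flagged uninhabited, and are excluded from profiling, zone
design and scanning. Mass conservation holds to 1e-6 relative for
population and every count variable, at any grid size.

## Accessibility indicators

All catchments and buffers are *strictly inside* (a site exactly on the
radius does not count); the convention is tested. Road distances run on
a lattice street graph (default 500 m spacing) — a synthetic stand-in
with the right qualitative behaviour (network ≥ Euclidean, detours
around the lattice) but none of a real network's topology. Distances
are snapped: straight connector + shortest path + connector, minimized
over sites by a single multi-source Dijkstra.

Open choices, all config-exposed:

* **Park combination rule** — how multiple attracting parks combine is
  unspecified in the source procedure; the default counts attracting
  parks, with `max` and `area_weighted` alternatives.
* **School grading weights** — ZEP=1, AR=2, other=3 is an explicit
  guess at an unspecified scheme (higher = more favourable
  socio-educational context, matching the ordinal use of the
  classification); with equal weights the index degenerates to school
  density.
* **Retail score** — the outlet count within 200 m apportioned by
  category floor-space share; with equal floor spaces the categories
  sum to the plain count. `calibrate_retail_radius` reproduces the
  radius-selection rule (smallest 10 m step at which ≥ 50% of cells
  have an outlet).

## MFA and contextual profiles

Quantitative groups are z-standardized and analysed by PCA; qualitative
groups are expanded to centred indicator columns with
correspondence-analysis scaling `(1_k − p_k)/√(Q·p_k)`. Each group is
divided by √λ₁ of its separate analysis (the Escofier–Pagès metric), so
each group's leading dimension carries unit inertia; the source
procedure says only that the weighting is "based on the highest
eigenvalue" — the √λ₁ division is the canonical choice and reduces
correctly in the single-group limit (plain standardized PCA up to a
global factor). Constant variables are dropped with a warning;
single-level qualitative variables are an error; missing values must be
imputed or dropped upstream (the pipeline median-imputes and logs).

Ten components are retained by default (preserving most of the
variability) and fed to Ward hierarchical clustering via
`scipy.cluster.hierarchy` (minimum within-variance merges; validated
against an exhaustive greedy ΔESS oracle on small inputs). The cut is
k = 5 by default but a flag: the original choice was a dendrogram
judgement call. Classes are relabelled A→E by ascending composite
deprivation — the class mean of standardized unemployment +
precarious-jobs + safety-net coverage. The composite is used *only* to
order labels; the source orders its profiles qualitatively without a
formula. In the pipeline the psychosocial indicators are discretized to
ordered quintile categories before the MFA, exercising the qualitative
branch the way mixed contextual data would.

## Zone design

Zones must partition the inhabited cells, stay contiguous under
4-adjacency (diagonal contact is not contiguity — stricter, and avoids
string-of-pearls zones) and keep population > 0. The annealer minimizes

`E = w_pop·Σ_z((pop_z − T)/T)² + w_homog·(1 − IAC) + w_shape·mean(P2A)`

with T = 2000 inhabitants. **IAC** is the one-way ANOVA intraclass
correlation ICC(1) of the numeric profile score (A=1 … E=5) grouped by
zone, `(MSB − MSW)/(MSB + (n̄−1)·MSW)` with n̄ the mean zone size (an
η² variant is available); the source names the criterion without a
formula, and ICC(1) is the standard homogeneity ICC. **P2A** is the
isoperimetric quotient `perimeter²/(4πA)` (1 for a disc), computed for
cell unions by exact edge counting. Moves reassign one boundary cell
when donor and receiver both stay contiguous and non-empty; acceptance
is Metropolis under geometric cooling (T₀ = 1, decay 0.999, 20,000
iterations by default); all statistics update incrementally so a move
costs O(zone size). The best-ever state is returned, making the
achieved objective non-increasing in iteration count. Six weight
presets are shipped (population / homogeneity / shape dominant and
mixtures); the exact historical weightings are unknown. On cities with
blockwise-constant profiles the homogeneity preset reliably exceeds
the conventional IAC > 0.5 bar (typically reaching ~0.8).

## Rates

Direct standardization over the sex × age strata with the whole
synthetic study area as the default reference (the original standard
population is unnamed; the reference is swappable). CIs are normal
approximations on the weighted-Poisson variance — adequate for the
event counts the generator produces, anti-conservative below ~10
events per stratum. Profile comparisons use the χ² homogeneity test
with expectations proportional to person-years; the cluster crosstab
contrasts cluster populations by profile and binary features with
per-row 2×2 χ² (no continuity correction).

## Spatial scan

Circular windows are centred on every zone centroid and grown in
centroid-distance order (ties by zone id) until the next zone would
push the window past 50% of the population at risk; membership is by
centroid inclusion, not polygon intersection, matching the
centroid-based procedure. The Poisson LLR uses the 0·ln 0 = 0
convention and is counted only in the scanned direction (c > E high,
c < E low); high and low are scanned separately (whether the original
analysis ran one combined or two separate scans is unstated — both are
offered). Expected counts are population shares (crude) or indirect
age/sex standardization `E_i = Σ_s N_is·C_s/N_s`; both conserve
ΣE = C exactly, and replicates are regenerated under the adjusted
expectations so adjustment affects observed and null alike. Inference
conditions on C: multinomial replicates with probabilities E/C,
re-scanned identically; with 999 replicates p-values live on
{0.001, 0.002, …, 1}. Secondary clusters are reported in decreasing
LLR among windows sharing no zone with a better-ranked cluster (the
usual no-geographical-overlap reporting rule). On ≤ 30 zones the
vectorized scan is verified against an exhaustive window-by-window
evaluation; under flat risk its rejection rate at 0.05 is nominal
within binomial error.

## Problem sizes

The validation suite and the acceptance script run at desk scale,
chosen as the smallest sizes at which every statistical property is
cleanly measurable: 36 blocks / ~500 inhabited 250 m cells / ~72,000
inhabitants / 8 years (~3,500 cases) for the zone-design and
planted-cluster analyses; 20-zone tables for the 200-simulation type-I
study (199 replicates each); 50 replicates for cluster recovery. The
planted-cluster benchmark covers ~10% of the extent with relative risk
3, which at these case counts puts the observed LLR far beyond every
null replicate — hence the floor p-value of 0.001.

## Limitations

The synthetic city is a structural, not empirical, model: Voronoi
blocks, a lattice road network, radially organized deprivation and
independent noise across variables. Passing tests demonstrate that the
algorithms are correct and the pipeline recovers planted structure
under its own assumptions; they say nothing about effect sizes in any
real city, and the specific profile tables or rate levels produced
here are not comparable to values estimated from restricted census and
registry data. Elliptic and space–time scan windows, Bernoulli/ordinal
scan models, Gumbel-approximated p-values, amenity *usage* modelling,
temporal risk trends and denominator drift are out of scope.
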