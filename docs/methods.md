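# Methods

This note documents the models and procedures `txaccess` implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Access model

A census tract's minors have legally protected access to confidential
contraceptive care in an epoch when at least one of two criteria holds:

1. **Catchment criterion.** Some program-funded clinic lies within a
   drive-time threshold of the tract's population-weighted centroid. The
   threshold defaults to 30 minutes, after Medicaid network-adequacy
   standards for maximum reasonable travel to care, and is *inclusive*
   (travel time ≤ 30.0 grants access). The original analysis did not state
   whether its boundary was inclusive; we chose the inclusive reading and
   expose the threshold as configuration.
2. **Law criterion.** The tract sits in a state whose statutes both let all
   minors consent to contraceptive services and guarantee confidentiality
   ("protective"). Law status is epoch-constant: one record per state.

Crossing two epochs yields the change label: *lost* (access only in the
first), *maintained*, *gained*, *never*. Two sensitivity modes replace the
access rule: `catchment_only` drops the law criterion (identifying
protective-state tracts that lost their only in-range clinic), and
`expanded_law` also counts consent-with-physician-discretion states as
protective.

Youth at risk is the summed population aged 15–17 over lost tracts. The
Medicaid-enrolled share of that population is estimated per tract as
(Medicaid-enrolled minors) × (proportion of minors aged 15–17), rounded
half-up to a whole person *before* summation; the source analysis is silent
on rounding, and per-tract half-up keeps the estimate integral and
reproducible.

## Travel times

The road network is an undirected graph with located nodes and
minute-weighted edges (no one-way streets or turn penalties — beyond the
resolution of the question). Origins and clinics snap to their nearest node
by straight-line distance (Euclidean for planar synthetic coordinates,
haversine/unit-sphere for lon/lat); the off-network snap distance is
charged at a configured access speed. Minimum time to *any* clinic is
computed with one multi-source Dijkstra pass per epoch via a virtual source
attached to every clinic's snapped node, which equals (and is tested
against) the per-clinic minimum. Unreachable targets get +∞; an epoch with
no clinics yields "no access", not an error. A network-free fallback
converts straight-line distance to minutes directly; on a complete graph
whose edges encode straight-line times the two modes agree exactly.

## Roster handling

Clinic identity is keyed on a normalized name (case-folded,
punctuation-stripped, whitespace-collapsed) plus coordinates rounded to 4
decimals (~11 m); ids are not assumed stable across source documents.
Deduplication keeps the first record per key. Membership is the exact
partition left/joined/stayed; net loss = |left| − |joined|. Affiliation is
assigned with precedence CrisisPregnancyCenter > PlannedParenthood > FQHC >
Other: the categories were published without a precedence rule, and the
name/registry-based CPC and PP identifications are disjoint from FQHC
designation in practice; the precedence is a documented, configurable
choice. RUCC 1–3 is urban, 4–9 rural. Composition tables carry per-epoch
counts, net change, and column percentages rounded half-up to one decimal
(matching how printed tables round); χ² tests are Pearson without
continuity correction.

## Statistics

**Odds ratios.** Lost-vs-maintained only: never-access and gained tracts
are excluded by design, and rows missing a covariate are dropped from that
covariate's analysis only. Continuous covariates are binned at their
empirical 25/50/75 percentiles with ties to the lower bin (a rule
`pandas.qcut` does not implement, hence hand-rolled); a constant series is
a degenerate-quartile error. For a categorical predictor the estimate is
the cross-product 2×2 odds ratio with Wald 95% CI
`exp(ln OR ± 1.96·√(Σ 1/cell))`; this coincides with the
maximum-likelihood univariate logistic coefficient, which the tests verify
against statsmodels to 4 significant figures. Wald intervals (not
profile-likelihood) were adopted because they reproduce every published
interval from its own cells. Zero cells are an error — continuity
corrections are out of scope. No multivariate model (covariates are
collinear) and no multiplicity adjustment; two-sided α = 0.05.

**Interrupted time series.** Annual clinic counts are fitted by OLS with
design `1 + (year − start) + post + post·(year − breakpoint)`, a
level-and-slope-change parameterization; the pre-break slope is the year
coefficient and the post-break slope the sum of year and interaction
coefficients, each with a Wald 95% CI (the post-slope CI via the linear
combination). The exact design matrix of the original analysis is
unpublished; this is the standard segmented-regression form. At least two
points are required per segment — the motivating series itself has only
two post-break years, so a stricter minimum would reject the design the
method exists for.

## Synthetic generator

`generate_scenario` builds a full study world from one seeded RNG stream
(fixed draw order, so equal configs give bit-identical bundles): states as
square planar blocks with law records (a configurable fraction fully
protective, the rest split among no-law / limited-category /
physician-discretion types), tracts nested in states with 1–9
lognormal-weighted sub-unit points, clinics placed near tract centroids
with a configurable affiliation mix, epoch-two rosters from
affiliation-specific exit probabilities (default 0.99 for Planned
Parenthood, echoing the observed 99% exit; ~0.25/0.36 for FQHC/other so
roughly 40% of the roster exits) plus an 11% entry rate, optional exact
name+coordinate duplicates under fresh ids, and a connected road network
(4-nearest-neighbour edges plus a Euclidean minimum spanning tree obtained
from the Delaunay triangulation; edge minutes = length × speed).

Default geometry — clinic density 0.06 per tract and 6 minutes per
coordinate unit against the 30-minute threshold — was set once so the
realized category mix matches the study's magnitudes (roughly 8% lost, 84%
maintained, 1% gained, 6% never).

**Planted effects.** Loss is produced mechanically (exits shrink
catchments; protective states cannot lose), then covariates named in
`planted_or` are sampled *conditionally on the realized loss indicator*:
binary/categorical covariates with level odds scaled by the planted OR,
continuous covariates with a geometric odds gradient across quartiles
(top-vs-bottom odds equal to the planted OR) materialized through the
covariate's base quantile function. Kept tracts always draw from the base
distribution, so downstream empirical quartile cut points stay close to
the base quartiles and the contingency estimate converges to the planted
value. When a region OR is planted, region becomes a tract-level covariate
(otherwise it is the state's region); nothing in the access rules consumes
region, so state nesting of the access logic is unaffected. The annual
count series plants the published segment slopes (−68.2/yr before 2019,
−918.8/yr after) around a base level of 6000 with Gaussian noise (sd 10).
Medicaid-enrolled minors, whose real sourcing is undocumented, are drawn
as a Beta(2,4) fraction of each tract's minors.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real US geography and state statutes; spatially
correlated clinic exits (closures cluster by grantee; synthetic exits are
independent given affiliation and region); traffic, one-way streets, and
drive-time polygons; correlation *between* covariates (each planted
covariate is conditionally independent given loss, whereas real SVI, race,
ethnicity and birth-rate measures are strongly collinear — the very reason
the original analysis stayed univariate); geocoding error; and clinic
capacity or actual utilization.

## Calibrated fixtures

`txaccess.calibrated` builds rosters and tract tables whose *marginal*
counts match the published composition (4466 roster records with 123
duplicates, 1743 exits, 494 entries, per-affiliation/density/region/law
margins; 72 760 tracts with 6299 lost, published contingency cells, youth
totals 933 649 / 642 850 / 1 811 818). Attributes are assigned blockwise
and independently within membership blocks, so joint distributions are
arbitrary but every margin the tabulations consume is exact. Cells that
sum short of their block total leave the remainder missing, mirroring the
<1% missing-covariate exclusions. These fixtures exercise the arithmetic;
they carry no geographic information.

Published tract totals are internally inconsistent in places (72 620 vs
72 760 evaluated tracts; 3832 vs 4669 never-access; 721 vs 729 gained; the
39.0% exit share uses the pre-deduplication denominator 4466 while
1249 = 4343 − 3094 is post-deduplication). The pipeline reports its own
internally consistent counts and the fixtures expose both net-loss
denominators.

## Numerical notes and limitations

* Percentages print with decimal round-half-up, not banker's rounding.
* Dijkstra, χ², OLS and logistic ML come from networkx, scipy and
  statsmodels; the contingency OR, Wald intervals, quartile rule, and all
  classification logic are implemented here and cross-checked against
  independent oracles (exhaustive path enumeration, textbook χ² formula,
  ML logistic fits) in the test suite.
* Problem sizes used in tests and the acceptance script (20-state,
  20 000-tract recovery scenarios; 50 interrupted-time-series replicates;
  1000 randomized catchment cases) are the package's own defaults chosen
  to make sampling error small relative to the effects being recovered.
* Duplicate detection handles exact normalized-key copies only; fuzzy
  record linkage is out of scope, as is any real-registry lookup.
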