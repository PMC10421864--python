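# Methods

## Scope and model structure

`lucflux` implements annual bookkeeping of net CO₂ fluxes on a gridded
landscape with five land-use categories (forest, shrub/grass, plantation,
urban, water). Per cell and year the net flux is the sum of conversion
emissions, biomass-burning emissions, peat-burning emissions and drained-
peat decomposition, minus the growth sink. The chain has four stages:
feature construction and voted classification produce annual maps; the
state module tracks conversions, merged fire events and the evolving
aboveground-biomass (AGB) field; the emission module prices each event;
reporting derives rates, shares and correlations.

## Units and numerical conventions

Biomass state is carried in t dry matter ha⁻¹; emission arithmetic runs in
g CO₂ with areas in m², fuel in kg and depth in m (1 t ha⁻¹ = 0.1 kg m⁻²);
aggregates are reported in Tg CO₂ yr⁻¹ and Mg CO₂ ha⁻¹ yr⁻¹. The
carbon-to-CO₂ ratio is exactly 44/12. All flux identities
(E_T = ΣE − Sink) hold exactly in floating point because E_T is always a
derived signed sum, never stored separately.

The fuel-depletion sum over the I fires of a year is evaluated in closed
form, `AGB_pre · (1 − (1−BE)^I) / BE`, which equals the literal geometric
sum to ~1e-15 relative (verified exhaustively for BE ∈ {0.05,…,1.0},
I ≤ 20). BE = 0 is handled as the degenerate limit `AGB_pre · I`
(nothing burns regardless). Display rounding (integer vs one-decimal
percentages) is applied only at the formatting boundary.

## Annual update order

The within-year order is **growth → fires → conversion**: fires burn the
stock standing after that year's growth, and a conversion — recorded in
the end-of-year map — resets AGB to the target category's default
post-conversion stocking. The ordering is a modelling choice (the source
data fix only the annual map sequence, not intra-year timing); its
rationale is that dry-season fires burn vegetation that grew during the
year, and clearing observed in year *y*'s map completed by the end of *y*.
Growth (and hence the sink) uses the category standing at the start of the
year; fire parameters use the target-year map, which is the map the fire
detections overlay.

A conversion into a category whose default stocking exceeds the standing
AGB would give a negative biomass drop; such conversions contribute zero
to E_LUC (regrowth belongs to the sink, not to negative emissions).
AGB is floored at zero on every path.

## Fires, ordinals and peat

Daily detections carry a confidence class; the nominal-confidence map
(NCM) keeps nominal+high detections, the low-confidence map (LCM) keeps
all three, so NCM events are always a subset of LCM events. Detections on
consecutive days at one cell are one ongoing fire; a gap of more than
`merge_gap` days (default 1) starts a new event. Each cell's events are
numbered consecutively from the accounting start (the *fire ordinal*); the
peat burn depth decays with the ordinal through the DR schedule
(1.0 for the first fire, non-increasing, clamped at its last entry for
ordinals beyond the schedule). Burned area equals full cell area —
sub-cell burn fractions are out of scope.

Drainage is temporal by default: a peat cell is drained from the first
year its map category is shrub/grass, plantation or urban (water is
flooding, not drainage), and stays drained; `static=True` reproduces the
whole-period reading where a cell ever drained counts as drained
throughout. Decomposition uses the drained/undrained emission factor of
the cell's current category.

## Classification

Features (228 per cell) are: the annual composite of the 7 bands (most
recent good-quality observation searching backward from December 31 within
the calendar year; cells with no good day are nodata, never zero-filled),
13 spectral indices, 8 time-series statistics per band over the good days,
and the 9×9-window mean and population SD of each of the 76 base features.
Windows truncate at grid edges and exclude nodata members — no reflectance
is fabricated. The index and statistic sets are pluggable registries with
strict-count validation; the shipped defaults (standard vegetation, water
and burn normalized differences, simple ratios, two soil-adjusted forms;
mean/SD/min/max/median/10th/90th/range) are documented placeholders that
users can replace without code change.

The classifier is an interchangeable fit/predict component; the default is
a scikit-learn random forest (100 trees, fixed seed). Supervised points
are digitised at the first and last years; points with identical labels in
both are usable for intermediate years. Classification runs five times on
stratified four-fifths splits; the per-cell plurality over the five maps
wins, ties break toward the category with more supervised points, and a
double tie falls back to the fixed category order. Post-processing then
(1) gap-fills nodata by iterated 8-neighbour majority (ties resolved by
the previous year's category when it is among the modes, else fixed
order), (2) makes plantation absorbing, and (3) rewrites one-year
urban→forest and water→forest transitions to shrub/grass. The rewrite is
deliberately year-over-year only — the physical argument (a mature forest
cannot appear in one year) does not constrain multi-year gaps. The
composite is idempotent, which the suite checks on random map stacks.

## Parameters and the uncertainty envelope

Every scaling factor is an envelope (min ≤ central ≤ max). The shipped
default file holds documented placeholder envelopes spanning published
ranges for insular Southeast Asian landscapes (e.g. live/dead carbon
contents 0.4560/0.4716, first-fire burn depth 0.33 m central, forest
growth 3.4 t DM ha⁻¹ yr⁻¹ central per IPCC tropical-rainforest guidance);
it is not a calibrated site dataset and real runs should supply their own.
Peat combustion carries its own per-category emission factor (EF_pb)
distinct from the biomass-burning factor, since the two fuels differ.

Envelope runs collapse every parameter to one bound. Because the sink
enters the net flux negatively, the default collapsing is *sign-aware*:
the emission-maximising scenario pairs maximal emission-side parameters
with minimal growth (and vice versa), making Emin ≤ Eavg ≤ Emax a true
bracket; `sign_aware=False` collapses growth to the named bound for the
raw reading. Strict per-region-year bracketing is a first-order property,
not a theorem: with heavy multi-year fire feedback a higher burning
efficiency depletes fuel for later years and could in principle cross the
central run. On the scripted study scenes (short horizons, at most a few
fires per cell) the bracket holds everywhere, and the suite asserts it.
The 2×2 ensemble over fire regimes {NCM, LCM} and two AGB sources is a
plain arithmetic mean per cell, year and component; fewer members are
averaged as-is.

The sink converts dry-matter growth to CO₂ via CC_L·44/12 for dimensional
consistency with the emission terms; a flag accepts growth already
expressed in CO₂ units.

## Synthetic scenes and the oracle

The scene generator emulates the real inputs: scripted per-year truth
categories, category-consistent initial AGB (defaults 250/10/20/2/0
t DM ha⁻¹ with optional jitter), a static peat mask, region labels,
explicit fire events with fixed confidence (so regime branching is
deterministic), and daily 7-band reflectance built from disjoint
class signatures plus a shared seasonal sinusoid, Gaussian noise and a
cloud fraction of bad-flagged days. All randomness flows from named
substreams of one seed. What it does *not* emulate: mixed pixels,
spatially correlated cloud, class-dependent phenology differences,
sensor drift, or georeferencing error — so a perfect score on noise-free
scenes demonstrates the pipeline's internal consistency, not real-world
map accuracy.

`oracle_emissions` is a deliberately independent reference path: plain
Python per-cell loops, iterative (not closed-form) depletion sums, its own
run-merging and drainage bookkeeping. The vectorised pipeline fed truth
maps must agree with it component-wise to 1e-9 relative on twenty random
scenes; observed agreement is at machine precision (~1e-16).

## Problem sizes and defaults

Test and acceptance runs use 6×6 to 15×15 grids over 2–5 years, 8–24
observation days per year, 30–60 trees and ≤ 30 points per class — sizes
chosen so the full suite completes in well under a minute while still
exercising every code path (multi-fire depletion, repeated peat burns,
conversions, cloud gaps, both regimes). The accounting mathematics is
resolution-independent; scaling up changes runtime, not results.

## Known limitations

* Only CO₂ is accounted (no CH₄/N₂O), and only the AGB pool is carried as
  state — belowground and debris pools are fixed ratios of AGB, so a fire
  or conversion depletes them proportionally rather than independently.
* Fire-affected cells that also convert in the same year generate both
  burning and conversion emissions; the conversion is priced on the
  post-fire stock, which bounds but does not eliminate double counting.
* The drainage rule cannot distinguish drained from undrained non-forest
  on peat; emission factors are category proxies.
* Classification accuracy on small, isolated conversion patches is limited
  by the 9×9 neighbourhood features, which dominate the feature vector
  (152 of 228) and pull patch edges toward the surrounding class.
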