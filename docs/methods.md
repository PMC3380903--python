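# Methods

This note documents the models behind `rainsure`, the parameters that
matter, the numerical choices in the calibration, and what the synthetic
generators do and do not establish about real data.

## 1. Daily rainfall generator

Occurrence. A day is wet with probability `p_wet[month, h]`, where `h`
encodes the wet/dry history of the last `order` days (order 1–3, default
3; the most recent day is the least significant bit). Higher-order
chains are the standard device for tropical rainfall, whose convective
persistence a first-order chain understates. Years are 365 days; leap
days are irrelevant at the dekad scale. Each year consumes an
independent child stream of the master `SeedSequence` and starts from an
all-dry history, so year k is unchanged when more years are appended.

Amounts. Wet-day totals are gamma(shape, scale) with monthly parameters
(defaults shape 0.9, scale 13 mm → mean ≈ 11.7 mm, right-skewed, typical
of convective rain).

Canícula. Inside a configurable calendar window (default 15 July –
15 August) the wet probability is multiplied by a depression factor,
reproducing the mid-season dry spell that separates the primera and
postrera cropping seasons in Central America.

Fixture climates. `tropical_wet_season()` has a June–November rainy
season (wet-day probability 0.45 plus a persistence bonus of 15% per
recent wet day) and totals ≈ 350 mm over the default 8-dekad cropping
window — inside the 300–400 mm optimum for drybeans.
`droughty_wet_season()` (wet probability 0.32 → effective 0.42 with
persistence scaling, scale 12 mm, canícula factor 0.35) totals ≈ 295 mm,
just below the optimum, so most years are mildly stressed and the lowest
yield quartile carries substantial, variable deficits. These are study
conditions, not estimates of any station's climate; an earlier, harsher
draft (~190 mm/season) made a quarter of all years total crop failures,
which is not what a bean-growing region with droughty bad years looks
like, and was revised on realism grounds.

## 2. Soil-bucket crop model

Per dekad `i` with rainfall `R_i` on a soil with water-holding capacity
`W` and runoff fraction `f`:

    infiltration  I_i = R_i (1 − f)
    storage       S_i = min(S_{i−1} + I_i, W)        (excess drains)
    uptake        U_i = min(S_i, D_i)                 (stage demand D_i)
    supply        u_i = U_i / D_i  (1 if D_i = 0);  S_i ← S_i − U_i

and the season yield is

    Y = Y_pot · max(0, 1 − Σ_i w_i (1 − u_i))^γ · ε

with stage weights `w_i = D_i / Σ D` (unit sum, peaking at flowering/pod
fill), convexity `γ = 2`, and multiplicative lognormal noise `ε` (unit
mean, σ = 0.05, switchable off). Initial storage is 0.25 W at the window
start (10 days before sowing).

Why additive stress. The deficit index the calibration fits is a *sum*
of per-dekad shortfalls, so the crop stand-in must make yield loss
(approximately) additive across stage shortfalls — that is precisely the
dependence structure the index method presumes of a crop. A
multiplicative product of stage stresses was evaluated and rejected: a
product is not monotone in any sum of shortfalls, which caps the
achievable deficit–yield correlation well below what the method requires
and makes the fitted MWR profile unstable. The convexity exponent keeps
total-failure behaviour (an all-dry season yields < 5% of potential on
every default soil) while leaving the response near-affine under the
mild-to-moderate stress that dominates the calibration quartile.

Default demands `(0, 10, 10, 25, 40, 40, 40, 30)` mm/dekad for the
8-dekad window (pre-sowing dekad, establishment, vegetative, flowering,
pod fill, maturation; 195 mm net, ≈ 220–260 mm as rainfall after runoff)
for a 70-day cycle. A 9-dekad variant appends a zero-demand dekad.

Soils. Eight generics: textures sand/loam/clay-loam/silty-clay with deep
WHC 60/100/120/140 mm, shallow = half; runoff fraction
`min(0.6, base · (1 + 2·slope))` with base 0.03/0.07/0.12/0.16 and
default slope 0.3 (the region's steep hillsides). Heavier texture and
steeper slope shed more rain; shallower profiles buffer less. Values are
package defaults in the spirit of generic soil libraries, not
measurements.

Sowing. Either a fixed day of year or the contract's transparent onset
rule (first day preceded by k consecutive days each strictly over τ mm;
default k = 5, τ = 5). In grid simulations, years in which the rule is
never met inside the sowing window sow on the window's last day —
farmers must plant — while the rule function itself reports "no onset".
Rule-based sowing matters: it aligns the crop window with the arrival of
the rains, without which early-season storage carry-over is unexplained
by a rainfall-only index and depresses R² (a structural component of
basis risk, not an implementation artifact).

## 3. MWR calibration

Definitions. Dekad deficit `min(RAIN − MWR, 0)`; season total = sum;
rainfall index = Σ MWR. The lowest quartile is the ⌊n/4⌋ lowest-yield
years (stable input order breaks ties, with a warning); the initial MWR
heuristic is a per-dekad quantile (default median) of rainfall among the
top-quartile-yield years — good years bound the requirement from above.
Low quantiles give conservative vectors under which good years show
exactly zero deficit; the median is a better optimizer start.

Objective. Squared Pearson correlation between season total deficit and
yield over the lowest quartile, maximized subject to MWR ≥ 0. The
objective is piecewise smooth with kinks wherever an MWR entry crosses a
season's rainfall.

Level anchoring. The correlation is invariant to shifting a dekad's
deficits by a constant (e.g. raising an MWR entry already above every
season's rainfall), so the MWR *level* is not identified by R² alone —
unanchored search can drift to vectors under which every season,
including normal ones, is deep "in deficit", which inflates exceedance
probabilities and premiums into nonsense. The anchor is the method's own
premise that non-drought years carry no deficit: a candidate is
penalised (0.01 per mm) when the median total deficit of the seasons
*outside* the calibration quartile falls below −10 mm. A hard constraint
(MWR bounded by low quantiles of good-year rainfall) was tried and
rejected: good years contain individual dry dekads bridged by soil
storage, so the hard bound collapses the index. The reported R² is
always the pure squared correlation.

Optimizer. Gradient-free bounded search: Nelder-Mead restarted from a
diverse, seed-deterministic start set (the top-quartile heuristic at
quantiles 0.5/0.25/0.1, per-dekad rainfall quantiles of the calibration
subset, jittered copies), relaunched from the incumbent until it stops
improving, then a coordinate-wise polish that scans every breakpoint
interval (the 1-d kinks sit exactly at the subset's rainfall values) and
refines the best by golden section. Quasi-Newton with numeric gradients
stalls on the kinks and was abandoned. Tolerance 1e-8 on the objective;
up to 2000 simplex iterations per start. The returned objective is never
below the objective at the supplied start; ties go to the earliest
start.

Canonicalisation. At a solution, (a) entries above the subset's
per-dekad rainfall maximum are capped at that maximum (a pure constant
shift, correlation-invariant), and (b) entries that bind no season are
snapped to 0 — so dekads the data say nothing about get MWR 0, which
also resolves objective-equivalent plateaus deterministically.

Degenerate inputs. Fewer than 4 years, constant yields in the
calibration subset, or constant inputs to R² raise errors rather than
returning numbers.

Windows. The default calibration window is 8 dekads from day −10 to
day +70 relative to sowing; the packaged contract sheet spans 9 dekads
(days 1–90, a trailing zero-requirement dekad). Both conventions are
useful — the shorter window for calibration, the calendar-aligned one
for a printed sheet — so the window length is a first-class parameter
everywhere and neither is asserted as canonical.

## 4. Contracts and pricing

A season triggers when total deficit ≤ trigger (a negative mm value);
the indemnity is `rate · max(0, trigger − total)` — the deficit *in
excess of* the trigger, so a season exactly at the trigger is formally
triggered but pays zero (the sheet's "equal to or less than" wording and
its per-mm-after-the-trigger formula are both honoured; no minimum
payment is assumed). Payout is continuous at the trigger and
non-decreasing as any dekad dries.

Exceedance probabilities are empirical season fractions — no
distribution fit, no tail extrapolation. Fair premium = mean seasonal
payout (burn rate); offered premium = fair × (1 + loading), loading
defaulting to 0. Soil-averaged rows are arithmetic means over soils of
the probability and premiums. Deficits and triggers are stored as
negative millimetres throughout; currency is a tagged decimal with no FX
logic.

## 5. What the synthetic pipeline does and does not show

The generators provide data with the *structure* the method assumes:
persistence-driven tropical rainfall with a mid-season dry spell, and
yields whose loss is additive in stage water shortfalls with known
sensitivities. Under those conditions the pipeline demonstrably works:
the calibrated index reaches R² ≈ 0.75–0.95 on droughty deep-loam runs,
recovers the rank order of the true stage demands from noise-free data,
and orders soil risk (shallow sand needs indemnities at least as often
as deep silty clay, aggregated over weather streams).

Passing these checks does **not** show that real drybean yields are this
predictable from dekadal rainfall: real crops respond to temperature,
pests, management and within-dekad timing; real rainfall has spatial
gradients between farm and gauge (basis risk borne by the farmer); and
absolute yield levels here are arbitrary (potential 2000 kg/ha).
Occasional runs whose lowest quartile is only mildly stressed are
noise-dominated and calibrate poorly (R² ≈ 0.5–0.6) — droughty sites are
exactly where the index is sharp, and benign sites are where it is not.
Problem sizes in the tests and acceptance script (1–3 pixels, 2–8 soils,
30–99 years) were chosen as the smallest that exercise every code path
with stable statistics; the method itself has no scale assumptions
beyond ≥ 4 years per run.
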