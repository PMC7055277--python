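# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `odflow`, in the spirit of a model-documentation page.

## Gridding and the high-demand network

Endpoints are projected with an equirectangular map about a configurable
reference latitude (x = 111320·cos(lat_ref)·Δlon, y = 111320·Δlat metres)
and binned into half-open square cells of side `cell_side` (default 100 m),
indexed (row, col) from the south-west corner. The projection choice
matters little at city scale; what matters for reproducibility is that it
is fixed and documented. Great-circle distances use the haversine formula
with Earth radius 6371.0088 km; synthetic planar layouts use Euclidean
distances.

A cell is a *high-demand zone* when at least `M` trips arrive **and** at
least `M` depart (both boundaries inclusive). The filter is single-pass:
counts are computed on the full in-bounds trip set, the OD restriction is
applied once, and post-restriction degrees are allowed to dip below `M` —
re-iterating the filter would change the zone set and is deliberately not
done. Interval statistics on displacements use half-open intervals
[0, 1.8), [1.8, 20), [20, ∞) km throughout; descriptions of the local
interval sometimes close the right end at 1.8 km, and standardizing on
half-open intervals moves only the measure-zero boundary trips.
Self-loop trips (same origin and destination zone) are retained everywhere
and carry zone-level distance 0, so they count as local.

## Degree-distribution fitting

Degrees of high-demand zones are large integers (≥ the demand threshold),
so all five candidate models are fitted as *continuous* densities on
[k_min, ∞) by maximum likelihood; `k_min` defaults to 1000, the demand
threshold itself, and is not estimated by a KS scan. The stretched
exponential uses the profile likelihood λ̂(β) = n/Σ(kᵝ − k_minᵝ) with a
bounded 1-D search over β (tolerance 1e-8). The power law with exponential
cutoff maximizes its 2-D likelihood by Nelder–Mead over (γ, ln λ); its
normalization needs Γ(a, x) at a ≤ 0, computed by downward recurrence
Γ(a, x) = (Γ(a+1, x) − xᵃe⁻ˣ)/a from the positive region, with the a = 0
limit (E₁) substituted whenever |a| < 1e-6 to avoid catastrophic
cancellation (the neglected term is O(a), far below fitting noise). Near
γ = 1 the likelihood surface in γ is extremely flat; the fitter therefore
reports a profile-flatness diagnostic (likelihood drop at γ ± 0.05) rather
than pretending the exponent is determined to many digits.

Model comparison follows the standard heavy-tail workflow: KS distance as
goodness of fit, pairwise variance-normalized (Vuong) log-likelihood
ratios with two-sided normal p-values, a ranking by significant pairwise
wins (p < 0.1) with KS as tie-break. Bootstrap p-values for the KS
statistic are out of scope.

## Kernel estimation

Transition probabilities w = T_ij/k_i^out are paired with distances as
(log₁₀(d/d₀), log₁₀ w), d₀ = 1 km, for non-null w inside the default fit
window 0.1 km ≤ d ≤ 11 km (the lower bound excludes self-loops).

*Plateau.* c is the density mode of log₁₀ w over pairs with d ≤ R. The
plateau is treated as global even though each row has its own
normalization; the mode absorbs the spread, and per-row plateau estimation
is a non-goal. Consequence: c reflects the typical number of zones within
reach of an origin — a geometry property — so synthetic layouts cannot and
do not target any particular reference value of c.

*Decay.* each long-range pair is inverted through
β_ij = [c·ln10 + ln(R/d) − ln w]/(d − R), and β is the mode of the
resulting density. Pairs just beyond R produce huge |β_ij| outliers
(division by d − R → 0), which motivates the mode-estimation design below.

*Mode estimation.* `density_mode` is a linear-binned Gaussian KDE:
values are histogrammed onto a 1024-point uniform grid spanning the
0.5–99.5 percentile range padded by three bandwidths, convolved with a
Gaussian kernel using Silverman's bandwidth 0.9·min(σ, IQR/1.34)·n^(−1/5),
and the argmax of the smoothed density is returned. The percentile window
only sets the evaluation range (all values contribute); without it the
β outliers would stretch the grid and destroy mode resolution. A
histogram-peak fallback (`bandwidth_rule="histogram"`) skips smoothing.
Tests check the binned estimator against a direct dense-grid Gaussian KDE.

*Breakpoint selection.* Published analyses typically fix R by inspection;
`select_R` operationalizes that as a residual scan. Pairs are reduced to
per-bin medians of log₁₀ w on 44 uniform bins in log₁₀ d. For each
candidate R (default grid 0.5–5.0 km, step 0.1 km) a median-consistent
piecewise curve is fitted — plateau = median of log₁₀ w below R, decay by
least squares on the bin medians beyond R — and scored by the mean squared
residual over bins up to 2.5·R. The tail cap keeps the score focused on
the corner region where the breakpoint leaves its signature: bin medians
far beyond R drift systematically because long pairs over-represent
origins with small row normalizations, and without the cap that drift
biases the scan by about one grid step. Candidates lacking ten pairs
below R, four populated bins in (R, 2.5R], or yielding a negative decay
fit are skipped; ties go to the smaller R. The returned (c, β) are
re-estimated at the winning R with the density-mode estimator, which is
the package's primary kernel estimator.

On exact model matrices built on ≥ 400 uniform-random zones the scan
returns the injected R within one grid step and the mode estimator returns
β within a few percent (tested at ±10%).

## OD rank

The spectrum of W is computed densely (`numpy.linalg.eigvals`; intended
for N ≤ ~10⁴). Eigenvalue multiplicities are counted with tolerance 1e-8,
both against the value 1 and against the largest modulus, and strong
connectivity is cross-checked by component analysis of the positive-entry
pattern. The stationary vector uses power iteration (sup-norm tolerance
1e-12, at most 1e5 sweeps) with a dense left-eigensolver alternative; the
result is coerced real non-negative, normalized, and must satisfy
‖PW − P‖∞ < 1e-10. No damping or teleportation is added — a transition
matrix whose graph is not strongly connected fails loudly instead of being
patched, because a degenerate unit eigenvalue is a finding about the
network, not a numerical nuisance. The mean-field parameter q* uses the
closed form q* = [Σp² − ΣP∞p]/[Σp² − 1/N], p = k_in/𝒯; a uniform p makes
the problem degenerate (0/0) and is reported as such. q* is returned
unclipped, so values outside [0, 1] signal that the mean-field form fits
poorly.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:
zone layouts (lattice, uniform-random, or clustered Gaussian blobs),
heavy-tailed zone attractiveness sampled from the same degree models the
fitting stage supports, and destinations drawn from the truncated-Lévy
kernel with defaults R = 1.8 km and β = 0.15 km⁻¹ — the values fitted to
the reference taxi network — on an 800-zone, 14 km × 14 km default
geometry chosen to give a pair-distance range comfortably spanning the
0.1–11 km fit window. Attractiveness defaults are the reference in-degree
stretched-exponential (β = 0.708, λ = 4.138×10⁻⁵) or out-degree
power-law-with-cutoff (γ = 1, λ = 6.086×10⁻⁶) parameters with
k_min = 1000. The stretched exponential is sampled by inverse CDF,
k = (k_minᵝ − ln(1−u)/λ)^(1/β); the cutoff model by rejection with a
shifted-exponential proposal and acceptance ratio (k_min/k)^γ, with a
warning when the acceptance rate falls below 1e-3. Jitter places endpoint
coordinates uniformly within the half-open 100 m cell; timestamps are
synthetic sequential minutes (no stage uses time). Planar coordinates are
the default; a lon/lat mode wraps metres around a reference latitude so
the gridding stage can be exercised end to end.

What the generator does **not** emulate: street geometry, temporal demand
profiles, airport-like singular attractors (visible in real data as bumps
near 10 and 20 km that the kernel model deliberately does not capture),
and the true spatial arrangement of a city's high-demand zones. Passing
recovery tests therefore demonstrate correctness of the estimators under
the model's own assumptions, not fidelity of the model to any particular
city.

## Problem sizes and determinism

Default test and acceptance sizes — 800 zones for kernel recovery, 10⁵
degree samples, 200 zones for the spectral check, 10⁶ draws for
Monte Carlo frequency checks, 3×10⁶ trips for the sampled end-to-end
closure — were chosen so each check's sampling error sits well inside its
assertion band while the whole suite runs in well under a minute; the
sampled closure uses a ±20% band on the decay rate (versus ±10% on exact
matrices) because at that depth empirical log₁₀ w is visibly quantized by
integer trip counts. All stochastic components take explicit seeds
(`numpy.random.default_rng`); identical configuration and seed reproduce
byte-identical trip tables and pipeline outputs.
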