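# Methods

## Geometry and coordinate conventions

All positions live in an overhead-camera frame: origin at the tank's
top-left corner, x rightward, y downward, units cm. Headings are measured
from +x with positive angles toward +y, so 45° points right-and-down; the
two-branch arccosine formula used for trajectory angles is algebraically the
atan2 heading in this frame (verified by a property test). The default
arena is a 130 cm square with the reward chamber (9.5 cm diameter, 6.5 cm
door) at the end of an L-shaped tunnel of two equal 30 cm legs in the
top-left region, and two displacement vectors: lateral (+50, 0) and diagonal
(+50, +50) cm.

Model return paths are constructed *from the published per-strategy
constants* (PI 45°/38.6 cm; APC lateral 135°/38.6 cm; APC diagonal
180°/27.3 cm; RR 90° then a 90° turn, 54.5 cm split equally over two legs),
anchored at the displaced door — not re-derived from the shell/tunnel
coordinates, whose mapping onto the published global angles is not
recoverable from the arena description alone. Shell and tunnel coordinates
are kept for synthetic-data realism only.

## Trajectory comparison

Every observed-vs-model comparison follows one recipe: truncate both
polylines to the common arc length min(L_obs, L_model) (last partial
segment linearly interpolated), resample each at 1000 equal arc-length
stations, and average the 1000 pairwise Euclidean distances.

"Evenly spaced" is read as equal *arc length*, not equal time: model paths
have no timestamps, and arc-length spacing makes observed and model paths
commensurable. The resampling fits x and y separately with a
modified-Akima (shape-preserving piecewise-cubic) interpolant against
cumulative arc length. One numerical choice matters here: on very sparse
polylines (a 2-vertex segment, the 3-vertex RR L), a cubic through the raw
knots smooths direction changes at the scale of entire segments — a perfect
RR follower would score ~2.8 cm against its own model purely from corner
rounding. Knots are therefore refined to the station resolution (no segment
longer than L/999) before fitting, which confines the cubic smoothing to
below station scale and makes resampling polyline-faithful (an L-shaped
path keeps its arc length to <0.1%; a noise-free follower scores <1e-3 cm).
Consequences: interpolation is exact on straight runs, idempotent on
equal-spacing 1000-point paths, translation-equivariant exactly, and
rotation-equivariant to ~1e-5 cm (component-wise fitting is not exactly
rotation-symmetric).

Turn-back cropping: trajectories are first truncated to the 60 s analysis
window, then cut at the first run of 2 consecutive 1 s steps whose heading
lies within 30° of the bearing to the chamber *and* whose distance to the
chamber decreases. Cone width and persistence are exposed as parameters;
the values are our operationalisation of "oriented back to the chamber",
which the source protocol does not specify numerically. Cropped results
with fewer than 3 samples are rejected as degenerate.

## Random-trajectory null and classification

The null for a trial is built from 10,000 straight lines anchored at the
trial's release point (the same anchoring as the model paths), headings
uniform on [0°, 180°), length min(L_obs, L_PI). Because a straight line
resampled at equal arc-length stations is exactly the linear sweep
start + r_k·u, the null is evaluated in closed form and vectorised over
headings; a test asserts bit-level agreement with the explicit
generate → truncate → interpolate → score route.

Null summaries: a and b are the sample minimum and maximum of the 10,000
mean distances (the fitted-uniform interval is not otherwise identified);
SD_uniform = (b−a)/√12; SD_normal is the sample SD (ddof = 1); q20 the
empirical 20% quantile. The default decision rule accepts the argmin
strategy iff its mean distance < μ − SD_uniform; SD_normal and q20 rules
are available for sensitivity analysis. Exact distance ties (1e-9 cm)
break PI > APC > RR and are logged.

Instead of a per-fish GLMM of the 1000 point distances with model as both
fixed effect and random intercept — a specification that is degenerate as
stated — model separation is quantified by the argmin ranking plus a moving-
block bootstrap contrast of each pair of distance vectors (circular blocks
of 50 over the station index, 1000 resamples, percentile 95% interval),
which respects the strong serial dependence of neighbouring stations.

### Capture geometry and what RANDOM recall can reach

The rule's behaviour for straight swimmers is fully characterised by a
capture map: sweeping a straight trajectory over every heading shows the
μ − SD_uniform threshold accepts headings within roughly ±26° of the PI and
APC models (the L-shaped RR model captures almost no straight headings at
its longer common length). About half of uniformly headed swimmers
therefore land in a capture band, so RANDOM recall for uniform-heading
swimmers plateaus near 45–55% — the method is deliberately liberal toward
model assignment, and the acceptance suite documents (and currently fails)
a stricter 70% recall expectation rather than hiding it. Strategy-follower
recovery is unaffected (100% at κ = 50 in the shipped conditions).

## Axial circular statistics

Angles are axial (defined modulo 180°) and handled by doubling onto the
full circle throughout. The first straight angle accretes segments while
each deviates ≤ 10° from the immediately previous segment (not the running
mean); the y_end = y_1 tie in the branch formula resolves to the first
branch, its continuous limit. The Rayleigh test uses the standard series
approximation to the null of Z = nR̄²; it matches pingouin's implementation
to 1e-3 in p.

### Ten-model orientation family

The nested von Mises mixture family is fit by maximum likelihood on the
doubled angles: M1 uniform; M2A unimodal; M2B unimodal + uniform; M2C two
concentrations at one direction; M3A/M3B axial bimodal (second mode fixed
180° away) with equal/free weight; M4A/M4B axial with a second
concentration; M5A/M5B bimodal with free second mode. Two identifiability
constraints are imposed: the first component is the major one (λ ∈ [0.5, 1])
and the minor mode is no sharper than the major (κ₂ = r·κ₁, r ∈ [0, 1]).
Without them, rich members win the AIC ranking spuriously by placing a
tiny-weight, very-high-κ spike on a local clump of points. Each member is
maximised with L-BFGS-B from a moment-based start, warm starts embedding
every nested parent's optimum (guaranteeing the nested-likelihood ordering
to optimizer tolerance), and 10 random restarts; κ is bounded at 200 on the
doubled circle. Models are AIC-ranked; the "rt"-style statistic is reported
as the likelihood ratio of the best model against M1 with a χ² reference on
the best model's parameter count. Known limitation: at n = 200 the 2-unit
AIC margin still lets a 2–3-parameter member beat M1 on genuinely uniform
data in ~10–20% of replicates; selection rates are reported, not assumed.

## Group-level inference

Per-group metrics (first angle, start-end angle — axial degrees — and full
pre-turn-back path length) are tested against the published expectations.
The chooser codifies the source's practice: Shapiro–Wilk p > 0.05 selects a
one-sample bootstrap t (9999 replicates; null resamples of the
μ₀-recentred sample; p = (1 + #{|t*| ≥ |t|})/(reps+1), the +1 correction
chosen as the standard resampling estimator; degenerate resamples with zero
variance count as t* = 0 at μ₀ and are otherwise excluded), else a
signed-rank Wilcoxon (V = sum of positive ranks, zero differences dropped,
exact p for n ≤ 25 without ties). Groups smaller than 3 report raw values
only. Measured type-I error of the bootstrap t at α = 0.05, n = 8 is ~0.04.

Path length across the five groups (PI, APC split by displacement, RR,
RANDOM — the split that yields df = 4) uses Kruskal–Wallis, then pairwise
two-sample rank-sum tests with Holm adjustment.

Strategy choice is a multinomial logit (RANDOM reference) of age, swimming
speed, displacement type and trial number. With at most two trials per
fish, a fish-level variance component is not identifiable, so the
within-fish dependence is handled by cluster-robust standard errors; the
fit uses BFGS on internally standardised continuous covariates (slopes and
SEs are reported back on the original scale; the intercept row is the
log-odds at covariate means), with an L1-penalized fallback flagged on
separation or non-convergence.

The visual-acuity helper evaluates the published small-fish regression
acuity = 2.2957 + 1.225·(lens diameter, mm), valid below 10 mm.

## Synthetic cohorts

The generator emulates the study conditions: 1 Hz samples from the
displaced door, 60 s analysis window, 40 fish × two counterbalanced trials
(half the fish lateral-first), and strategy frequencies defaulting to the
reported 8 PI / 6 APC / 5 RR of 37 trials with RANDOM as the remainder
(the published per-label counts sum to 35 of 37; the generator closes the
gap in RANDOM). Strategy followers aim each second at the model-polyline
point one step ahead of their intended arc position, with von Mises heading
noise (default κ = 50, ≈8° SD) and Normal step lengths (fish speed mean,
1 cm/s SD); with noise off they land on the polyline exactly. The turn-back
toward the chamber is scripted after a set fraction of the model length
(default 1.0), giving the cropper a known ground truth. RANDOM swimmers run
a correlated walk (per-step turning κ = 6, ≈24° SD — a realistic wander for
a 3–5 cm fish) from an initial heading uniform on [0°, 180°), the
half-plane the door opens onto and the support of the random null; this
makes the axial first-angle distribution exactly uniform. Walls are
reflective (a fish cannot leave the tank) and reflections are logged.
Covariates: age ~ Normal(450, 150) days clipped at 120, speed ~
Normal(3, 1) cm/s clipped to [0.5, 8]; an optional multinomial-logit
assignment with stated coefficients supports recovery tests.

What the generator does *not* emulate — real fishes' pauses, wall-following,
thigmotaxis, variable click-digitisation error, or any emergent decision to
turn back — bounds what passing tests show: they validate the pipeline's
correctness and calibration under the stated model of the behaviour, not
the biological claims themselves.

## Problem sizes and determinism

Shipped analyses use the study-scale conditions directly: 10,000-line
nulls, 9999 bootstrap replicates, 1000-station resampling, 40-fish
cohorts; the calibration simulations use 500 null cohorts (type-I error),
20 replicates per selection scenario and 100 mode-recovery seeds. Every
stochastic stage takes an explicit seed; pipeline runs derive per-trial
child seeds deterministically from the run seed, and the run manifest
(config snapshot, seeds, input digests, stage parameters, version) is
sufficient to reproduce outputs bit-identically.
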