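# Methods

## Model

The package works at equilibrium with a hybrid feedback model of the
pituitary–thyroid axis: Michaelis–Menten kinetics in the feedforward path
(TSH stimulating thyroidal T4 secretion) and exponential/logarithmic
feedback inhibition (FT4 suppressing pituitary TSH release). The two
characteristic curves are

    TSH = S · exp(−φ · FT4)                  (inverted pituitary response)
    FT4 = K_T · TSH / (D_T + TSH)            (thyroid response)

with K_T derived from the thyroid's secretory capacity G_T and constants
for distribution, elimination and plasma protein binding of T4:

    K_T = α_T · G_T / (β_T · (1 + K41·[TBG] + K42·[TTR])).

We implement K_T and the deiodinase estimator

    G_D = β₃₁ · (K_M1 + [FT4]) · (1 + K30·[TBG]) · [FT3] / (α₃₁ · [FT4])

explicitly as fractions with the binding/clearance terms in the
denominator; this is the only reading consistent with K_T carrying
concentration units (pmol/L) and G_D a rate (nmol/s), and it matches the
SPINA model family from which the constants are taken.

Assumptions: steady state only (no ODE time courses); feedback acts through
FT4 alone (no separate FT3 feedback term — an extension of the model the
source literature itself leaves open); one individual is fully described by
(S, φ, G_T) on top of population-level binding/clearance constants; φ ≥ 0,
with φ = 0 admitted as a degenerate closed-form case.

## Units and constants

FT4 and FT3 in pmol/L, TSH in mIU/L, G_T in pmol/s, φ in L/pmol (implied by
sampled φ ranges of ~0.27–0.50 against FT4 in pmol/L), S in mIU/L, G_D in
nmol/s. Where captions in the source literature mix nmol/s and pmol/s for
G_T, everything is normalised to pmol/s — a three-orders-of-magnitude
typesetting inconsistency we flag rather than propagate.

The binding/clearance constants are not individual-specific and are shipped
as a named, fully overridable default set in `src/mimelog/data/
spina_defaults.cfg` (values from the SPINA literature): D_T = 2.75 mIU/L,
α_T = 0.1 /L, β_T = 1.1e-6 /s, K41 = 2e10 L/mol, K42 = 2e8 L/mol,
[TBG] = 3e-7 mol/L, [TTR] = 4.5e-6 mol/L, α₃₁ = 0.026 /L, β₃₁ = 8e-6 /s,
K_M1 = 500 nmol/L, K30 = 2e9 L/mol. Every operation takes the constants
explicitly, so no result depends on a hidden default. With these values
G_T = 3.43 pmol/s gives K_T ≈ 45.2 pmol/L and a euthyroid set point near
FT4 16 pmol/L / TSH 1.5 mIU/L, and SPINA-GD(15, 5) ≈ 30.8 nmol/s — all
inside the published physiological ranges. Count-type results (six
intersections; 75,000 cluster members) are invariant to the constant
values, since intersections exist and are unique for any positive set.
Unit conversions (pmol/L ↔ mol/L, K_M1 in nmol/L) are centralised in one
conversion layer in `estimators.py`.

## Set-point solver

The residual g(FT4) = FT4 − thyroid(pituitary(FT4)) is strictly increasing
with g(0) ≤ 0 and g(K_T) > 0, so the intersection is bracketed on [0, K_T]
and unique. We use Brent's method with an absolute FT4 tolerance of 1e-9
pmol/L by default (configurable); TSH* is then evaluated on the pituitary
curve, making the pituitary residual exact by construction. φ = 0
short-circuits to the closed form TSH* = S, FT4* = K_T·S/(D_T+S). A failed
bracket is impossible for valid positive parameters and is treated as an
internal error reporting the offending parameters. Tests cross-check the
solver against a pure bisection oracle and, in the TSH ≪ D_T regime, the
Lambert-W closed form FT4* = W(φ·K_T·S/D_T)/φ.

## Estimators

φ = ln(TSH₂/TSH₁)/(FT4₁−FT4₂) and S = TSH₁·e^{φ·FT4₁}. The printed source
form is ambiguous about which difference order pairs with which ratio; the
implemented convention is the one under which (a) the physiological inverse
relationship yields φ > 0 and (b) S evaluated at either time point agrees —
a documented convention, not a guess. Noisy real pairs can produce φ ≤ 0;
the value is returned with a quality flag (`non_physiological` / `flat`)
instead of an error, because the empirical φ distribution is itself a study
object. Equal FT4 at both visits makes the gradient unidentifiable and
raises an error at the estimator level; the cohort pipeline converts this
into a per-patient exclusion reason.

## Cluster simulation

The fixed-gradient design crosses a deterministic G_T grid with n_s random
draws of S and n_phi draws of φ (full Cartesian product — the design that
makes 50 × 50 draws on a 30-level grid yield exactly 75,000 points). Grid
semantics: "from 1.67 to 7.51 step 0.2" is built by index arithmetic
(low + k·step, no accumulation drift) and includes every lattice value
≤ high, giving 30 levels ending at 7.47 since 7.51 is not on the lattice —
the reading consistent with the 75,000 count. Draws violating positivity
(S ≤ 0, φ < 0) are rejected and redrawn. One top-level seed spawns
independent sub-streams per parameter, so changing n_s does not perturb the
φ draws.

The adaptive mode emulates set-point adaptation across the functional range
(as under LT4 treatment): each member's φ is a base draw (default
N(0.3, 0.08)) plus a monotone non-decreasing linkage in G_T. "Continuously
increased" is all the source states; we default to a linear ramp of the
mean from 0 at the grid minimum to +0.2 L/pmol at the grid maximum,
config-exposed so other monotone forms can be swapped in. Base draws are
per-individual by default (`phi_per_individual=False` shares them per
draw index) — the per-level alternative is configurable because the source
does not specify it.

`cluster_summary` reports marginal quantiles and the convex-hull area of
the (FT4, TSH) cloud relative to its bounding rectangle. This is a
deliberately qualitative descriptor of the kite shape; no formal bivariate
95% reference region is estimated.

## Cohort pipeline

Cross-sectional comparison: records are restricted to FT4 ∈ [10, 20] pmol/L
and TSH ∈ [0.1, 4.0] mIU/L (closed intervals — endpoint semantics are our
choice, the source does not state them), with carcinoma follow-up patients
excluded. Malformed rows are reported with row identity, never silently
dropped, and the filter is idempotent.

Longitudinal selection: per patient, the visit attaining maximum TSH and
the visit attaining minimum TSH are paired, each contributing its same-visit
FT4 — the reading of "maximum and minimum TSH and FT4 values" under which
the two-point φ estimator applies; ties break at the earliest visit. The
patient qualifies when the LT4 dose differs by ≥ 50 µg/day between the
selected visits and both TSH values lie in the measurable range, jointly
excluding small-perturbation patients and complete TSH suppression. Kendall
tau (φ vs mean FT4, φ vs mean TSH) and the two-group ln(TSH)-slope contrast
(OLS interaction term) are routine statistics delegated to scipy and
statsmodels; every reported statistic carries its n, and correlations are
reported as undefined below n = 5 or for constant columns. Weight-adjusted
dose is dose/weight in µg/kg/day.

An optional re-analysis path ingests externally supplied patient tables
(XLSX or delimited text) through a user-written column-schema map; its
absence never affects anything else. The pipeline reproduces the
computation on such tables, not any particular published statistic, since
those depend on the clinical dataset. Spreadsheet-interchange (DIF) files
are not read directly; convert them to CSV or XLSX first.

## Synthetic cohorts

The generator emulates the observational study structure: 268 euthyroid
controls, 170 LT4-treated patients with benign disease and 64 longitudinal
carcinoma follow-up patients (sizes configurable). Controls draw
(G_T, S, φ) from the healthy-population ranges (G_T 1.67–7.51 pmol/s,
S 100–600 mIU/L, φ 0.27–0.50 L/pmol) and sit exactly on their model set
points before noise; the treated group gets a steeper gradient
(φ 0.40–0.60) and an extended capacity range (3–14 pmol/s), displacing its
ranges, plus a dose (1.0–2.2 µg/kg/day) with deiodinase activity declining
in weight-adjusted dose. Longitudinal patients have two visits separated by
3–7 pmol/L in FT4 with a dose change driving the shift, and a constructed
decreasing φ–FT4 linkage (φ = 0.65 − 0.02·meanFT4 + jitter); 6 patients
with sub-threshold dose changes and 6 with completely suppressed TSH are
planted as known non-qualifiers for bookkeeping tests.

Measurement noise is multiplicative log-normal on TSH (σ = 0.05, the value
used throughout the two-visit recovery analyses) and additive Gaussian on
FT4/FT3 (sd 0.5 / 0.2 pmol/L); the real assays' error structure is unknown,
so these are stated assumptions, config-exposed, and `noise_scale=0`
reproduces exact set points. FT3 is generated by inverting the SPINA-GD
formula at the subject's deiodinase activity, so generated records are
internally consistent.

What passing tests on these cohorts show — and do not show: they verify
that the selection rules, estimators and statistics recover planted ground
truth under the stated noise model; they say nothing about assay-specific
error structure, within-patient autocorrelation, missingness patterns or
unmodelled FT3 feedback present in real clinical data.

## Problem sizes and determinism

Defaults used by the test suite and the acceptance script: the full
75,000-member cluster (solved in a few seconds), 1,000 random triples for
oracle agreement, 1,000 draws for parameter recovery, one n = 64
longitudinal cohort for linkage recovery and 100 null-cohort replicates for
the false-positive rate. All simulations are seeded; identical seeds give
bitwise-identical tables, and the CLI writes its resolved configuration and
seed next to every output.

## Known limitations

Equilibrium only — no dynamics, no TRH/hypothalamic tier, no FT3 feedback
term. The adaptive linkage form is an interpretation (any monotone form is
admissible). The kite-shape descriptor is a convex-hull heuristic, not a
probabilistic reference region. Real-data statistics depend on the clinical
dataset and are deliberately outside the test surface.
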