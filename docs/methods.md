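# Methods

## Dose-volume histograms and V-metrics

A differential DVH stores the fraction of structure volume `v_i` per dose
bin `d_i` on a uniform 0.1 Gy grid; the cumulative form stores the fraction
receiving at least each dose. Conversions are exact inverses: the mass
dropped by the cumulative curve between grid doses `d_k` and `d_{k+1}` is
assigned to `d_k` (the at-or-above convention), and arbitrary input grids
are reassigned mass-preservingly to the 0.1 Gy grid (conserved mass checked
to 1e-6). Round-tripping differential → cumulative → differential
reproduces the input to 1e-9.

V-metrics (V5–V25, percent of volume receiving ≥ 5–25 Gy) count whole bins
whose representative dose is ≥ the threshold, inclusive at equality. At
0.1 Gy resolution this differs from interpolated evaluation by at most one
bin (≤ 0.1 Gy of dose), and it keeps the hand-checkable semantics that a
bin sitting exactly at the threshold contributes fully. V5 ≥ V10 ≥ … ≥ V25
holds by construction.

Relative volumes are primary; the absolute structure volume (cm³) is
carried as metadata. CSV files are long-format UTF-8 with a required
header (`patient_id, structure, kind, dose_gy, volume_fraction` or
`volume_ccm`); parse errors report file line numbers.

## The LKB NTCP model

Each bin dose is first corrected to its 2 Gy/fraction equivalent with the
linear-quadratic model,

    LQED2_i = D_i · (1 + (D_i/e)/(α/β)) / (1 + 2/(α/β)),

where `e` is the phase's fraction count and α/β = 10 Gy for pelvic bone
marrow. `D_i/e = 2` makes the correction the identity to machine precision.
The DVH is collapsed to a generalized equivalent uniform dose,

    Deff = (Σ_i v_i · LQED2_i^(1/n))^n,

and the complication probability is the probit

    NTCP = Φ(x),    x = (Deff − TD50) / (m · TD50).

Φ is evaluated in closed form via `erf` (absolute accuracy ≤ 1e-12), not by
numeric quadrature of the defining integral. Default HT3+ parameters are
n = 1 (bone marrow treated as a fully parallel organ), m = 0.09,
TD50 = 30 Gy (95% CI 28–32 Gy).

Two notes on the published parameter set as printed:

- The slope CI appears as "0.4–0.3", which cannot contain the 0.09 point
  estimate — an apparent typographical error in the source. CI bounds are
  therefore treated as user-supplied values: they are sorted, a warning is
  emitted when a point estimate falls outside its CI, and nothing is
  silently "corrected" to a guessed value. `ntcp_interval` evaluates the
  model at the four (m, TD50) CI-endpoint combinations and returns the
  min/max, always widened to contain the point estimate.
- Whether the published parameters were fitted against fractionation-
  corrected or physical-dose Deff is not stated; the engine applies the
  LQED2 correction as specified above in all cases.

Two-phase conformal plans are combined by summing per-phase Deff values, as
the source analysis prescribes. Voxel-wise EQD2 accumulation would be
radiobiologically cleaner but requires registered dose grids that DVH-level
data do not provide; it is out of scope.

## Maximum-likelihood fitting

`LKBProbitModel` (a scikit-learn `BaseEstimator`) maximizes the Bernoulli
log-likelihood Σ[y log NTCP + (1−y) log(1−NTCP)] over (m, TD50) with n held
fixed. NTCP is clipped to [1e-12, 1−1e-12] inside the likelihood to avoid
log(0). Optimization is a derivative-free Nelder–Mead simplex from nine
grid-spread starts in the box m ∈ [0.01, 1], TD50 ∈ [5, 100] Gy
(quadratic penalty outside the box), with tolerance 1e-8 on the
log-likelihood; the best converged start wins and ties are broken by the
smallest m. All-0 or all-1 outcomes raise a non-identifiability error;
failure of every start raises a convergence error. 95% CIs are
profile-likelihood intervals (log-likelihood drop of 1.92, the 1-df
chi-squared criterion), found by bisection on the profile with the other
parameter re-optimized at each step; an interval hitting the search box is
truncated there.

On cohorts of 2000 with Deff ~ U(20, 40) Gy the fit recovers generating
parameters to within ±0.02 on m and ±1 Gy on TD50 averaged over 20 seeded
replicates (see `tests/test_acceptance.py` and `scripts/acceptance.py`).

## Blood counts and CTCAE grading

Weekly haemoglobin (g/dL) and WCC/ANC/platelets (×10⁹/L) are indexed by
week with week 0 as baseline. Ratios divide each week by baseline; nadirs
are minima over observed weeks (gaps skipped), with the earliest week
reported on ties; ratio-nadir × baseline equals the absolute nadir exactly.

CTCAE v4.0 cytopenia thresholds (strict `<` at every boundary, so a count
exactly on a boundary takes the milder grade):

| lineage | G1 | G2 | G3 | G4 |
|---|---|---|---|---|
| anemia (HgB) | < LLN–10.0 | < 10.0–8.0 | < 8.0 | — (see below) |
| leukopenia (WCC) | < LLN–3.0 | < 3.0–2.0 | < 2.0–1.0 | < 1.0 |
| neutropenia (ANC) | < LLN–1.5 | < 1.5–1.0 | < 1.0–0.5 | < 0.5 |
| thrombocytopenia (plats) | < LLN–75 | < 75–50 | < 50–25 | < 25 |

Default lower limits of normal: WCC 4.0, ANC 1.5, platelets 150, HgB 12.0
(female) / 13.5 (male); all configurable. Anemia grade 4 requires
life-threatening clinical criteria not derivable from counts, so the
maximum assignable anemia grade here is 3 — a documented limitation (the
underlying data also lack transfusion information). Baseline is never
graded; HT3+ is true iff any lineage reaches grade ≥ 3 at any observed
on-treatment week, and co-occurring lineages are reported separately rather
than merged into a combined "leukopenia/neutropenia" count.

## Statistical battery

All tests are two-sided. Group dose metrics are compared with the
Mann–Whitney U test — exact (full null distribution) when the smaller group
has ≤ 8 observations and the pooled sample is tie-free, otherwise the
normal approximation with tie and continuity corrections. Blood-count
nadirs are compared with Welch's unequal-variance t-test
(Welch–Satterthwaite df); the degenerate zero-variance case returns p = 1
for equal means and a floored p with an explicit note otherwise.

Regressions always include an intercept. Univariate panels fit one
predictor at a time; multivariate models combine the four covariates
(female, age, T3/4, node-positive; coded 1 for female/T3-4/node-positive)
with one dose metric per model — fitting all dose-metric levels jointly
would be hopelessly collinear (adjacent V-levels correlate near 1).
Logistic fits use Newton/IRLS (cap 100 iterations, tolerance 1e-10) and
raise an explicit separation error instead of reporting diverged
coefficients; inside the pipeline such fits appear as flagged rows with NaN
estimates. Exact fits report p = 1e-12 as a floor, never 0.

Multiple testing is controlled within families keyed by
(model, panel, group, structure, analyte, outcome kind): step-down Holm
(family-wise error) is the primary method because it is the named
procedure, and Benjamini–Hochberg (FDR at 5%) is reported alongside since
the source describes both; corrections never mix families.

## Synthetic cohort generator

The generator's defaults are the study conditions: 25 CRT and 21 IMRT
patients; covariates drawn with P(female) = 27/46, P(T3–4) = 23/46,
P(node+) = 19/46 (independently — the implied joint rates are close to the
reported ones) and age from a truncated normal, mean 66, SD 10, on
[44, 88] years.

**DVHs.** Per structure, the five V-levels are drawn from [0, 100]-truncated
normals with the published group means/SDs, coupled through a Gaussian
copula with a shared patient-level effect (cross-level correlation 0.7) so
metrics are realistically correlated, then projected onto monotone
orderings (V5 ≥ … ≥ V25) by pool-adjacent-violators. Two numerical
choices matter:

- The truncated-normal *location* is solved (Brent root-find) so the
  truncated *mean* equals the calibration target; naive `loc = mean`
  truncation would inflate means by several points where means are small
  relative to SDs (lumbosacral CRT).
- The monotone projection preserves the sum across levels but shifts
  individual level means where adjacent levels overlap heavily — up to a
  few percentage points at the outer levels of the most overlapping
  structures, under ~0.5 points for the well-separated whole-pelvis and
  IMRT tables. Calibration tests therefore use absolute tolerances
  (±1.5 points for the whole-pelvis V10 anchor, ±4 elsewhere).

The cumulative DVH is a piecewise-linear curve through 100% at 0 Gy, the
five drawn knots at 5–25 Gy, and a linear decay to 0 at the plan maximum
(50.4 Gy phase-summed for CRT; 55.9 Gy = 53.2 × 1.05 hotspot for IMRT),
converted to differential form at 0.1 Gy. The tail above 25 Gy is
unconstrained by the published tables, so this shape is a modelling choice;
cohort-level NTCP means are sensitive to it, which is exactly why printed
cohort NTCP values are not treated as reproduction targets. Conformal
plans are split into two phases (30.6 Gy/17 fx, 19.8 Gy/11 fx) by scaling
every bin dose proportionally; IMRT is one phase of 28 fractions.

**Bloods.** Baselines come from truncated normals on the published ranges
(SD back-filled as range/4 — an assumption, since the source prints ranges,
not SDs), with females shifted down (HgB −1.0 g/dL, WCC −0.8, ANC −0.7,
platelets −15 ×10⁹/L) to reproduce the reported gender association of
absolute nadirs without affecting ratios. Weekly counts follow

    count_w = baseline · clip(1 − S_a · g_w · ε, 0.05, 1.1) · η,

with suppression template g = (0.35, 0.7, 1.0, 0.95, 0.6) for weeks 1–5
(nadir at weeks 2–3, recovery at week 4), per-observation noise
ε ~ lognormal(0, 0.1), patient frailty u ~ lognormal(0, 0.15) inside
S_a, and a small dose-independent biological/measurement noise
η ~ lognormal(0, 0.03). Susceptibilities per percent V10:
S_wcc = 0.010 · iliac V10 · u, S_anc = 0.015 · (½ iliac + ½ lumbosacral)
V10 · u — the reported 1%/% (WCC) and 1–2%/% (ANC) iliac associations —
and, chosen from the published nadir-ratio magnitudes, S_hgb = 0.002 and
S_plats = 0.011 per percent iliac V10. The η term exists so counts vary
even at zero suppression (no real blood series is noise-free); without it
a null generator would produce constant ratios and type-I-error
calibration would be degenerate. All knobs are config-exposed.

**Outcomes.** HT3+ ground truth is a Bernoulli draw with probability
NTCP(whole-pelvis plan Deff) under the generator's LKB parameters, which
is what makes end-to-end parameter recovery a meaningful check. The
observed HT3+ flag used by the analysis is graded from the simulated
counts and need not coincide patient-by-patient with the latent truth.

A single `numpy` Generator is consumed in a fixed per-patient order
(covariates → DVHs by structure → bloods → outcome), so a fixed seed gives
bit-identical cohorts and byte-identical files.

**What passing tests do not show.** The generator emulates marginal
distributions and one plausible correlation structure, not anatomy: DVH
shapes between knots are linear, chemotherapy effects are absorbed into
the suppression template rather than modelled, and outcome counts at n = 46
are far too small to validate the NTCP model clinically. Recovery tests
demonstrate the *pipeline's* correctness, not the clinical truth of the
parameters.

## Pipeline

`run_comparison` validates the input schema up front (aborting with a
per-patient summary of missing structures/series), then emits: the
structure × level group comparison; the baseline/nadir blood summary with
Welch tests; the weekly-ratio table; the regression panels with Holm and
BH decisions; and the NTCP panel (per-patient Deff, NTCP, CI-endpoint
range; group means; Welch comparison of per-patient NTCP between groups —
the same test family used for the blood counts, since the source does not
name the test used for its NTCP comparison). Numeric output formatting is
fixed (`%.4g` tables, `%.6g` NTCP) and the manifest records seed, config
and library versions but no timestamps, so reruns are byte-identical. The
default cohort analysis completes in well under a minute; the five-minute
end-to-end budget is asserted in the acceptance tests.

## Known limitations

- V-metrics are bin counts, not sub-bin interpolations (≤ one 0.1 Gy bin
  of difference).
- The anemia lineage cannot reach grade 4 from count data alone.
- The generator's covariates are drawn independently; real T-stage and
  nodal status are correlated.
- Multivariate logistic models on 21–25 patients with a handful of events
  frequently separate; these appear as flagged rows, not estimates.
- The printed slope CI is kept as printed (sorted), with a warning, rather
  than guessed at.
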