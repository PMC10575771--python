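# Methods

## Effect sizes

For one study with patient summary `(x̄_p, S_p, n_p)` and control summary
`(x̄_c, S_c, n_c)`:

* `lnVR = ln(S_p/S_c) + 1/(2(n_p−1)) − 1/(2(n_c−1))`, sampling variance
  `1/(2(n_p−1)) + 1/(2(n_c−1))`.  The added terms remove the small-sample
  bias of the log sample SD.
* `lnCVR = ln[(S_p/x̄_p)/(S_c/x̄_c)]` plus the same bias terms.  Because SD
  typically scales with the mean in metabolite data, the CV ratio is the
  primary variability measure; `lnCVR − lnVR = ln(x̄_c/x̄_p)` exactly.
  Its sampling variance uses the independent-groups approximation
  `S_p²/(n_p x̄_p²) + 1/(2(n_p−1)) + S_c²/(n_c x̄_c²) + 1/(2(n_c−1))`,
  **without** a mean-SD correlation term.  This is an assumption, not a
  consequence of the estimator; it is recorded in the serialised
  provenance of every analysis.
* Hedges' `g = J·d`, `d = (x̄_p−x̄_c)/s_pooled`,
  `J = 1 − 3/(4 df − 1)`, `df = n_p+n_c−2`; variance
  `J²[N/(n_p n_c) + d²/(2N)]` with `N = n_p+n_c` (flag `var_method="df"`
  replaces `2N` by `2 df`).  Simulation at n = 20+20 puts the empirical
  variance of g within ~5% of this formula (the simulated/nominal ratio is
  reported by the acceptance script).

All logs are natural.  Extreme effect sizes are never winsorised; the
forest tables carry everything and heterogeneity statistics flag the
spread.

## Random-effects model

Study effects follow `y_i = x_i'β + u_i + ε_i`, `u_i ~ N(0, τ²)`,
`ε_i ~ N(0, v_i)` with known `v_i`.  τ² is estimated by REML.  The
restricted log-likelihood (constants dropped) is
`−½[Σ log(v_i+τ²) + log det(X'WX) + r'Wr]` with `W = diag(1/(v_i+τ²))`.
The maximiser is found by Fisher scoring (score
`−½tr(P) + ½y'P²y`, expected information `½tr(P²)`,
`P = W − WX(X'WX)⁻¹X'W`) wrapped in a safeguard: iterations maintain a
sign-change bracket on the score and fall back to its bisection whenever
the Newton proposal leaves the central 60% of the bracket.  Plain Fisher
scoring can zig-zag around the optimum with slow geometric decay on
near-null data; the safeguard converges in well under the 200-iteration
cap at tolerance 1e-10 (on τ², relative above 1).  Non-negativity is
enforced by projection; a boundary solution with negative score returns
τ² = 0.  Starting value: the (general-X) DerSimonian–Laird moment
estimate, also available as `method="dl"` for sensitivity analyses.

Given τ̂², β̂ is weighted least squares with `w_i = 1/(v_i+τ̂²)`;
inference is plain Wald z with 95% intervals at ±1.959964 — no
Knapp–Hartung adjustment, matching the reporting style of standard
random-effects software.  Heterogeneity:
`I² = 100·τ̂²/(τ̂² + s²)`, `s² = (k−1)Σw⁰ / [(Σw⁰)² − Σ(w⁰)²]`,
`w⁰_i = 1/v_i`.  I² is invariant to jointly rescaling all `v_i` and τ².

Under the null (τ = 0, μ = 0, k = 20, `v_i ~ U(0.01, 0.05)`) the pooled
z-test rejects at ~0.04: slightly conservative because τ̂² > 0 half the
time even when τ = 0, inflating the standard error.  The engine reproduces
`metafor::rma(method="REML")` to ten decimal places on a six-study
fixture (pooling and meta-regression), and matches a 1e-5-step grid search
of the restricted likelihood within 1e-4 on random small instances.

Subgroup (antipsychotic-naive vs medicated) comparisons use a Wald test
`z = (est_a − est_b)/√(se_a² + se_b²)` on disjoint study subsets, each
subgroup re-estimating its own τ².  Multiplicity over brain regions is
controlled by Benjamini–Hochberg step-up FDR at q = 0.10, applied per
outcome measure × metabolite × subset family (configurable); the flags are
recomputable from the exported p-values alone.

## Meta-regression policy

Primary moderators: combined mean age, proportion male, PANSS total, CPZ
dose — run per region × metabolite for lnCVR and g when at least
`min_k = 5` studies carry the moderator (records missing a moderator drop
out of that regression only).  Significant (p < 0.05) age or PANSS
regressions trigger a dispersion follow-up on the moderator's SD; regions
whose primary lnCVR pooling survives FDR get data-quality follow-ups on
the SNR and FWHM patient/control ratios.  The reported moderator
coefficient is the slope per unit moderator, with its own Wald z and p
alongside.

## Dip statistic and Monte-Carlo calibration

The dip of a sample is `min_G sup_x |F_n(x) − G(x)|` over unimodal CDFs G
(convex to the left of the mode, concave to the right, an atom permitted
at the mode).  On distinct sorted values `t_j` with ecdf heights `c_j` and
left limits `b_j`, a candidate mode `t_pk` admits a fit inside band d iff
(i) a convex function fits between the clipped bounds `max(c−d, 0)` and
`min(b+d, 1)` up to `t_pk`, (ii) a concave function fits from `t_pk` on,
and (iii) the smallest left-limit value achievable at the mode does not
exceed the largest mode value achievable from the right (support-line
envelopes through one upper- and one lower-clipped point).  The dip is the
minimum over modes, found by ordering modes by cheap greatest-convex-
minorant / least-concave-majorant lower bounds and bisecting the
feasibility test only where the bound undercuts the current best.  The
numba-compiled implementation was validated against direct LP minimisation
over piecewise-linear unimodal CDFs on thousands of random samples
(including heavy ties) to ~1e-12; the shipped tests repeat that comparison
for all sample sizes ≤ 8 at 1e-9.  Degenerate input: a constant sample
returns the lower bound `1/(2n)` by convention; `1/(2n) ≤ D ≤ 1/4` always.

P-values are Monte-Carlo: `p = (1 + #{D_null ≥ D})/(n_sim + 1)` with null
samples of the same n from Uniform(0, 1) — the same null behind the
classical dip tables — so the test is exactly calibrated for uniform data
(measured 0.053 at n = 100, n_sim = 999) and **conservative for
lighter-shouldered unimodal data**: normal samples of n = 100 reject at
~0.002.  A non-significant dip on normal-ish data is therefore weak
evidence, while a significant one is trustworthy.  Power at n = 200 for an
equal mixture of normals at ±3 SD exceeds 99%; a separation of 2 SD leaves
the mixture unimodal and the test correctly almost never rejects.  Null
dips are counted by a band-feasibility test at D directly (no bisection),
which makes the calibration loop ~100× faster than computing each null
dip exactly.  Default `n_sim = 2000`; the seed is mandatory and every
sub-seed (per-study tests inside `pool_and_test`) derives from it.

Multi-study pooling normalises each study by dividing by its mean
(default) or subtracting it; both schemes are reported when individual
data are supplied, since either reading of "mean-scaled" is defensible.
Cr-scaled and CSF-corrected data should be kept as separate strata (the
pipeline groups by `reference_scheme`).

## Synthetic data

`gen_study_level` draws, per study i, a true variability effect
`θ_i = φ + Σβ_m(m_i − m̄) + N(0, τ²)` and a mean effect
`δ_i = δ + Σβ_m(m_i − m̄) + N(0, τ²)` (moderator effects centred so the
population values stay φ and δ), then simulates actual normal individuals
(`CV_p = CV_c e^{θ_i}`, `μ_p = μ_c + δ_i σ_c`) and emits their sample
mean/SD/n — so summary noise has correct finite-sample behaviour and the
emitted table is exactly consistent with the stored raw samples.
Defaults: k = 60 studies, 15–60 per arm, control CV 0.15 around mean 10
(institutional units) with lognormal between-study scale spread
(`mean_log_sd = 0.3`), φ = 0.15, δ = −0.15, τ = 0.05, moderators drawn
from distributions typical of schizophrenia case-control samples
(age 31 ± 6, 66% male, PANSS 75 ± 15, CPZ 400 ± 150 mg/day).  Seeding is
counter-based (`default_rng([seed, i])`): adding studies never perturbs
earlier ones.  `gen_individual` draws patient values from a 1- or
2-component Gaussian mixture (components at `μ_c ± separation·σ_c/2`);
controls stay unimodal.

What the generator does **not** emulate: non-normal within-arm
distributions, reporting/publication bias, correlated moderators,
measurement error in the moderators, and shared-control dependence between
cohorts.  Passing recovery tests therefore shows the estimators are
correct under the model's own assumptions, not that real 1H-MRS data meet
them.

## Ingest conventions

Six canonical brain regions (MFC incl. anterior cingulate; DLPFC; frontal
white matter; thalamus; temporal lobe incl. hippocampus and STG; basal
ganglia incl. caudate/putamen/pallidum/nigra) via a versioned synonym
table; unknown labels raise — there is no catch-all bucket.  Control arms
shared by several clinical groups divide n by the number of groups,
keeping the fractional value by default because the `1/(2(n−1))` bias
terms are continuous in n (`rounded` mode rounds half-down, floor 2).
J-edited / EPSI acquisitions may be rescaled by 1000 or 100000 for
numerical comparability; all effect sizes are scale-invariant so this
never changes results.  Longitudinal studies contribute their first
timepoint; overlap de-duplication across publications is a curation
decision in the input table, not automated.  Every rejected row appears in
the rejects report with a reason.

## Problem sizes

Simulation-based checks use 200 replicates for parameter recovery and
power, 1000–4000 for type-I calibration, `n_sim = 999–2000` for dip
p-values, and 50 instances for the REML/grid comparison; these sizes give
Monte-Carlo standard errors comfortably inside the asserted bands while
keeping a full test run to about a minute of compute.

## Known limitations

* The lnCVR variance omits the mean-SD correlation term; with strong
  mean-variance coupling inside arms it is mildly conservative.
* No publication-bias diagnostics (funnel/Egger) and no multivariate
  handling of the dependence between metabolites or regions measured in
  the same cohort.
* The dip test's uniform-null calibration is conservative away from the
  uniform; calibration against a fitted unimodal null would be more
  powerful but is deliberately out of scope.
* Wald (not Knapp–Hartung) intervals can be slightly narrow at very small
  k.
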