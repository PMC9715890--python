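# Methods

## Problem and model

After esophagectomy for squamous cell carcinoma, nodal stage is assigned by
examining the harvested lymph nodes: pN0 if none is positive, pN+
otherwise.  A pN0 label can be wrong — the patient may harbor nodal disease
in nodes that were not harvested.  The package models this misclassification
under three assumptions:

1. there are no false node-positive calls; patients are pN+, true pN0, or
   false pN0 (occult disease, none of the examined nodes positive);
2. within a patient, every node is equally likely to be involved, so the
   chance of finding disease depends only on the number of nodes examined
   `e` (node-station anatomy is deliberately ignored);
3. within a T stage, the latent metastasis prevalence is common to all
   patients, so pN+ and false-pN0 patients share one involvement law.

Under (2)–(3) the positive-node count `m` of a node-positive patient is
binomial given a patient-specific involvement probability, and letting that
probability vary across patients as Beta(α, β) gives the beta-binomial

    P(m | e) = C(e, m) · B(α + m, β + e − m) / B(α, β).

The binomial coefficient is kept (the pmf must normalize for simulation);
it is constant in (α, β), so estimation and the `m = 0` case are unaffected
by its presence.

The chain of derived quantities, per T stage:

* false-negative probability `P(FN | e) = B(α, β + e) / B(α, β)` — the
  pmf at `m = 0`; strictly decreasing in `e`, equal to 1 at `e = 0`;
* expected false negatives at each observed `e`:
  `FN_e = min(P(FN|e) · TP_e / (1 − P(FN|e)), N_e)`, where `TP_e` counts
  pN+ patients (including those with every examined node positive) and
  `N_e` counts pN0 patients; the cap enforces `FN_e ≤ N_e`.  `FN_e` is kept
  as a real number — rounding to whole patients would break monotonicity of
  the downstream quantities;
* adjusted prevalence `rate = (ΣFN + ΣTP) / (ΣN + ΣTP)`; the denominator is
  the stratum size, so adjusted ≥ raw always;
* nodal staging score
  `NSS(e) = (1 − rate) / ((1 − rate) + rate · P(FN | e))` — Bayes' rule
  with the adjusted rate as prior; equals `1 − rate` at `e = 0` and
  increases strictly to 1;
* adequate harvest: the smallest `e` with `NSS(e) > 0.90` (strict
  inequality; a `strict=False` flag gives ≥).  The search runs over
  `e = 0..e_max` (default 200); an unattainable target returns the score at
  `e_max` flagged as such, and a prior already above the target returns 0
  with a warning.

## Fitting

Only node-positive patients enter the fit, and patients whose examined
nodes were all positive (`m = e`) are excluded first — they would always
have shown more positives with a larger harvest and carry no information
about the negative fraction; they remain in the `TP_e` tallies.

The fitting sample is thereby conditioned on `m ≥ 1`, so the likelihood is
the zero-truncated beta-binomial, `P(m|e) / (1 − P(0|e))`.  This matters:
maximizing the plain likelihood on pN+-only data overstates nodal
involvement (zero draws are never observed), which understates `P(FN)` and
leaves the adjusted rate short of the true prevalence — an asymptotic bias
of ~0.03 in prevalence under realistic settings, measured on the package's
own generator.  The truncated fit removes it; the plain objective remains
available (`truncated=False`) for comparison with earlier staging-score
implementations.

Optimization runs in (log α, log β) space (L-BFGS-B with the analytic
digamma gradient; Nelder-Mead fallback if the line search fails), started
from method-of-moments estimates on the `m/e` fractions clipped to
[0.01, 100], bounded to log-shape ∈ [log 1e-4, log 1e4], objective
tolerance 1e-12.  Non-convergence is reported (`converged=False`), never
silent.  An exhaustive log-spaced grid search over the same objective
(`grid_search_mle`) serves as a brute-force cross-check in the tests and in
the fitting driver.  Fewer than two informative pairs raises a fit error
suggesting stratum pooling rather than returning a degenerate fit.

All pmf and beta-function arithmetic is done in log space via
`scipy.special.gammaln`/`betaln`; log-likelihoods that overflow return a
large negative sentinel instead of −inf so optimizers never see NaN.

## Uncertainty

Percentile bootstrap, 95 % by default: patients are resampled with
replacement within each T stratum — pN0 and pN+ jointly, preserving the
stratum size — and the entire chain (truncated fit, false-negative
estimates, adjusted rate) reruns on each replicate, so shape and rate
uncertainty propagate coherently and the increase (adjusted − raw) is
computed jointly per replicate rather than by interval arithmetic.  A
master seed spawns one `SeedSequence` substream per replicate; results are
bit-reproducible and independent of evaluation order.  Replicates whose fit
fails are dropped and counted; above 10 % failures the run aborts.
Percentile intervals can exclude the point estimate on skewed statistics
(the shape parameters especially); this is warned about, not hidden.

## Synthetic cohorts

`simulate_cohort` draws, per patient: latent nodal status
Bernoulli(prevalence); examined-node count from a shifted negative binomial
(support ≥ 1; mean `mu`, dispersion `k`), uniform, or empirical weights;
and, for latent positives, `m` from the beta-binomial via its beta-mixture
representation.  Latent positives with `m = 0` are exactly the
false-negative pN0 patients, so `P(FN)` and `1 − NSS` are exact on the
generator by construction — the end-to-end tests exploit this.  A
`zero_truncated` convention (resampling until `m ≥ 1`) is provided for
sensitivity checks; it generates no false negatives.

Survival is exponential with independent exponential censoring; the hazard
is selected by the *latent* status (defaults 0.008/month for truly
node-negative, 0.025 for node-positive, censoring 0.015 — five-year
disease-specific survival of roughly 60 % vs 20 %), so occult disease
worsens survival among observed pN0 patients.  That is the mechanism the
survival validation must detect, and the simplest one that produces it.

Preset populations: `seer-like` (strata 210/238/551/271, examined-node
median ≈ 12, IQR 6–19) and `institution-like` (150/288/515/451, median ≈ 19,
IQR 12–26), emulating a US registry extract and an East-Asian institutional
series of resected esophageal squamous cell carcinoma.  Latent prevalences
are the corrected rates such cohorts exhibit (0.243/0.402/0.512/0.706 and
0.269/0.500/0.611/0.676); each preset's shape pairs were solved once so
that prevalence × (1 − mean P(FN)) under its examined-node distribution
reproduces the populations' observed raw rates (e.g. 0.186 for T1 and
47.1 % overall observed positivity in the institutional preset), with a
median of 2–3 positive nodes among observed pN+ patients.  The resulting
P(FN) curves are similar across T stages — per-node involvement varies much
less with tumor depth than prevalence does.

What the generator does *not* emulate: nodal-station anatomy and
location-dependent yield, covariate effects (grade, size, neoadjuvant
therapy) on prevalence or involvement, non-proportional or non-exponential
hazards, and registry artefacts (missing counts, heaped node numbers).
Passing tests therefore show the estimators are correct *under the model's
own assumptions*, not that the assumptions hold in real cohorts.

## Validation by survival

pN0 patients are scored `NSS(e_i)` with their stratum's adjusted rate and
grouped by pooled sample quartiles (a within-stratum flag is available;
pooling is the default since the score is already stratum-adjusted).  The
score takes one value per `e` within a stratum, so ties are common; values
at a cut go to the lower group deterministically.  Kaplan–Meier estimation
and the multi-group log-rank test come from `lifelines`; the tests verify
them against a direct product-limit computation.  At registry-scale cohort
sizes (~800 scored pN0 patients) and realistic hazard contrast the quartile
separation is directionally consistent but not always significant; the
dedicated validation tests use a clearly hazard-separated cohort
(hazard ratio ≈ 7.5) at n = 2000, where separation is reliably detected.

Cox regression and spline analyses of score–hazard shape are validation on
covariate-rich real data and are out of scope here; the model-free
Kaplan–Meier/log-rank check is the part a synthetic cohort can exercise.

## Numerical and design notes

* Cohort tables are CSV with a header; a `column_map` adapts registry-style
  headers.  Records with `nodes_examined = 0` are rejected at read time —
  `P(FN | 0) = 1`, such patients carry no nodal information.  Row-level
  diagnostics accompany every validation failure.
* Rates are kept at full precision internally; rounding to 3 decimals (or
  one decimal in percent) happens only at presentation.
* T4 is one stratum; published stage tables at this granularity do not
  split a/b.
* The adequacy threshold uses strict `>` to match the "over 90 %" reading;
  at the printed precision of published thresholds the distinction rarely
  moves the answer by more than one node.
* Published sources of this kind disagree internally on some tallies (text
  vs table patient counts; in-text vs tabulated adequate-harvest numbers,
  e.g. 12/25/30/45 in prose vs 11/24/33/41 tabulated for one cohort).  The
  package asserts only quantities that are arithmetically determined by
  published stratum counts and otherwise validates against its own
  generator, where the truth is known.
* Problem sizes in the test suite — 500–2000 fitting pairs for recovery,
  10 000 patients per stratum for end-to-end consistency, 100 × 200
  bootstrap replicates at n = 2000 for coverage — were chosen as the
  smallest scales at which the Monte-Carlo error is comfortably inside the
  asserted tolerances.
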