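# Methods

## Dose-response model and fitting

Curves are modeled with the four-parameter log-logistic sigmoid
`y(x) = A_max + (A_min − A_max)/(1 + (x/EC50)^Hill)` on percent-inhibition
responses. The Hill slope is constrained to (0.1, 10]: the sign convention
(inhibition rising with dose) implies a positive slope, and the upper bound
prevents step-function degeneracy. Fitting is bounded nonlinear least
squares (scipy's trust-region reflective) on the internal parameterization
`(A_min, A_max, log10 EC50, log Hill)`; the log scales stabilize the very
different magnitudes of EC50 (nM, spanning decades) and Hill.
Initialization: asymptotes at the measured extremes clipped into their
boxes, EC50 at the tested concentration whose response is nearest the
mid-response level, Hill at 1. `log10 EC50` is allowed 3 decades beyond the
tested range on either side, so out-of-range potencies can be expressed
(and later censored) rather than clamped at the boundary.

Asymptote boxes for the flexible (EC50-model) fit are
`R_min ≤ A_min ≤ 0` and `min(0, R_min) ≤ A_max ≤ max(100, R_max)` with
`R_min`/`R_max` the extreme measured responses. When every response is
positive the `A_min` box collapses to the single point 0 and the parameter
is held fixed (general rule: any box narrower than 1e-9 pins its parameter
at the midpoint, since the optimizer requires strict bounds). A consequence
worth knowing: a true lower asymptote below the smallest *measured*
response is unreachable by construction, so exact noiseless recovery of
`A_min` holds only for `A_min = 0` truths; the recovery tests reflect this.

### Completeness test and refit rules

The upper bend level of the sigmoid is
`(A_min − A_max)/(1 + 4.6805) + A_max`, attained at concentration
`EC50 · 4.6805^(1/Hill)` (a closed-form identity the test suite asserts to
1e-9 relative). A curve is complete when at least two measured
concentrations exceed that bend concentration — i.e. the data actually
resolve the upper plateau. The bend rule is stated as a response level but
applied in concentration units via the model inverse; this reading is
dimensionally coherent and reproduces the `4.6805 × EC50` bend
concentration for Hill = 1.

EC50-model pipeline: (1) flexible fit (curves with fewer than five distinct
concentrations skip this underdetermined stage); (2) if incomplete, refit
with `A_max = 100` — the data cannot estimate the upper asymptote, and 100%
inhibition is the only principled fallback; (3) if the surviving fit's
amplitude is below 30 (percent), refit with `A_max = 100` so that assay
noise is not interpreted as a genuine low-amplitude response. The amplitude
rule is evaluated after the completeness refit, on whichever fit survived
it; since the completeness refit already pins `A_max = 100` (amplitude
≥ 100), the amplitude refit can only fire on a surviving flexible fit.
This ordering is a documented choice; the rules are idempotent under it.
Non-convergent fits are flagged and excluded from metric tables rather than
given sentinel values — capped sentinels are exactly the artifact the
adjusted metric exists to avoid.

The IC50 model fixes `A_min = 0`, `A_max = 100` (two free parameters,
minimum three distinct concentrations). The residual standard error is
`sqrt(SSR/(n − p))` with `p` the number of free parameters of the final fit
(4, 3 or 2), undefined for saturated fits (`n ≤ p`).

## Metrics

EC50/IC50 estimates exceeding the maximal tested concentration are recorded
as `+Inf` (one-sided censoring: values below the minimal tested
concentration stay finite, matching the asymmetry of the completeness
problem). The AUC is the ratio of grid sums given in the README over a
*linear* concentration grid with both endpoints included (last interval
clamped); default step 1 nM. The linear grid is deliberate: it weights
high-concentration windows in proportion to their width in nM, which is
exactly the mechanism by which differing top concentrations skew the
unadjusted AUC — and what the shared-window adjustment removes. The
normalization by `max(A_max, 100) − A_min` keeps AUC in [0, 1] even for
overshooting fits. Grid-sum values converge to the Riemann integral as the
step shrinks (asserted against the Hill = 1 closed form to 1e-4); the 1 nM
default is a documented discretization convention, configurable via
`grid_step`.

## Harmonization

Drug/cell-line names are canonicalized (uppercase, non-alphanumerics
stripped, optional synonym table) before matching. Each study's
representative dose window per drug is its *modal* per-curve tested range
(ties toward the larger top concentration, then the wider span) — studies
occasionally run one drug over several dilution series, and the modal rule
resists that ambiguity without per-pair bookkeeping. The drug's shared
range is the intersection of the studies' modal ranges; drugs present in
one study only, or with disjoint ranges, are reported as incomparable and
skipped. Every curve of a comparable drug is scored over the shared range —
including cell lines screened by a single study, so pooled analyses keep
their full breadth — and per-(drug, cell line) adjusted values are averaged
across studies. Curves whose own tested window does not cover the shared
range are still scored from their fitted model but flagged `extrapolated`
for auditability.

## Concordance

Potency metrics are compared on their finite subset (a censored value on
either side drops the pair); AUC metrics are never censored. Point
estimates are scipy's Pearson/Spearman (average ranks for ties).
Uncertainty is a percentile bootstrap 95% CI on Pearson's r (resampling
pairs with replacement; constant resamples excluded) and a permutation
p-value — the fraction of side-permutations whose |r| reaches the observed
|r|, floored at `1/(n_resample + 1)`; default 1000 resamples, all driven by
an explicit seed. Correlations are not reported on fewer than three pairs
or zero variance; such groups are emitted as no-value results with a
reason. Per-drug results carry the drug-class annotation ("unclassified"
when absent), the strict `moderate` flag (r > 0.5), and a `best_metric`
flag on the metric with the highest r for that drug and study pair.

## Synthetic screens

The generator emulates several studies screening the same drug/cell-line
panel under different serial-dilution designs. Defaults: an 8-point
half-log series to 8 µM, a 9-point two-fold series to 2 µM (bottom
7.8125 nM) and a 16-point two-fold series to 66 µM — the dose layouts of
the large public screens this package targets. Ground truth per (drug,
cell line): activity class with proportions 0.30 cytotoxic / 0.45
cytostatic / 0.25 inactive (targeted-therapy panels are dominated by
cytostatic and inactive responses; the exact mix is a modeling choice),
`A_max` of 100, U[30, 90) or U[0, 30) respectively, `A_min = 0`,
`log10 EC50` uniform on [0.5, 4.5] (≈3 nM–32 µM, spanning all three
windows), and `Hill = exp(N(0, 0.3))` clipped to (0.1, 10]. Noise is
homoscedastic Gaussian on percent inhibition, sd 5 by default, unclipped
(raw screens under- and overshoot); with it, fitted residual standard
errors land in the upper single digits, the scale reported for real
screens. An optional per-study additive bias (default 0) emulates assay
offsets that no bioinformatic adjustment can remove.

The generator draws classes independently per (drug, cell line) and models
no growth-rate confounds, plate/edge effects, heteroscedasticity, or
drug-level correlation structure across cell lines. Passing tests
therefore show that the *method* behaves as designed under its stated
noise model, not that any particular real dataset will reach the same
agreement levels.

## Analysis sizes

Default analysis sizes used by the test suite and `scripts/acceptance.py`
are the package's own choices for routine desk-scale runs: the showcase
pipeline uses 10 drugs × 40 cell lines × 3 designs; the adjusted-vs-
unadjusted win rate uses 10 independent simulations of 8 drugs × 30 cell
lines; recovery and residual-error checks use 100–300 curves. The
adjusted-AUC advantage on wide-design pairs is decisive at these sizes
(pooled r ≈ 0.99 adjusted vs ≈ 0.82–0.94 unadjusted), so larger panels add
runtime, not information.

## Known limitations

* No weighted regression, outlier rejection, or biphasic/bell-shaped
  models; replicates enter as separate least-squares points.
* The modal-range rule is one convention for studies with several dose
  series per drug; per-pair curve intersections are a defensible
  alternative with different edge behavior.
* Pooled averaging weights studies equally regardless of their replicate
  counts or noise levels.
* Identifier canonicalization is purely lexical; genuinely different
  entities with colliding names (or synonyms absent from the table) must be
  resolved by the caller.
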