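# Methods

## The response framework

RECIP 1.0 grades treatment response in metastatic castration-resistant
prostate cancer (mCRPC) from paired PSMA PET/CT scans — a baseline scan
before therapy and an interim scan at about 12 weeks. Two quantities enter:
the percent change in total PSMA-positive tumor volume (PSMA-VOL, mL,
summed over all segmented lesions), and a binary consensus call for the
appearance of new lesions. The four categories are

| Category | Definition |
|---|---|
| CR | no residual PSMA-ligand uptake on the interim scan |
| PR | volume decline ≥ 30% without new lesions |
| PD | volume increase ≥ 20% with new lesions |
| SD | everything else |

SD deliberately absorbs the two *heterogeneous* patterns — a volume decline
accompanied by new lesions, and volume growth without them — because their
survival separates from both true responders and true progressors.
Thresholds are inclusive (a change of exactly −30% is a response), matching
the convention used for the PSA thresholds; a strict variant is available
behind the `inclusive` flag of `VolumeCutoffs`.

PSA response follows PCWG3: ≥ 50% decline is a response, ≥ 25% increase is
progression. The composite PSA+RECIP endpoints are two *independent* binary
indicators: responder = PSA response OR RECIP-PR/CR; progressor = PSA
progression OR RECIP-PD. A patient meeting both definitions keeps both
flags; no precedence is defined, and downstream analyses treat the two
endpoints separately.

`baseline_vol = 0` is rejected rather than special-cased: a patient
entering therapy has measurable disease, and percent change is undefined at
a zero baseline.

## Cutoff development

The ±10/20/30/40/50% candidate thresholds are evaluated per direction by
binarizing the cohort (meets the candidate vs not; the unfavorable side
carries the higher risk score) and computing Harrell's C-index of that
indicator against overall survival. Per direction the maximal C-index wins;
candidates within `tie_tolerance` (default 0.005 C-index units — "similar
prognostic value" has no published numeric definition, so it is a
configurable parameter) of the maximum are treated as tied and resolved
toward the **larger magnitude**, which is more robust to measurement error
and biologic variability of tumor-volume quantification. Candidates that
split off an empty group are kept in the table with an undefined (NaN)
C-index rather than silently dropped.

## Survival statistics

* **Kaplan-Meier** — product-limit estimator (via lifelines). The median is
  the earliest time the curve reaches 0.5; its 95% CI inverts the log-log
  (exp(−exp)) transformed Greenwood interval at 0.5. The method name is
  recorded on the result object since published analyses rarely state it.
* **Cox regression** — univariate only, Efron tie handling (via lifelines).
  Monotone partial likelihoods (perfect separation) raise
  `ConvergenceError` instead of returning a diverged coefficient; the
  heuristic flags a non-finite or absurdly large standard error.
* **Harrell's C-index** — implemented in-package. An ordered pair (i, j) is
  usable iff i dies strictly before j's follow-up ends, or i dies exactly
  when j is censored; pairs of deaths at identical times carry no ordering
  information and are excluded. Tied risk scores score 1/2. These rules
  agree exactly with `sksurv.metrics.concordance_index_censored` and
  `lifelines.utils.concordance_index`, which the tests use as independent
  cross-checks alongside an O(n²) pair-enumeration oracle.
* **Correlated C-index comparison** — for two risk scores on the same
  subjects, `compare_cindex` estimates Var(c_a − c_b) from per-subject
  influence values `(s_k − c·n_k) / M` (s_k = subject k's pair-score sum,
  n_k its usable-pair count, M the total), i.e. an infinitesimal-jackknife
  covariance that keeps the correlation induced by scoring the same
  patients twice. A two-sided normal approximation gives p. Identical pair
  orderings give a degenerate variance and p = 1 with a warning. The
  estimator tracks an exact delete-one jackknife (test-verified) and its
  type-I error under a two-noise-predictor null at n = 200 sits at
  0.05–0.07 over 1000 replicates.

Categorical predictors map to ordinal risk (CR < PR < SD < PD) for the
RECIP C-index; binary endpoints use the indicator itself (oriented so the
unfavorable state has higher risk).

## Reader consensus and agreement

Clinical consensus sessions cannot be re-enacted in software; the default
surrogate is a majority vote over an odd number of readers (policy recorded
in cohort provenance; `unanimous-positive` is available as a conservative
alternative). Fleiss' κ is computed on the binary new-lesion call with
chance agreement from pooled category marginals (statsmodels backend).
When every rating falls in one category the denominator vanishes; the
result then reports κ as undefined while still returning the full-agreement
fraction of 1.

## The synthetic cohort

No patient records ship with the package; the generator emulates the
statistical structure the analyses assume, with defaults chosen to mirror a
124-patient Lu-PSMA-treated mCRPC population:

| Parameter | Default | Meaning |
|---|---|---|
| `class_probs` | (0.42, 0.22, 0.36) | latent responder/stable/progressor mix (volume-category proportions) |
| `vol_change_loc`, `vol_change_scale` | (−50, 0, +60), 25 | per-class percent-change normal, truncated at −100% |
| `nl_probs` | (0.31, 0.59, 0.89) | new-lesion probability per realized volume category |
| `median_os` | (21.7, 13.1, 8.3) mo | exponential median OS per RECIP category (PR/SD/PD) |
| `censor_rate` | 0.10 | expected administratively censored fraction |
| `reader_error` | 0.08 | per-reader flip probability vs the latent new-lesion truth |
| `psa_corr` | 0.70 | probability the PSA category matches the latent volume class |

Survival is drawn directly from the realized RECIP category (not from a
continuous latent hazard): that is exactly the structure the prognostic
claims test, and it makes the configured medians exact recovery targets.
New-lesion flags are drawn conditional on the realized volume-response
category for the same reason — the published per-category rates are then
recovered by construction rather than diluted through class/category
mismatch. Censoring is administrative and independent of everything:
censoring times are Uniform(0, horizon), with the horizon solved
numerically from the config's analytic category mixture so the expected
censored fraction equals `censor_rate`. (An earlier draw of the censoring
time uniform on (0, T) is *informative* — it preferentially removes
short-lived subjects early and biases Kaplan-Meier medians upward by ~8% —
and was rejected.) `weibull_shape` ≠ 1 switches the survival law to
Weibull for robustness experiments; medians remain exact.

Each patient draws from a `(seed, patient-index)` substream, so a cohort
extends without reshuffling. With the defaults the generator reproduces,
without further tuning, an inter-reader κ of ≈ 0.69, full three-reader
agreement in ≈ 77–79% of patients, ≈ 58–60% of patients with new lesions,
and per-category KM medians within a few percent of (21.7, 13.1, 8.3)
months.

What the generator does **not** emulate: lesion anatomy and disease-site
distributions, tracer kinetics, PSA kinetics beyond a single banded percent
change, dependence of censoring on enrollment date, or any treatment-cycle
dynamics. Passing recovery tests therefore demonstrates the correctness of
the statistical machinery under the stated generative assumptions, not
clinical validity on real data.

## Voxel-level layer

`psma_vol` is labeled-voxel count × voxel volume (mm³ → mL); segmentation
itself is out of scope and label maps are consumed from external tools or
from the built-in Gaussian-blob phantoms. An interim lesion is *new* iff no
baseline lesion centroid lies within `match_radius` (default 15 mm — expert
visual matching has no published algorithmic counterpart, so the radius is
explicit) and its SUVmax exceeds a caller-supplied reference-region mean
SUV; the reference region (e.g. liver) is deliberately a parameter because
the clinical criterion does not pin it down.

## Problem sizes and numerical notes

Monte Carlo checks run at the sizes stated in the tests: pair-enumeration
oracles at n ≤ 30 (100 cohorts), Cox recovery at n = 2000 (100
replicates), null calibration of the correlated-C test at n = 200 (1000
replicates), cutoff recovery at n = 400 (100 replicates), and simulator
self-consistency at n = 5000. The C-index uses O(n²) memory and is intended
for cohort-scale n (≲ 5000). Percent changes are computed on raw mL values
with no log transform. All randomness flows from `numpy.random.default_rng`
seeded explicitly; nothing reads global random state.
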