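"""Survival statistics used to develop and evaluate response criteria.

Provides the four tools the development procedure rests on:

* Kaplan-Meier estimation with median survival and its 95% CI,
* univariate Cox proportional-hazards regression (Efron tie handling),
* Harrell's concordance index with per-subject influence values,
* a correlated-C comparison for two risk scores evaluated on the same
  subjects, with variance from the joint jackknife of the two estimates.

Kaplan-Meier and Cox fits are delegated to lifelines; the concordance
machinery (pair rules, influence values, correlated comparison) is
implemented here because the paired-comparison variance requires access to
per-subject pair sums that off-the-shelf C-index routines do not expose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.utils import median_survival_times
from scipy import stats

from .errors import CohortValidationError, ConvergenceError, UndefinedStatisticError


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival data: follow-up in months and event flags."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        if times.ndim != 1 or times.shape != events.shape:
            raise CohortValidationError("times and events must be equal-length 1-D")
        if times.size == 0:
            raise CohortValidationError("empty survival sample")
        if (times < 0).any() or not np.isfinite(times).all():
            raise CohortValidationError("times must be finite and nonnegative")
        if not np.isin(events, (0, 1)).all():
            raise CohortValidationError("events must be binary (0/1)")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve with median survival.

    ``median`` is the earliest time at which the curve reaches 0.5 or below;
    NaN when the curve never does. The median CI inverts the log-log
    (exp(-exp)) transformed Greenwood interval at 0.5.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int
    ci_method: str = "log-log Greenwood inverted at 0.5"

    def survival_at(self, t: float) -> float:
        """Step-function value of the curve at time ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass
class HazardRatioResult:
    """Univariate Cox fit: hazard ratio with Wald 95% CI and p-value."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    n: int
    n_events: int


@dataclass
class CIndexResult:
    """Harrell's C with standard error and per-subject influence values.

    ``influence`` are first-order leave-one-out perturbations of the estimate
    (they sum to zero); their squared sum is the infinitesimal-jackknife
    variance and they carry the covariance needed to compare two correlated
    C-indices evaluated on the same subjects.
    """

    c: float
    se: float
    n_pairs: int
    concordant: float
    influence: np.ndarray = field(repr=False)


@dataclass
class CIndexComparison:
    """Difference of two correlated C-indices with normal-approximation p."""

    delta: float
    se: float
    p: float
    c_a: float
    c_b: float


def km_estimate(sample: SurvivalSample, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier product-limit estimate with median survival and 95% CI."""
    if np.all(sample.times == 0):
        raise CohortValidationError("all follow-up times are zero")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(sample.times, sample.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    probs = sf.iloc[:, 0].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    ci_frame = median_survival_times(kmf.confidence_interval_)
    lo, hi = (float(v) for v in ci_frame.iloc[0])
    return KMCurve(
        event_times=times,
        survival_prob=probs,
        median=median,
        median_ci=(lo, hi),
        n=len(sample),
    )


def cox_univariate(sample: SurvivalSample, covariate) -> HazardRatioResult:
    """Univariate Cox regression of survival on one numeric covariate.

    Ties are handled by the Efron approximation. A binary group code is a
    valid covariate; the hazard ratio then contrasts group 1 vs group 0.
    Monotone partial likelihoods (perfect separation) raise
    :class:`ConvergenceError` rather than returning a silent divergence.
    """
    x = np.asarray(covariate, dtype=float)
    if x.shape != sample.times.shape:
        raise CohortValidationError("covariate length must match sample")
    if np.ptp(x) == 0:
        raise CohortValidationError("covariate is constant")
    frame = pd.DataFrame({"time": sample.times, "event": sample.events, "x": x})
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(frame, duration_col="time", event_col="event")
    except (_LLConvergenceError, ValueError) as exc:
        raise ConvergenceError(f"Cox partial likelihood did not converge: {exc}") from exc
    summary = fitter.summary.loc["x"]
    coef = float(summary["coef"])
    se = float(summary["se(coef)"])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 50:
        raise ConvergenceError("monotone partial likelihood (perfect separation)")
    return HazardRatioResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p=float(summary["p"]),
        coef=coef,
        se=se,
        n=len(sample),
        n_events=int(sample.events.sum()),
    )


def _pair_scores(sample: SurvivalSample, risk: np.ndarray):
    """Comparable-pair mask and per-ordered-pair concordance scores.

    An ordered pair (i, j) is usable when subject i dies strictly before j's
    follow-up ends, or dies exactly when j is censored. Pairs of deaths at
    identical times and pairs whose earlier time is censored carry no
    ordering information and are excluded.
    """
    t = sample.times
    d = sample.events.astype(bool)
    earlier = t[:, None] < t[None, :]
    tied_time = (t[:, None] == t[None, :]) & d[:, None] & ~d[None, :]
    usable = (earlier & d[:, None]) | tied_time
    np.fill_diagonal(usable, False)
    higher = risk[:, None] > risk[None, :]
    tied_risk = risk[:, None] == risk[None, :]
    scores = np.where(higher, 1.0, np.where(tied_risk, 0.5, 0.0))
    return usable, scores


def harrell_cindex(sample: SurvivalSample, risk) -> CIndexResult:
    """Harrell's concordance index of a risk score for right-censored survival.

    Concordance means the subject with the higher risk score dies earlier;
    tied risks count 1/2. Raises :class:`UndefinedStatisticError` when the
    sample contains no usable pair.
    """
    risk = np.asarray(risk, dtype=float)
    if risk.shape != sample.times.shape:
        raise CohortValidationError("risk length must match sample")
    if not np.isfinite(risk).all():
        raise CohortValidationError("risk scores must be finite")
    usable, scores = _pair_scores(sample, risk)
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        raise UndefinedStatisticError("no usable pair for concordance")
    pair_scores = np.where(usable, scores, 0.0)
    numerator = float(pair_scores.sum())
    c = numerator / n_pairs
    # Per-subject pair sums over both roles (earlier and later member).
    s_k = pair_scores.sum(axis=1) + pair_scores.sum(axis=0)
    n_k = usable.sum(axis=1) + usable.sum(axis=0)
    influence = (s_k - c * n_k) / n_pairs
    se = float(np.sqrt((influence**2).sum()))
    return CIndexResult(
        c=float(c), se=se, n_pairs=n_pairs, concordant=numerator, influence=influence
    )


def compare_cindex(sample: SurvivalSample, risk_a, risk_b) -> CIndexComparison:
    """Test the difference of two C-indices computed on the same subjects.

    The variance of ``c_a - c_b`` is estimated from the joint per-subject
    influence values, which accounts for the correlation induced by scoring
    the same patients twice. A degenerate (zero) variance with the two risk
    scores inducing identical pair orderings yields p = 1 with a warning.
    """
    res_a = harrell_cindex(sample, risk_a)
    res_b = harrell_cindex(sample, risk_b)
    delta = res_a.c - res_b.c
    var = float(((res_a.influence - res_b.influence) ** 2).sum())
    if var <= 0.0:
        if delta != 0.0:  # pragma: no cover - defensive
            raise UndefinedStatisticError("zero variance with nonzero difference")
        warnings.warn(
            "identical pair orderings: difference degenerate, p set to 1",
            stacklevel=2,
        )
        return CIndexComparison(delta=0.0, se=0.0, p=1.0, c_a=res_a.c, c_b=res_b.c)
    se = float(np.sqrt(var))
    z = delta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CIndexComparison(delta=float(delta), se=se, p=p, c_a=res_a.c, c_b=res_b.c)


def km_by_group(times, events, groups) -> dict:
    """Kaplan-Meier curves per group label; convenience for stratified output."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        out[g] = km_estimate(SurvivalSample(times[mask], events[mask]))
    return out
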