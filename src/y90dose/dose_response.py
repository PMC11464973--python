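"""Simulated lesion cohorts and dose-response statistics.

The cohort generator draws one Bernoulli response per lesion from a
Gompertz-like sigmoid of the tumour absorbed dose,

    p(D) = exp(-8 exp(-0.03 D)) * (1 - 3.3e-5 D),

evaluated on a fixed design of 100 lesions with doses 1, 3, ..., 199 Gy.
The analysis layer mirrors the standard clinical workflow: Wilcoxon rank-sum
comparison of responder vs non-responder doses, ROC analysis of dose as a
response classifier (trapezoidal AUC with a DeLong confidence interval and
the Youden-optimal cutoff), and a two-parameter logistic dose-response fit
with ED50/ED80 and delta-method confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

_GOMPERTZ_SCALE = 8.0
_GOMPERTZ_RATE = 0.03  # Gy^-1
_LINEAR_SLOPE = 3.3e-5  # Gy^-1
_DOSE_MAX = 199.0


def response_probability(dose_gy) -> np.ndarray | float:
    """True response probability of the simulation model, clipped to [0, 1]."""
    d = np.asarray(dose_gy, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    if np.any(d > _DOSE_MAX):
        warnings.warn(
            f"dose above {_DOSE_MAX:.0f} Gy is outside the model's design range",
            stacklevel=2,
        )
    p = np.exp(-_GOMPERTZ_SCALE * np.exp(-_GOMPERTZ_RATE * d)) * (
        1.0 - _LINEAR_SLOPE * d
    )
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(dose_gy) else p


@dataclass
class LesionCohort:
    """Per-lesion absorbed doses (Gy) and binary responses (1 = responder)."""

    doses_gy: np.ndarray
    responses: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.doses_gy = np.asarray(self.doses_gy, dtype=float)
        self.responses = np.asarray(self.responses, dtype=int)
        if self.doses_gy.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if not np.isin(self.responses, (0, 1)).all():
            raise ValueError("responses must be binary")

    @property
    def n(self) -> int:
        return self.doses_gy.size

    @property
    def responder_doses(self) -> np.ndarray:
        return self.doses_gy[self.responses == 1]

    @property
    def non_responder_doses(self) -> np.ndarray:
        return self.doses_gy[self.responses == 0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lesion_id": np.arange(1, self.n + 1),
                "dose_gy": self.doses_gy,
                "response": self.responses,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LesionCohort":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(doses_gy=df["dose_gy"].to_numpy(),
                   responses=df["response"].to_numpy())


def simulate_cohort(
    seed: int,
    n: int = 100,
    dose_start_gy: float = 1.0,
    dose_step_gy: float = 2.0,
) -> LesionCohort:
    """Simulate a lesion cohort on the fixed dose design.

    Doses are ``dose_start, dose_start + step, ...`` (n lesions; the default
    covers 1-199 Gy) and each response is a single Bernoulli draw with
    p = ``response_probability(D)``. Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    doses = dose_start_gy + dose_step_gy * np.arange(n)
    p = response_probability(doses)
    responses = (rng.random(n) < p).astype(int)
    return LesionCohort(doses_gy=doses, responses=responses, seed=seed)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first group
    pvalue: float


def rank_sum_test(doses_group1, doses_group0) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Normal approximation with tie correction and continuity correction, the
    standard large-sample flavour.
    """
    g1 = np.asarray(doses_group1, dtype=float)
    g0 = np.asarray(doses_group0, dtype=float)
    if g1.size == 0 or g0.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(
        g1, g0, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RankSumResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Empirical ROC of dose as a response classifier.

    ``thresholds`` are the candidate cutoffs (predict responder when
    dose >= threshold); sensitivity/specificity are aligned with them.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC."""
    m, n = pos.size, neg.size
    # placement values
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m for y in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_analysis(cohort: LesionCohort) -> RocResult:
    """Empirical ROC curve, trapezoidal AUC, DeLong 95% CI and Youden cutoff.

    The trapezoidal AUC over all distinct thresholds equals the Mann-Whitney
    statistic U/(n1*n0). Youden ties resolve to the lowest threshold.
    """
    pos = cohort.responder_doses
    neg = cohort.non_responder_doses
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC analysis needs both classes present")
    thr = np.unique(cohort.doses_gy)
    # predict positive when dose >= t; include -inf (all positive) endpoint
    thresholds = np.concatenate([[-np.inf], thr, [np.inf]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    se = np.sqrt(_delong_auc_variance(pos, neg))
    z = stats.norm.ppf(0.975)
    ci = (max(auc - z * se, 0.0), min(auc + z * se, 1.0))
    j = sens + spec - 1.0
    finite = np.isfinite(thresholds)
    jf, tf = j[finite], thresholds[finite]
    best = np.flatnonzero(np.isclose(jf, jf.max()))
    k = best[np.argmin(tf[best])]
    k_full = np.flatnonzero(finite)[k]
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci95=ci,
        youden_threshold=float(tf[k]),
        youden_sensitivity=float(sens[k_full]),
        youden_specificity=float(spec[k_full]),
    )


# ---------------------------------------------------------------------------
# logistic dose-response model
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Two-parameter logistic fit logit P = beta0 + beta1 * D.

    ``a``/``b`` expose the decreasing-exponent convention
    P = e^(-aD+b)/(1+e^(-aD+b)), i.e. a = -beta1, b = beta0.
    """

    beta0: float
    beta1: float
    cov: np.ndarray
    converged: bool
    ed50_gy: float | None
    ed50_ci95: tuple[float, float] | None
    ed80_gy: float | None
    ed80_ci95: tuple[float, float] | None

    @property
    def a(self) -> float:
        return -self.beta1

    @property
    def b(self) -> float:
        return self.beta0

    def predict(self, dose_gy) -> np.ndarray:
        eta = self.beta0 + self.beta1 * np.asarray(dose_gy, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def ed(self, p: float) -> float:
        """Dose with fitted response probability p."""
        if not 0 < p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.beta1 == 0:
            raise ValueError("zero slope: ED undefined")
        return (np.log(p / (1 - p)) - self.beta0) / self.beta1


def _ed_delta_ci(beta0, beta1, cov, p, z=1.959963984540054):
    logit_p = np.log(p / (1 - p))
    ed = (logit_p - beta0) / beta1
    grad = np.array([-1.0 / beta1, -ed / beta1])
    var = float(grad @ cov @ grad)
    half = z * np.sqrt(max(var, 0.0))
    return float(ed), (float(ed - half), float(ed + half))


def _ed_profile_ci(doses, y, weights, p, level=0.95):
    """Profile-likelihood CI for EDp by likelihood-ratio inversion.

    Reparametrise beta0 = logit(p) - beta1*EDp and profile over beta1.
    """
    from scipy.optimize import brentq, minimize_scalar

    logit_p = np.log(p / (1 - p))

    def nll_at(edp):
        def nll(b1):
            eta = logit_p + b1 * (doses - edp)
            return -np.sum(weights * (y * eta - np.logaddexp(0.0, eta)))

        return minimize_scalar(nll, bounds=(1e-6, 1.0), method="bounded").fun

    # full model
    import statsmodels.api as sm

    fit = sm.GLM(y, sm.add_constant(doses), family=sm.families.Binomial(),
                 freq_weights=weights).fit()
    ll_max = fit.llf
    crit = stats.chi2.ppf(level, 1) / 2.0
    ed_hat = (logit_p - fit.params[0]) / fit.params[1]

    def diff(edp):
        return (ll_max - (-nll_at(edp))) - crit

    lo, hi = ed_hat, ed_hat
    step = 5.0
    while diff(lo) < 0 and lo > ed_hat - 400:
        lo -= step
    while diff(hi) < 0 and hi < ed_hat + 600:
        hi += step
    lower = brentq(diff, lo, ed_hat) if diff(lo) >= 0 else -np.inf
    upper = brentq(diff, ed_hat, hi) if diff(hi) >= 0 else np.inf
    return float(ed_hat), (float(lower), float(upper))


def logistic_fit(
    cohort: LesionCohort | None = None,
    *,
    doses_gy=None,
    responses=None,
    weights=None,
    ci_method: str = "delta",
) -> LogisticFit:
    """Maximum-likelihood two-parameter logistic dose-response fit.

    Accepts either a cohort of binary responses or explicit
    ``doses_gy``/``responses`` arrays; ``responses`` may be fractional
    (with ``weights``) for fitting to known response probabilities.
    ED50/ED80 confidence intervals use the delta method on the dose scale by
    default; ``ci_method="profile"`` inverts the likelihood-ratio test.
    Complete separation is flagged via ``converged=False`` with no ED
    estimates.
    """
    import statsmodels.api as sm

    if cohort is not None:
        doses_gy = cohort.doses_gy
        responses = cohort.responses
    doses_gy = np.asarray(doses_gy, dtype=float)
    y = np.asarray(responses, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    is_binary = np.isin(y, (0.0, 1.0)).all()
    if is_binary and (y.min() == y.max()):
        raise ValueError("logistic fit needs both responders and non-responders")

    exog = sm.add_constant(doses_gy)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, exog, family=sm.families.Binomial(),
                         freq_weights=w).fit(maxiter=200)
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            converged = bool(res.converged) and np.all(np.isfinite(cov))
        except Exception:
            params = np.array([np.nan, np.nan])
            cov = np.full((2, 2), np.nan)
            converged = False
    # treat absurd slopes / exploded SEs as separation
    if converged and (abs(params[1]) > 5.0 or np.sqrt(cov[1, 1]) > 5.0):
        converged = False
    if not converged or params[1] == 0:
        return LogisticFit(
            beta0=float(params[0]), beta1=float(params[1]), cov=cov,
            converged=False, ed50_gy=None, ed50_ci95=None,
            ed80_gy=None, ed80_ci95=None,
        )
    if ci_method == "profile":
        ed50, ci50 = _ed_profile_ci(doses_gy, y, w, 0.5)
        ed80, ci80 = _ed_profile_ci(doses_gy, y, w, 0.8)
    else:
        ed50, ci50 = _ed_delta_ci(params[0], params[1], cov, 0.5)
        ed80, ci80 = _ed_delta_ci(params[0], params[1], cov, 0.8)
    return LogisticFit(
        beta0=float(params[0]), beta1=float(params[1]), cov=cov, converged=True,
        ed50_gy=ed50, ed50_ci95=ci50, ed80_gy=ed80, ed80_ci95=ci80,
    )
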