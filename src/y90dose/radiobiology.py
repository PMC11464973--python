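"""Radiobiological models for Y-90 microsphere therapy.

Tumour control probability (TCP) follows the linear-quadratic model with the
Lea-Catcheside protraction factor G; for a permanent Y-90 implant with no
activity re-localisation G collapses to lambda/(lambda + mu), the competition
between physical decay and sublethal-damage repair. Normal-tissue
complication probability (NTCP) uses the Lyman probit model with the
whole-organ tolerance dose scaled by the irradiated liver fraction,
TD50(v) = TD50/v. The microscale model maps the lobular trapping statistics
of microspheres onto a targeted-liver TD50 as a function of the targeted
fraction v and the activity per sphere. The therapeutic index TD50/ED50
(times the T/N ratio when expressed on tumour dose) and the complication-free
tumour control P* = TCP*(1-NTCP) combine the two sides for treatment
tailoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .constants import Y90


@dataclass(frozen=True)
class RadiobioParams:
    """Linear-quadratic TCP parameter bundle.

    ``beta`` is derived from ``alpha`` through the alpha/beta ratio
    (default 10 Gy, the conventional tumour value) and the protraction factor
    from the decay and repair rates.
    """

    alpha_per_gy: float
    n0: float
    alpha_beta_ratio_gy: float = 10.0
    mu_per_h: float = Y90.mu_dna_repair_per_h
    lambda_per_h: float = Y90.lambda_per_h

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("clonogen number N0 must be > 0")
        if self.alpha_per_gy < 0 or self.alpha_beta_ratio_gy <= 0:
            raise ValueError("alpha must be >= 0 and alpha/beta > 0")

    @property
    def beta_per_gy2(self) -> float:
        return self.alpha_per_gy / self.alpha_beta_ratio_gy

    @property
    def g_factor(self) -> float:
        return lea_catcheside_g(self.lambda_per_h, self.mu_per_h)


@dataclass(frozen=True)
class NtcpParams:
    """Lyman NTCP parameters: whole-organ TD50, slope m, irradiated fraction v."""

    td50_ref_gy: float
    m: float
    v: float = 1.0

    def __post_init__(self) -> None:
        if self.td50_ref_gy <= 0:
            raise ValueError("TD50 must be > 0")
        if self.m <= 0:
            raise ValueError("slope m must be > 0")
        if not 0 < self.v <= 1:
            raise ValueError("irradiated fraction v must be in (0, 1]")

    @property
    def td50_gy(self) -> float:
        """Volume-scaled tolerance dose TD50(v) = TD50/v."""
        return self.td50_ref_gy / self.v


@dataclass(frozen=True)
class MicroscaleParams:
    """Microscale TD50 model inputs: targeted fraction v and kBq per sphere."""

    v: float
    msa_kbq: float

    def __post_init__(self) -> None:
        if self.msa_kbq < 0:
            raise ValueError("activity per sphere must be >= 0")
        if self.v > 1:
            raise ValueError("targeted fraction v must be <= 1")


def lea_catcheside_g(lambda_per_h: float, mu_per_h: float) -> float:
    """Protraction factor G = lambda/(lambda + mu) for a permanent implant."""
    if lambda_per_h <= 0 or mu_per_h < 0:
        raise ValueError("rates must be positive")
    return lambda_per_h / (lambda_per_h + mu_per_h)


def tcp_lq(dose_gy, params: RadiobioParams) -> np.ndarray | float:
    """Poisson TCP, P = exp(-N0 exp(-alpha D - G beta D^2))."""
    d = np.asarray(dose_gy, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    surviving = params.n0 * np.exp(
        -params.alpha_per_gy * d - params.g_factor * params.beta_per_gy2 * d**2
    )
    p = np.exp(-surviving)
    return float(p) if np.isscalar(dose_gy) else p


@dataclass
class TcpFit:
    """Binned least-squares LQ TCP fit (free N0 and alpha)."""

    params: RadiobioParams
    bin_mean_dose_gy: np.ndarray
    bin_response_fraction: np.ndarray
    bin_counts: np.ndarray
    converged: bool
    ed50_gy: float | None
    ed80_gy: float | None

    def predict(self, dose_gy):
        return tcp_lq(dose_gy, self.params)


def _tcp_ed(params: RadiobioParams, p: float) -> float | None:
    f = lambda d: tcp_lq(d, params) - p
    try:
        return float(optimize.brentq(f, 0.0, 2000.0))
    except ValueError:
        return None


def fit_tcp(
    cohort,
    bin_width_gy: float = 25.0,
    weighted: bool = True,
    alpha_beta_ratio_gy: float = 10.0,
) -> TcpFit:
    """Fit the LQ TCP to a binary-response cohort via dose binning.

    Doses are binned into ``bin_width_gy`` intervals; each bin contributes
    its mean dose and observed response fraction, fitted by
    Levenberg-Marquardt least squares with N0 and alpha free (beta tied
    through alpha/beta, G fixed from the decay/repair rates). Bins are
    weighted by lesion count unless ``weighted=False``. Degenerate data
    (fewer than 3 non-empty bins, a single response level, or
    non-convergence) is flagged.
    """
    doses = np.asarray(cohort.doses_gy, dtype=float)
    resp = np.asarray(cohort.responses, dtype=float)
    idx = np.floor(doses / bin_width_gy).astype(int)
    bins = np.unique(idx)
    mean_d = np.array([doses[idx == b].mean() for b in bins])
    frac = np.array([resp[idx == b].mean() for b in bins])
    counts = np.array([(idx == b).sum() for b in bins])
    g = lea_catcheside_g(Y90.lambda_per_h, Y90.mu_dna_repair_per_h)

    def make(n0, alpha):
        return RadiobioParams(alpha_per_gy=alpha, n0=n0,
                              alpha_beta_ratio_gy=alpha_beta_ratio_gy)

    def fail():
        p = make(1.0, 0.01)
        return TcpFit(params=p, bin_mean_dose_gy=mean_d,
                      bin_response_fraction=frac, bin_counts=counts,
                      converged=False, ed50_gy=None, ed80_gy=None)

    if len(bins) < 3 or frac.min() == frac.max():
        return fail()

    def model(d, log_n0, alpha):
        n0 = np.exp(log_n0)
        beta = alpha / alpha_beta_ratio_gy
        return np.exp(-n0 * np.exp(-alpha * d - g * beta * d**2))

    sigma = 1.0 / np.sqrt(counts) if weighted else None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                model, mean_d, frac, p0=(np.log(5.0), 0.02), sigma=sigma,
                method="lm", maxfev=10000,
            )
    except (RuntimeError, optimize.OptimizeWarning):
        return fail()
    if not np.all(np.isfinite(popt)) or popt[1] <= 0:
        return fail()
    params = make(float(np.exp(popt[0])), float(popt[1]))
    return TcpFit(
        params=params, bin_mean_dose_gy=mean_d, bin_response_fraction=frac,
        bin_counts=counts, converged=True,
        ed50_gy=_tcp_ed(params, 0.5), ed80_gy=_tcp_ed(params, 0.8),
    )


def eud(dose_values_gy, alpha_per_gy: float, weights=None) -> float:
    """Equivalent uniform dose, EUD = -(1/alpha) ln(mean(exp(-alpha D))).

    ``dose_values_gy`` may be per-voxel doses or differential-DVH bin doses
    with ``weights`` the bin volumes. The cell-kill average penalises cold
    spots; EUD lies between min and max dose and tends to the arithmetic
    mean as alpha -> 0 (use :func:`mean_dose` for that limit).
    """
    d = np.asarray(dose_values_gy, dtype=float)
    if d.size == 0:
        raise ValueError("dose values must be non-empty")
    if alpha_per_gy <= 0:
        raise ValueError("alpha must be > 0 (the alpha->0 limit is the mean dose)")
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != d.shape or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    from scipy.special import logsumexp

    log_mean = logsumexp(-alpha_per_gy * d, b=w / w.sum())
    return float(-log_mean / alpha_per_gy)


def mean_dose(dose_values_gy, weights=None) -> float:
    """Arithmetic (alpha -> 0) limit of the EUD."""
    d = np.asarray(dose_values_gy, dtype=float)
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    return float(np.average(d, weights=w))


def lyman_ntcp(dose_gy, params: NtcpParams) -> np.ndarray | float:
    """Lyman NTCP: standard-normal CDF of t = (D - TD50/v)/(m TD50/v)."""
    d = np.asarray(dose_gy, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    td50_v = params.td50_gy
    t = (d - td50_v) / (params.m * td50_v)
    p = stats.norm.cdf(t)
    return float(p) if np.isscalar(dose_gy) else p


def microscale_td50(params: MicroscaleParams) -> float:
    """Targeted-liver TD50 (Gy) from the microsphere microscale model.

    TD50 = [25.2 + 22.1 (1 - exp(-2.74 msA))] / (v - 0.4)^0.584, msA in kBq
    per sphere. The model diverges as v -> 0.4 (selective treatments are
    predicted safe); for v <= 0.4 the TD50 is reported as infinite rather
    than raising.
    """
    if params.v <= 0.4:
        warnings.warn(
            "targeted fraction v <= 0.4: the microscale TD50 is unbounded",
            stacklevel=2,
        )
        return float("inf")
    numer = 25.2 + 22.1 * (1.0 - np.exp(-2.74 * params.msa_kbq))
    return float(numer / (params.v - 0.4) ** 0.584)


def therapeutic_index(
    td50_liver_gy: float, ed50_tumour_gy: float, tn_ratio: float = 1.0
) -> float:
    """TI = (TD50_liver / ED50_tumour) * r, on the tumour-dose scale.

    With r = 1 this is the plain TD50/ED50 ratio; the T/N ratio converts the
    liver tolerance into the tumour dose achievable at that tolerance.
    """
    if td50_liver_gy <= 0 or ed50_tumour_gy <= 0 or tn_ratio <= 0:
        raise ValueError("TD50, ED50 and T/N ratio must be > 0")
    return td50_liver_gy / ed50_tumour_gy * tn_ratio


def complication_free_tcp(
    dose_tumour_gy, tcp_params: RadiobioParams, ntcp_params: NtcpParams,
    dose_liver_gy=None,
) -> np.ndarray | float:
    """P* = TCP(D_tumour) * (1 - NTCP(D_liver)).

    ``dose_liver_gy`` defaults to the tumour dose (single-dose-axis form).
    """
    d_liver = dose_tumour_gy if dose_liver_gy is None else dose_liver_gy
    return tcp_lq(dose_tumour_gy, tcp_params) * (
        1.0 - lyman_ntcp(d_liver, ntcp_params)
    )


@dataclass(frozen=True)
class PstarScan:
    activity_gbq: np.ndarray
    tcp: np.ndarray
    ntcp: np.ndarray
    pstar: np.ndarray

    @property
    def optimum_gbq(self) -> float:
        return float(self.activity_gbq[np.argmax(self.pstar)])


def pstar_activity_scan(
    activities_gbq,
    dose_coeff_tumour_gy_per_gbq: float,
    dose_coeff_liver_gy_per_gbq: float,
    tcp_params: RadiobioParams,
    ntcp_params: NtcpParams,
) -> PstarScan:
    """Scan P* over administered activity via compartment dose coefficients.

    Tumour and liver doses are ``d_T * A`` and ``d_N * A`` (the
    multi-compartment coefficients); the returned scan locates the activity
    maximising the complication-free tumour control.
    """
    a = np.asarray(activities_gbq, dtype=float)
    if np.any(a < 0):
        raise ValueError("activity must be >= 0")
    tcp = tcp_lq(a * dose_coeff_tumour_gy_per_gbq, tcp_params)
    ntcp = lyman_ntcp(a * dose_coeff_liver_gy_per_gbq, ntcp_params)
    return PstarScan(activity_gbq=a, tcp=np.atleast_1d(tcp),
                     ntcp=np.atleast_1d(ntcp),
                     pstar=np.atleast_1d(tcp * (1.0 - ntcp)))
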