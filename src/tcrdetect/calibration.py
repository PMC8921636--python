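"""Maximum-likelihood calibration of the read model from spike-in counts.

Spike-in clonotypes have known in-sample frequencies, so the sampling stage
carries no information about the sequencing method: the likelihood involves
only the negative-binomial read model with mean ``mu_i = f_samp_i * r_e *
T_read`` and variance ``mu_i + eta * mu_i**lam``. The three parameters
``(r_e, eta, lam)`` are estimated jointly by multi-start Nelder-Mead on a
transformed scale (logit r_e, log eta, lam in a box), with an explicit
eta = 0 Poisson submodel compared by likelihood. Parameter uncertainty comes
from the inverse numeric Hessian at the optimum; the detection-limit
confidence interval from a seeded parametric bootstrap (Wald/delta method
available as an alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .errors import (
    ConvergenceError,
    DegenerateDataError,
    IdentifiabilityError,
    ModelParameterError,
    UnreachableTargetError,
)
from .model import ReadModelParams, negbin_read_pmf

__all__ = [
    "CalibrationObservation",
    "CalibrationResult",
    "DetectionLimit",
    "fit_read_model",
    "detection_limit",
    "detection_limit_ci",
]

PARAM_ORDER = ("r_e", "eta", "lam")

_ETA_LOG_BOUNDS = (math.log(1e-8), math.log(1e4))
_DEFAULT_LAM_BOUNDS = (0.5, 3.0)
# Log-likelihood margin below which the Poisson submodel is preferred.
_POISSON_PREFERENCE_TOL = 1e-6


@dataclass(frozen=True)
class CalibrationObservation:
    """One spike-in read-count observation with known sample frequency."""

    f_samp: float
    c_read: int
    chain: str = "TRB"
    set_id: str = ""
    replicate_id: str = ""

    def __post_init__(self):
        if not (0.0 < self.f_samp <= 1.0):
            raise ModelParameterError(f"f_samp must be in (0, 1], got {self.f_samp}")
        if self.c_read < 0:
            raise ModelParameterError(f"c_read must be >= 0, got {self.c_read}")


@dataclass
class CalibrationResult:
    """Maximum-likelihood fit of the read model with uncertainty."""

    params: ReadModelParams
    t_read: int
    log_likelihood: float
    param_covariance: np.ndarray
    n_obs: int
    converged: bool
    param_order: tuple = PARAM_ORDER


@dataclass
class DetectionLimit:
    """Minimal detectable in-sample frequency with confidence bounds."""

    f_samp95: float
    ci_low: float
    ci_high: float
    alpha: float = 0.95
    t_read: int = 10**6
    c_thresh: int = 0


def _nb_loglik(r_e: float, eta: float, lam: float, k: np.ndarray, c: np.ndarray) -> float:
    """Sum of read-model log pmfs; ``k = f_samp * T_read`` per observation."""
    mu = r_e * k
    if np.any(mu <= 0):
        return -np.inf
    if eta == 0.0:
        return float(stats.poisson.logpmf(c, mu).sum())
    with np.errstate(over="ignore", under="ignore"):
        size = mu ** (2.0 - lam) / eta
    if np.any(size < 1e-12):
        return -np.inf
    big = size > 1e12
    size_safe = np.where(big, 1.0, size)
    ll = np.where(
        big,
        stats.poisson.logpmf(c, mu),
        stats.nbinom.logpmf(c, size_safe, size_safe / (size_safe + mu)),
    )
    return float(ll.sum())


def _poisson_mle(k: np.ndarray, c: np.ndarray):
    """Closed-form Poisson fit: r_e maximizing sum(c log(r k) - r k)."""
    r_hat = float(np.clip(c.sum() / k.sum(), 1e-9, 1.0))
    return r_hat, _nb_loglik(r_hat, 0.0, 1.0, k, c)


def _moment_start(f: np.ndarray, c: np.ndarray, t_read: int, lam_bounds):
    """Method-of-moments initial values from per-tier means and variances."""
    r0 = float(np.clip(c.sum() / (f.sum() * t_read), 1e-6, 1.0 - 1e-6))
    means, excesses = [], []
    for fv in np.unique(f):
        grp = c[f == fv]
        if grp.size < 2:
            continue
        m, v = grp.mean(), grp.var(ddof=1)
        if m > 0 and v > m:
            means.append(m)
            excesses.append(v - m)
    if len(means) >= 2:
        slope, intercept = np.polyfit(np.log(means), np.log(excesses), 1)
        lam0 = float(np.clip(slope, *lam_bounds))
        eta0 = float(np.clip(math.exp(intercept), 1e-6, 1e4))
    else:
        lam0, eta0 = 1.3, 1.0
    return r0, eta0, lam0


def _numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    hess = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                val = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
            else:
                val = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def _psd_clip(mat: np.ndarray) -> np.ndarray:
    mat = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(mat)
    return (v * np.clip(w, 0.0, None)) @ v.T


def fit_read_model(
    observations,
    t_read: int,
    lam_bounds=_DEFAULT_LAM_BOUNDS,
) -> CalibrationResult:
    """Fit ``(r_e, eta, lam)`` to spike-in read counts by maximum likelihood.

    Requires at least three distinct spike-in frequencies (the mean-variance
    exponent is otherwise unidentifiable) and at least one nonzero count.
    Deterministic: a fixed multi-start grid plus a method-of-moments start.
    Raises :class:`ConvergenceError` (carrying the best fit found) if no start
    converges.
    """
    obs = list(observations)
    if t_read < 1:
        raise ModelParameterError("t_read must be a positive integer")
    f = np.array([o.f_samp for o in obs], dtype=float)
    c = np.array([o.c_read for o in obs], dtype=np.int64)
    if np.unique(f).size < 3:
        raise IdentifiabilityError(
            "need >= 3 distinct spike-in frequencies to identify the "
            "mean-variance exponent"
        )
    if np.all(c == 0):
        raise DegenerateDataError("all read counts are zero; nothing to calibrate")
    k = f * t_read

    lam_lo, lam_hi = lam_bounds
    eta_lo, eta_hi = _ETA_LOG_BOUNDS

    def unpack(theta):
        r_e = float(expit(np.clip(theta[0], -35.0, 35.0)))
        eta = math.exp(float(np.clip(theta[1], eta_lo, eta_hi)))
        lam = float(np.clip(theta[2], lam_lo, lam_hi))
        return r_e, eta, lam

    def nll(theta):
        r_e, eta, lam = unpack(theta)
        penalty = 0.0
        if theta[1] < eta_lo or theta[1] > eta_hi:
            penalty += 1e4 * (abs(theta[1] - np.clip(theta[1], eta_lo, eta_hi)))
        if theta[2] < lam_lo or theta[2] > lam_hi:
            penalty += 1e4 * (abs(theta[2] - np.clip(theta[2], lam_lo, lam_hi)))
        ll = _nb_loglik(r_e, eta, lam, k, c)
        if not math.isfinite(ll):
            return 1e12
        return -ll + penalty

    r0, eta0, lam0 = _moment_start(f, c, t_read, lam_bounds)
    starts = [(r0, eta0, lam0)]
    lam_grid = np.clip([0.8, 1.3, 2.0], lam_lo, lam_hi)
    for eta_s in (0.1, 1.0, 10.0):
        for lam_s in lam_grid:
            starts.append((r0, eta_s, float(lam_s)))

    best = None
    any_success = False
    for r_s, eta_s, lam_s in starts:
        theta0 = np.array([logit(r_s), math.log(eta_s), lam_s])
        res = optimize.minimize(
            nll, theta0, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-9},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res

    r_nb, eta_nb, lam_nb = unpack(best.x)
    ll_nb = _nb_loglik(r_nb, eta_nb, lam_nb, k, c)
    r_pois, ll_pois = _poisson_mle(k, c)

    if ll_nb <= ll_pois + _POISSON_PREFERENCE_TOL:
        params = ReadModelParams(r_pois, 0.0, 1.0)
        ll = ll_pois
        # Fisher information for r_e under the Poisson submodel: sum(c)/r^2.
        cov = np.zeros((3, 3))
        info = c.sum() / r_pois**2
        cov[0, 0] = 1.0 / info if info > 0 else 0.0
    else:
        params = ReadModelParams(r_nb, eta_nb, lam_nb)
        ll = ll_nb
        x_opt = np.array([r_nb, eta_nb, lam_nb])

        def ll_orig(x):
            r = float(np.clip(x[0], 1e-12, 1.0))
            e = max(float(x[1]), 1e-300)
            return _nb_loglik(r, e, float(x[2]), k, c)

        hess = _numeric_hessian(ll_orig, x_opt)
        try:
            cov = np.linalg.pinv(-hess)
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = np.zeros((3, 3))
        cov = _psd_clip(cov)

    result = CalibrationResult(
        params=params,
        t_read=int(t_read),
        log_likelihood=ll,
        param_covariance=cov,
        n_obs=len(obs),
        converged=any_success,
    )
    if not any_success:
        raise ConvergenceError("no optimizer start converged", best_result=result)
    return result


def _read_detection_prob(f_samp: float, params: ReadModelParams, t_read: int, c_thresh: int) -> float:
    """P(C_read > c_thresh) for a clonotype at known in-sample frequency."""
    mu = f_samp * params.r_e * t_read
    if mu == 0.0:
        return 0.0
    pmf = negbin_read_pmf(np.arange(c_thresh + 1), mu, params)
    return float(min(1.0, max(0.0, 1.0 - pmf.sum())))


def _solve_detection_limit(
    params: ReadModelParams,
    alpha: float,
    t_read: int,
    c_thresh: int,
    rtol: float = 1e-6,
    f_lo: float = 1e-14,
) -> float:
    if alpha <= 0.0:
        return f_lo
    p_max = _read_detection_prob(1.0, params, t_read, c_thresh)
    if p_max < alpha:
        raise UnreachableTargetError(
            f"detection probability {alpha} unreachable at any f_samp <= 1; "
            f"maximum achievable is {p_max:.6g}",
            max_achievable=p_max,
        )
    lo, hi = f_lo, 1.0
    while hi / lo - 1.0 > rtol:
        mid = math.sqrt(lo * hi)
        if _read_detection_prob(mid, params, t_read, c_thresh) < alpha:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def detection_limit(
    result,
    alpha: float = 0.95,
    t_read: int = 10**6,
    c_thresh: int = 0,
    rtol: float = 1e-6,
) -> DetectionLimit:
    """Minimal in-sample frequency detectable with probability ``alpha``.

    Uses only the read-model stage (spike-in frequencies are known in-sample
    quantities); solved by monotone bisection on log frequency. ``result``
    may be a :class:`CalibrationResult` or bare :class:`ReadModelParams`.
    The returned interval is degenerate (equal to the point estimate); use
    :func:`detection_limit_ci` for uncertainty.
    """
    params = result.params if isinstance(result, CalibrationResult) else result
    if not (0.0 <= alpha < 1.0):
        raise ModelParameterError(f"alpha must be in [0, 1), got {alpha}")
    f95 = _solve_detection_limit(params, alpha, t_read, c_thresh, rtol=rtol)
    return DetectionLimit(f95, f95, f95, alpha=alpha, t_read=int(t_read), c_thresh=int(c_thresh))


def detection_limit_ci(
    result: CalibrationResult,
    alpha: float = 0.95,
    t_read: int = 10**6,
    c_thresh: int = 0,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "bootstrap",
    lam_bounds=_DEFAULT_LAM_BOUNDS,
):
    """95% confidence interval for the detection limit.

    Parametric bootstrap: draw parameter vectors from the multivariate normal
    at the MLE (clipped to the feasible box), recompute the limit for each,
    and take the 2.5/97.5 percentiles; deterministic given ``seed``.
    ``method="wald"`` uses the delta method on the log limit instead.
    """
    cov = np.asarray(result.param_covariance, dtype=float)
    w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ModelParameterError("parameter covariance is not positive semi-definite")
    mean = np.array([result.params.r_e, result.params.eta, result.params.lam])
    point = _solve_detection_limit(result.params, alpha, t_read, c_thresh)

    if method == "wald":
        def logf95(x):
            p = ReadModelParams(
                float(np.clip(x[0], 1e-9, 1.0)),
                max(float(x[1]), 0.0),
                float(np.clip(x[2], *lam_bounds)),
            )
            return math.log(_solve_detection_limit(p, alpha, t_read, c_thresh))

        g = np.zeros(3)
        h = 1e-4 * np.maximum(np.abs(mean), 1e-3)
        for i in range(3):
            e = np.zeros(3); e[i] = h[i]
            g[i] = (logf95(mean + e) - logf95(mean - e)) / (2.0 * h[i])
        sd = math.sqrt(max(float(g @ cov @ g), 0.0))
        lo, hi = point * math.exp(-1.959964 * sd), point * math.exp(1.959964 * sd)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(mean, _psd_clip(cov), size=n_boot, method="eigh")
        draws[:, 0] = np.clip(draws[:, 0], 1e-9, 1.0)
        draws[:, 1] = np.clip(draws[:, 1], 0.0, None)
        draws[:, 2] = np.clip(draws[:, 2], *lam_bounds)
        limits = np.array([
            _solve_detection_limit(ReadModelParams(r, e, l), alpha, t_read, c_thresh)
            for r, e, l in draws
        ])
        lo, hi = np.percentile(limits, [2.5, 97.5])
    else:
        raise ModelParameterError(f"unknown CI method {method!r}")

    return float(min(lo, point)), float(max(hi, point))
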