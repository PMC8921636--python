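"""Two-stage probability model for the read count of a target TCR clonotype.

Stage one models blood sampling: the number of T cells carrying the target
receptor that end up in a blood sample of ``T_samp`` cells is Poisson with
rate ``f_body * T_samp``, where ``f_body`` is the clonotype's frequency among
all T cells in the body.

Stage two models library preparation and sequencing: given ``c_samp`` sampled
target cells, the in-sample frequency is ``f_samp = c_samp / T_samp`` and the
read count is negative binomial with mean ``mu = f_samp * r_e * T_read`` and a
power-law mean-variance relationship ``sigma^2 = mu + eta * mu**lam``. The
read efficiency ``r_e`` and the overdispersion parameters ``eta, lam`` are
properties of the sequencing method and are calibrated from spike-in data
(see :mod:`tcrdetect.calibration`).

The marginal read-count distribution sums the stage-two pmf over the stage-one
support, truncated where the Poisson mass is negligible. All probability mass
functions are evaluated in log space and exponentiated at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import ModelParameterError

__all__ = [
    "SamplingContext",
    "ReadModelParams",
    "SequencingContext",
    "poisson_sample_pmf",
    "negbin_read_pmf",
    "p2_given_csamp",
    "marginal_read_pmf",
]

# Above this dispersion size the negative binomial is numerically Poisson.
_SIZE_POISSON_FALLBACK = 1e12
# Below this size the variance is astronomically large and the pmf degenerate.
_SIZE_MIN = 1e-12

#: Default relative threshold below which stage-one Poisson terms are dropped.
DEFAULT_P1_REL_THRESHOLD = 1e-16
#: Default two-sided tail mass bounding the stage-one support window.
#: Smaller values fall below the resolution of the Poisson survival function.
DEFAULT_P1_TAIL_MASS = 1e-15


@dataclass(frozen=True)
class SamplingContext:
    """Target clonotype frequency in the body and blood-sample size.

    Parameters
    ----------
    f_body : float
        Frequency of the target TCR among all TCRs in the body, in [0, 1].
    t_samp : int
        Total number of TCRs (T cells) in the blood sample, >= 1.
    """

    f_body: float
    t_samp: int

    def __post_init__(self):
        if not (0.0 <= self.f_body <= 1.0) or not math.isfinite(self.f_body):
            raise ModelParameterError(f"f_body must be in [0, 1], got {self.f_body}")
        if self.t_samp < 1 or self.t_samp != int(self.t_samp):
            raise ModelParameterError(f"t_samp must be a positive integer, got {self.t_samp}")
        if not math.isfinite(self.f_body * self.t_samp):
            raise ModelParameterError("Poisson rate f_body * t_samp must be finite")

    @property
    def rate(self) -> float:
        """Poisson rate of the sampling stage, ``f_body * t_samp``."""
        return self.f_body * self.t_samp


@dataclass(frozen=True)
class ReadModelParams:
    """Calibrated sequencing-method parameters.

    Parameters
    ----------
    r_e : float
        Read efficiency in [0, 1]: expected reads per unit of
        ``f_samp * T_read``.
    eta : float
        Overdispersion scale (>= 0). ``eta = 0`` recovers the Poisson model.
    lam : float
        Mean-variance exponent in ``sigma^2 = mu + eta * mu**lam``.
    """

    r_e: float
    eta: float = 0.0
    lam: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.r_e <= 1.0):
            raise ModelParameterError(f"r_e must be in [0, 1], got {self.r_e}")
        if self.eta < 0 or not math.isfinite(self.eta):
            raise ModelParameterError(f"eta must be >= 0, got {self.eta}")
        if not math.isfinite(self.lam):
            raise ModelParameterError(f"lam must be finite, got {self.lam}")

    def variance(self, mu: float) -> float:
        """Read-count variance implied at mean ``mu``."""
        return mu + self.eta * mu**self.lam


@dataclass(frozen=True)
class SequencingContext:
    """Total read depth and the detection read threshold.

    ``t_read`` is the total read count for the relevant chain and library;
    a clonotype counts as detected when its read count strictly exceeds
    ``c_thresh``.
    """

    t_read: int
    c_thresh: int = 0

    def __post_init__(self):
        if self.t_read < 1 or self.t_read != int(self.t_read):
            raise ModelParameterError(f"t_read must be a positive integer, got {self.t_read}")
        if self.c_thresh < 0 or self.c_thresh != int(self.c_thresh):
            raise ModelParameterError(f"c_thresh must be a non-negative integer, got {self.c_thresh}")


def _validate_counts(c, name: str) -> np.ndarray:
    arr = np.asarray(c)
    if arr.size and (np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer)):
        if not np.all(np.equal(np.mod(arr, 1), 0)) or np.any(arr < 0):
            raise ModelParameterError(f"{name} must be non-negative integer(s)")
    return arr.astype(np.int64)


def poisson_sample_pmf(c_samp, ctx: SamplingContext):
    """Stage-one pmf: probability of drawing ``c_samp`` target cells.

    Vectorized over ``c_samp``; computed in log space.
    """
    scalar = np.isscalar(c_samp)
    c = _validate_counts(c_samp, "c_samp")
    out = np.exp(stats.poisson.logpmf(c, ctx.rate))
    return float(out) if scalar else out


def _negbin_logpmf_grid(c_read: np.ndarray, mu: np.ndarray, params: ReadModelParams) -> np.ndarray:
    """Log pmf matrix of shape (len(c_read), len(mu)).

    Each column uses its own (size, p) conversion; mu == 0 columns are a point
    mass at zero, and columns whose dispersion size exceeds the numerical
    Poisson threshold fall back to the Poisson pmf.
    """
    k = np.asarray(c_read, dtype=np.int64)[:, None]
    mu = np.asarray(mu, dtype=float)[None, :]
    zero = mu == 0.0
    mu_safe = np.where(zero, 1.0, mu)

    if params.eta == 0.0:
        log_p = stats.poisson.logpmf(k, mu_safe)
    else:
        with np.errstate(over="ignore", under="ignore"):
            size = mu_safe ** (2.0 - params.lam) / params.eta
        if np.any(~zero & (size < _SIZE_MIN)):
            raise ModelParameterError(
                "negative binomial dispersion size underflow: variance is "
                f"astronomically large for eta={params.eta}, lam={params.lam}"
            )
        poissonish = size > _SIZE_POISSON_FALLBACK
        size_safe = np.where(poissonish, 1.0, size)
        log_p_nb = stats.nbinom.logpmf(k, size_safe, size_safe / (size_safe + mu_safe))
        log_p = np.where(poissonish, stats.poisson.logpmf(k, mu_safe), log_p_nb)

    log_point_mass = np.where(k == 0, 0.0, -np.inf)
    return np.where(zero, log_point_mass, log_p)


def negbin_read_pmf(c_read, mu: float, params: ReadModelParams):
    """Stage-two pmf: probability of ``c_read`` reads at expected count ``mu``.

    Uses the conversion ``size = mu**(2 - lam) / eta`` and success probability
    ``size / (size + mu)``; ``eta = 0`` or ``mu = 0`` degrade to Poisson /
    a point mass at zero. Vectorized over ``c_read``.
    """
    if mu < 0 or not math.isfinite(mu):
        raise ModelParameterError(f"mu must be finite and >= 0, got {mu}")
    scalar = np.isscalar(c_read)
    c = _validate_counts(c_read, "c_read")
    out = np.exp(_negbin_logpmf_grid(np.atleast_1d(c), np.array([mu]), params)[:, 0])
    return float(out[0]) if scalar else out.reshape(np.shape(c))


def p2_given_csamp(
    c_read,
    c_samp: int,
    sctx: SamplingContext,
    rctx: SequencingContext,
    params: ReadModelParams,
):
    """Stage-two pmf conditional on the number of sampled target cells.

    The in-sample frequency is deduced as ``c_samp / t_samp`` so the expected
    read count is ``(c_samp / t_samp) * r_e * t_read``. ``c_samp = 0`` yields
    a point mass at zero reads.
    """
    c_samp_arr = _validate_counts(c_samp, "c_samp")
    mu = float(c_samp_arr) / sctx.t_samp * params.r_e * rctx.t_read
    return negbin_read_pmf(c_read, mu, params)


def truncated_sampling_support(
    ctx: SamplingContext,
    rel_threshold: float = DEFAULT_P1_REL_THRESHOLD,
    tail_mass: float = DEFAULT_P1_TAIL_MASS,
    sd_window: float = 10.0,
):
    """Stage-one support after truncation, with log probabilities.

    Returns ``(c_samp_values, log_p1)``. The window is the union of the
    mean +/- ``sd_window`` * sd interval and the two-sided Poisson quantile
    window at ``tail_mass``; terms with relative mass below ``rel_threshold``
    of the modal term are dropped. The ``c_samp = 0`` term is always kept so
    the marginal pmf normalizes.
    """
    rate = ctx.rate
    if rate == 0.0:
        return np.array([0], dtype=np.int64), np.array([0.0])
    sd = math.sqrt(rate)
    q_lo = stats.poisson.ppf(tail_mass, rate)
    q_hi = stats.poisson.isf(tail_mass, rate)
    lo = int(math.floor(rate - sd_window * sd))
    hi = int(math.ceil(rate + sd_window * sd)) + 40
    if math.isfinite(q_lo):
        lo = min(lo, int(q_lo))
    if math.isfinite(q_hi):
        hi = max(hi, int(q_hi))
    lo = max(lo, 0)
    cs = np.arange(lo, hi + 1, dtype=np.int64)
    logp1 = stats.poisson.logpmf(cs, rate)
    keep = logp1 >= logp1.max() + math.log(rel_threshold)
    cs, logp1 = cs[keep], logp1[keep]
    if cs.size == 0:  # pragma: no cover - cannot happen for valid inputs
        raise ModelParameterError("empty truncated support")
    if cs[0] != 0:
        cs = np.concatenate(([0], cs))
        logp1 = np.concatenate(([stats.poisson.logpmf(0, rate)], logp1))
    return cs, logp1


def marginal_read_pmf(
    c_read,
    sctx: SamplingContext,
    rctx: SequencingContext,
    params: ReadModelParams,
    rel_threshold: float = DEFAULT_P1_REL_THRESHOLD,
    support=None,
):
    """Marginal read-count pmf of the combined two-stage model.

    Sums ``P2(c_read | c_samp) * P1(c_samp)`` over the truncated stage-one
    support (always including ``c_samp = 0``). A precomputed support from
    :func:`truncated_sampling_support` may be passed to amortize grid
    evaluations. Vectorized over ``c_read``.
    """
    scalar = np.isscalar(c_read)
    c = np.atleast_1d(_validate_counts(c_read, "c_read"))
    if support is None:
        support = truncated_sampling_support(sctx, rel_threshold=rel_threshold)
    cs, logp1 = support
    mu = cs.astype(float) / sctx.t_samp * params.r_e * rctx.t_read
    logp2 = _negbin_logpmf_grid(c, mu, params)
    logpmf = logsumexp(logp2 + logp1[None, :], axis=1)
    out = np.exp(logpmf)
    return float(out[0]) if scalar else out.reshape(np.shape(np.asarray(c_read)))
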