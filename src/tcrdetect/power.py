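"""Detection power, minimal detectable frequency, and power grids.

Detection means observing strictly more than ``c_thresh`` reads of the target
clonotype, so power is ``1 - sum_{i=0}^{c_thresh} P(C_read = i)`` under the
marginal two-stage pmf. The inner sum is always computed directly; supported
thresholds are small (a typical cutoff is 18 reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelParameterError, UnreachableTargetError
from .model import (
    ReadModelParams,
    SamplingContext,
    SequencingContext,
    marginal_read_pmf,
    truncated_sampling_support,
)

__all__ = [
    "PowerQuery",
    "PowerGrid",
    "detection_power",
    "min_detectable_fbody",
    "power_grid",
    "contour_crossings",
]


@dataclass(frozen=True)
class PowerQuery:
    """A single detection-power evaluation point."""

    sampling: SamplingContext
    sequencing: SequencingContext
    params: ReadModelParams


def detection_power(query: PowerQuery, rel_threshold: float = 1e-16) -> float:
    """Probability of detecting the target clonotype, P(C_read > c_thresh)."""
    if query.sampling.f_body == 0.0:
        return 0.0
    ks = np.arange(query.sequencing.c_thresh + 1)
    pmf = marginal_read_pmf(
        ks, query.sampling, query.sequencing, query.params, rel_threshold=rel_threshold
    )
    return float(min(1.0, max(0.0, 1.0 - pmf.sum())))


def _power_at(f_body, t_samp, t_read, params, c_thresh) -> float:
    return detection_power(
        PowerQuery(
            SamplingContext(f_body, t_samp),
            SequencingContext(t_read, c_thresh),
            params,
        )
    )


def min_detectable_fbody(
    alpha: float,
    t_samp: int,
    t_read: int,
    params: ReadModelParams,
    c_thresh: int = 0,
    tol: float = 1e-4,
    f_lo: float = 1e-14,
    max_iter: int = 200,
) -> float:
    """Smallest body frequency detectable with probability ``alpha``.

    Monotone bisection on log f_body until the detection power matches
    ``alpha`` within ``tol``. Raises :class:`UnreachableTargetError` if even
    ``f_body = 1`` cannot reach ``alpha``.
    """
    if not (0.0 < alpha < 1.0):
        raise ModelParameterError(f"alpha must be in (0, 1), got {alpha}")
    p_hi = _power_at(1.0, t_samp, t_read, params, c_thresh)
    if p_hi < alpha:
        raise UnreachableTargetError(
            f"power {alpha} unreachable; maximum achievable is {p_hi:.6g}",
            max_achievable=p_hi,
        )
    lo, hi = math.log(f_lo), 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = _power_at(math.exp(mid), t_samp, t_read, params, c_thresh)
        if abs(p - alpha) < tol:
            return math.exp(mid)
        if p < alpha:
            lo = mid
        else:
            hi = mid
    return math.exp(hi)


@dataclass
class PowerGrid:
    """Detection power evaluated over sample-size x read-depth axes.

    ``power[i, j]`` is the detection probability at ``t_samp_axis[i]`` sampled
    cells and ``t_read_axis[j]`` reads. In the operating regime — expected
    reads ``f_body * r_e * t_read`` above ``c_thresh`` — entries are
    non-decreasing along both axes; below it, smaller samples make read
    counts lumpier, fattening the upper tail, and power can decrease with
    ``t_samp``.
    """

    t_samp_axis: np.ndarray
    t_read_axis: np.ndarray
    power: np.ndarray
    f_body: float
    c_thresh: int
    params: ReadModelParams = field(repr=False, default=None)


def power_grid(
    f_body: float,
    t_samp_axis,
    t_read_axis,
    params: ReadModelParams,
    c_thresh: int = 0,
    rel_threshold: float = 1e-16,
) -> PowerGrid:
    """Evaluate detection power on every (t_samp, t_read) axis pair.

    The truncated stage-one Poisson support is precomputed once per t_samp
    (it does not depend on the read depth) and reused across the row.
    """
    t_samp_axis = np.asarray(t_samp_axis, dtype=np.int64)
    t_read_axis = np.asarray(t_read_axis, dtype=np.int64)
    for axis, name in ((t_samp_axis, "t_samp_axis"), (t_read_axis, "t_read_axis")):
        if axis.size == 0 or np.any(axis < 1):
            raise ModelParameterError(f"{name} must be non-empty positive integers")
        if np.any(np.diff(axis) <= 0):
            raise ModelParameterError(f"{name} must be strictly ascending")

    ks = np.arange(c_thresh + 1)
    mat = np.zeros((t_samp_axis.size, t_read_axis.size))
    if f_body > 0.0:
        for i, t_samp in enumerate(t_samp_axis):
            sctx = SamplingContext(f_body, int(t_samp))
            support = truncated_sampling_support(sctx, rel_threshold=rel_threshold)
            for j, t_read in enumerate(t_read_axis):
                rctx = SequencingContext(int(t_read), c_thresh)
                pmf = marginal_read_pmf(ks, sctx, rctx, params, support=support)
                mat[i, j] = min(1.0, max(0.0, 1.0 - pmf.sum()))
    return PowerGrid(t_samp_axis, t_read_axis, mat, f_body, c_thresh, params)


def contour_crossings(grid: PowerGrid, level: float = 0.95) -> np.ndarray:
    """Read depth at which each grid row first crosses ``level``.

    Linear interpolation between grid nodes on the log read-depth axis;
    ``nan`` where the row never reaches the level. The crossing depth is
    non-increasing down the rows of a valid monotone grid (the rounded-corner
    shape of the 95% detection region).
    """
    out = np.full(grid.t_samp_axis.size, np.nan)
    log_reads = np.log(grid.t_read_axis.astype(float))
    for i, row in enumerate(grid.power):
        idx = np.nonzero(row >= level)[0]
        if idx.size == 0:
            continue
        j = idx[0]
        if j == 0 or row[j] == row[j - 1]:
            out[i] = grid.t_read_axis[j]
        else:
            frac = (level - row[j - 1]) / (row[j] - row[j - 1])
            out[i] = math.exp(log_reads[j - 1] + frac * (log_reads[j] - log_reads[j - 1]))
    return out
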