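"""Short-term largest Lyapunov exponent of trunk acceleration.

Twenty retained strides are time-normalized to 100 points each (2000-point
series, unfiltered), delay-embedded with a delay from the first minimum of
the average mutual information (searched over 7..18 samples) and a
dimension from the false-nearest-neighbour criterion (max 10), and the
exponent is the least-squares slope of the mean log divergence of
initially nearest trajectory pairs over the first half normalized stride,
expressed per stride (slope per sample x 100).

Nearest-neighbour searches are exact (full distance matrix for the
divergence curve, k-d tree for the false-nearest-neighbour scan) for
bit-level reproducibility at these series lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateSeriesError,
    EstimationError,
    InsufficientStridesError,
    LengthError,
)
from .gait_events import GaitEvents
from .io_config import AccelTrace, RunConfig

logger = logging.getLogger("trunkgait")


@dataclass
class EmbeddingParams:
    tau: int
    m: int
    theiler: int

    def __post_init__(self) -> None:
        if self.tau < 1 or self.m < 1 or self.theiler < 0:
            raise ValueError("invalid embedding parameters")


@dataclass
class DivergenceCurve:
    """Mean log separation of initially nearest pairs vs. step offset."""

    offsets: np.ndarray
    mean_log_dist: np.ndarray
    fit_slice: slice
    slope_per_sample: float


# ---------------------------------------------------------------------------
# time normalization
# ---------------------------------------------------------------------------

def time_normalize(
    x: np.ndarray,
    stride_windows: list[tuple[float, float]],
    fs: float,
    n_strides: int = 20,
    points: int = 100,
) -> np.ndarray:
    """Resample the first ``n_strides`` stride windows to ``points`` each.

    Linear-time interpolation on the raw (unfiltered) samples; output length
    is exactly ``n_strides * points``.
    """
    if len(stride_windows) < n_strides:
        raise InsufficientStridesError(len(stride_windows), n_strides)
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x)) / fs
    out = np.empty(n_strides * points)
    for k, (t0, t1) in enumerate(stride_windows[:n_strides]):
        grid = t0 + (t1 - t0) * np.arange(points) / points
        out[k * points : (k + 1) * points] = np.interp(grid, t, x)
    return out


# ---------------------------------------------------------------------------
# embedding parameters
# ---------------------------------------------------------------------------

def average_mutual_information(x: np.ndarray, lag: int, n_bins: int | None = None) -> float:
    """AMI between the series and its ``lag``-shifted copy (nats).

    Equiprobable (quantile) binning with ceil(sqrt(N/5)) bins by default.
    """
    x = np.asarray(x, dtype=float)
    n = len(x) - lag
    if n < 10:
        raise LengthError("series too short for this lag")
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(len(x) / 5)))
    a, b = x[:-lag], x[lag:]
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def ami_delay(x: np.ndarray, lag_min: int = 7, lag_max: int = 18) -> int:
    """First local minimum of the AMI in ``[lag_min, lag_max]``.

    If no interior local minimum exists in the search range, falls back to
    the argmin of the AMI over the range (documented fallback).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 500:
        raise LengthError(f"series of {len(x)} samples < 500")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series has no AMI structure")
    lags = np.arange(max(1, lag_min - 1), lag_max + 2)
    ami = np.array([average_mutual_information(x, int(k)) for k in lags])
    for i in range(1, len(lags) - 1):
        k = int(lags[i])
        if lag_min <= k <= lag_max and ami[i] < ami[i - 1] and ami[i] <= ami[i + 1]:
            return k
    in_range = (lags >= lag_min) & (lags <= lag_max)
    fallback = int(lags[in_range][np.argmin(ami[in_range])])
    logger.debug("no local AMI minimum in [%d, %d]; falling back to argmin=%d",
                 lag_min, lag_max, fallback)
    return fallback


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n < 1:
        raise LengthError("series too short to embed")
    return np.stack([x[i * tau : i * tau + n] for i in range(m)], axis=1)


def fnn_dimension(
    x: np.ndarray,
    tau: int,
    max_m: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
) -> int:
    """Smallest embedding dimension with < ``threshold`` false nearest neighbours.

    Kennel's two criteria: distance-ratio test against ``rtol`` and
    attractor-size test against ``atol`` (relative to the series SD).
    Returns ``max_m`` with a warning if the fraction never drops below the
    threshold (e.g. for stochastic series).
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series")
    if len(x) < (max_m - 1) * tau + 100:
        raise LengthError("series too short for FNN up to max_m")
    ra = float(np.std(x))
    for m in range(1, max_m):
        y = _embed(x, m, tau)
        n = len(y) - tau  # need x[i + m*tau] for the (m+1)-th coordinate
        if n < 10:
            break
        y = y[:n]
        d_m, nn = cKDTree(y).query(y, k=2)  # exact; first hit is the point itself
        d_m, nn = d_m[:, 1], nn[:, 1]
        extra = np.abs(x[np.arange(n) + m * tau] - x[nn + m * tau])
        d_m = np.maximum(d_m, 1e-12 * ra)
        d_m1 = np.sqrt(d_m ** 2 + extra ** 2)
        false = (extra / d_m > rtol) | (d_m1 / ra > atol)
        # fewer than `threshold` neighbours unfold when adding the next
        # coordinate: dimension m is already sufficient
        if np.mean(false) < threshold:
            return max(m, 2)
    logger.warning("FNN fraction never below %.1f%%; returning max_m=%d",
                   100 * threshold, max_m)
    return max_m


# ---------------------------------------------------------------------------
# Rosenstein short-series exponent
# ---------------------------------------------------------------------------

def divergence_curve(
    x: np.ndarray,
    tau: int,
    m: int,
    theiler: int = 100,
    max_offset: int = 50,
) -> DivergenceCurve:
    """Mean log divergence of initially nearest pairs (Rosenstein).

    Each embedded point is paired with its nearest neighbour at least
    ``theiler`` samples away in time; the curve is the mean natural log of
    pair distances after 0..``max_offset`` steps, over the pairs still
    defined at each offset.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series")
    y = _embed(x, m, tau)
    n = len(y)
    if n < 300:
        raise EstimationError(f"embedded trajectory of {n} points < 300")
    dist = cdist(y, y)
    i_idx = np.arange(n)
    band = np.abs(i_idx[:, None] - i_idx[None, :]) <= theiler
    dist[band] = np.inf
    nn = np.argmin(dist, axis=1)
    if not np.all(np.isfinite(dist[i_idx, nn])):
        raise EstimationError("no admissible neighbours outside the Theiler window")

    offsets = np.arange(max_offset + 1)
    mean_log = np.full(len(offsets), np.nan)
    # distances are floored relative to the attractor scale so that exact
    # repeats (perfectly periodic series) sit on a constant floor and yield
    # zero slope instead of amplified floating-point noise
    tiny = 1e-9 * float(np.std(x))
    for k in offsets:
        valid = (i_idx + k < n) & (nn + k < n)
        if valid.sum() < 10:
            break
        d = np.linalg.norm(y[i_idx[valid] + k] - y[nn[valid] + k], axis=1)
        mean_log[k] = float(np.mean(np.log(np.maximum(d, tiny))))
    good = np.isfinite(mean_log)
    if good.sum() < 5:
        raise EstimationError("too few valid offsets for a slope fit")
    fit = slice(0, int(np.max(offsets[good])) + 1)
    slope = float(np.polyfit(offsets[fit][good[fit]], mean_log[fit][good[fit]], 1)[0])
    return DivergenceCurve(offsets=offsets, mean_log_dist=mean_log,
                           fit_slice=fit, slope_per_sample=slope)


def rosenstein_slle(
    x: np.ndarray,
    tau: int,
    m: int,
    theiler: int = 100,
    max_offset: int = 50,
) -> float:
    """Largest Lyapunov exponent per sample (slope of the divergence curve)."""
    return divergence_curve(x, tau, m, theiler, max_offset).slope_per_sample


def walk_slle(
    trace: AccelTrace,
    events: GaitEvents,
    config: RunConfig | None = None,
    axes: tuple[str, ...] = ("AP", "ML", "V"),
) -> tuple[dict[str, float], dict[str, EmbeddingParams]]:
    """Per-axis short-term Lyapunov exponent, per normalized stride.

    Returns ``(lambdas, embeddings)`` where ``lambdas[axis]`` is the slope
    per sample times ``points_per_stride`` and ``embeddings`` records the
    delay and dimension chosen per axis.
    """
    config = config or RunConfig(fs=trace.fs)
    pts = config.points_per_stride
    max_offset = int(round(config.fit_window * pts))
    lambdas: dict[str, float] = {}
    params: dict[str, EmbeddingParams] = {}
    for ax in axes:
        series = time_normalize(trace.axis(ax), events.stride_windows, trace.fs,
                                n_strides=config.slle_strides, points=pts)
        tau = ami_delay(series, config.delay_min, config.delay_max)
        m = fnn_dimension(series, tau, config.fnn_max_dim,
                          config.fnn_rtol, config.fnn_atol)
        slope = rosenstein_slle(series, tau, m, theiler=config.theiler,
                                max_offset=max_offset)
        lambdas[ax] = slope * pts
        params[ax] = EmbeddingParams(tau=tau, m=m, theiler=config.theiler)
    return lambdas, params
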