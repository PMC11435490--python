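"""Gait-event detection from the vertical trunk acceleration.

The chain is: linear detrend -> zero-phase FIR low-pass at 3.2 Hz ->
numerical integration -> differentiation by a Gaussian first-derivative
continuous wavelet (scale 9 at 100 Hz).  Initial contacts are the dominant
extrema of the resulting signal between its successive zero-crossings (one
per step), refined to sub-sample precision.  Final contacts come from a
separate, lightly filtered copy of the vertical axis (the 3.2 Hz event band
cannot separate a toe-off trough from the neighbouring contact peak); see
:func:`detect_final_contacts`.  Side labels come from the sign of the
medio-lateral acceleration over the step following each initial contact.

The integrate-then-CWT-differentiate chain is, up to the wavelet smoothing,
an identity on the filtered signal, so the event signal tracks the filtered
vertical acceleration; the ``ic_polarity`` config flag selects whether
initial contacts are its maxima (default, ``"positive"``) or minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, signal

from .errors import (
    InsufficientGaitError,
    InsufficientStridesError,
    LabellingError,
    LengthError,
)
from .io_config import AccelTrace, RunConfig

logger = logging.getLogger("trunkgait")

#: maximum coefficient of variation of step intervals before a detection is
#: declared non-gait (regularity check; white noise fails it)
_MAX_STEP_CV = 0.45

#: extrema smaller than this fraction of the lower-quartile extremum are
#: ripple; anchoring on the lower quartile keeps the weak-step mode of a
#: strongly asymmetric gait while rejecting edge artifacts and noise blips
_MIN_PEAK_FRACTION = 0.30

#: the final contact is searched in the first part of the IC-to-IC interval
#: only (terminal double support ends well before midswing)
_FC_SEARCH_FRACTION = 0.45


@dataclass
class GaitEvents:
    """Initial/final contact times (s), side labels and retained stride windows."""

    ic_times: np.ndarray
    ic_sides: list[str]
    fc_times: np.ndarray
    fc_sides: list[str]
    stride_windows: list[tuple[float, float]] = field(default_factory=list)
    n_detected_strides: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        if np.any(np.diff(self.ic_times) <= 0):
            raise ValueError("ic_times must be strictly increasing")


@dataclass
class TemporalParams:
    """Per-side temporal gait parameters (s, means over retained strides)."""

    stride_time: float
    gait_speed: float
    stance: dict[str, float]
    swing: dict[str, float]
    double_support: dict[str, float]
    single_support: dict[str, float]

    def side_value(self, param: str, side: str) -> float:
        return getattr(self, param)[side]


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def preprocess_vertical(v: np.ndarray, fs: float, cutoff: float = 3.2,
                        order: int = 128) -> np.ndarray:
    """Detrend and zero-phase FIR low-pass the vertical acceleration.

    Hamming-window FIR of the given order applied forward-backward, so event
    times carry no group delay.  Requires ``len(v) >= 4 * order``.
    """
    v = np.asarray(v, dtype=float)
    if len(v) < 4 * order:
        raise LengthError(f"signal of {len(v)} samples < 4x filter order {order}")
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    detrended = signal.detrend(v, type="linear")
    taps = signal.firwin(order + 1, cutoff, fs=fs, window="hamming")
    return signal.filtfilt(taps, [1.0], detrended)


def gaus1_cwt(x: np.ndarray, scale: float) -> np.ndarray:
    """Continuous wavelet transform with the first-derivative-of-Gaussian wavelet.

    Convolving with the derivative of a Gaussian yields the smoothed first
    derivative of ``x``; the kernel is antisymmetric so there is no phase
    shift.  Same-length output, edges handled by zero extension.
    """
    half = int(np.ceil(5 * scale))
    u = np.arange(-half, half + 1, dtype=float)
    kernel = -u * np.exp(-(u ** 2) / (2.0 * scale ** 2))
    kernel /= np.sqrt(scale)
    # np.convolve flips the second argument, so passing the Gaussian
    # derivative directly yields (G' * x) = d/dt (G * x): the smoothed
    # derivative with positive sign.
    return np.convolve(x, kernel, mode="same")


def event_signal(v: np.ndarray, fs: float, config: RunConfig | None = None) -> np.ndarray:
    """Preprocess, integrate and CWT-differentiate the vertical axis."""
    config = config or RunConfig(fs=fs)
    pre = preprocess_vertical(v, fs, config.event_cutoff_hz, config.fir_order)
    integ = integrate.cumulative_trapezoid(pre, dx=1.0 / fs, initial=0.0)
    integ = signal.detrend(integ, type="linear")
    return gaus1_cwt(integ, config.cwt_scale)


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def _refine_extremum(d: np.ndarray, i: int) -> float:
    """Sub-sample extremum location by parabolic interpolation around ``i``."""
    if i <= 0 or i >= len(d) - 1:
        return float(i)
    denom = d[i - 1] - 2.0 * d[i] + d[i + 1]
    if denom == 0:
        return float(i)
    delta = 0.5 * (d[i - 1] - d[i + 1]) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


def _segment_extrema(d: np.ndarray, want_max: bool) -> tuple[np.ndarray, np.ndarray]:
    """Dominant extremum of each constant-sign segment between zero-crossings.

    Returns sub-sample extremum positions (parabolic refinement) and their
    magnitudes.
    """
    change = np.flatnonzero(np.diff(np.signbit(d)))
    bounds = np.concatenate(([0], change + 1, [len(d)]))
    idx, val = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = d[lo:hi]
        if len(seg) == 0:
            continue
        if want_max and seg.max() > 0:
            i = lo + int(np.argmax(seg))
            idx.append(_refine_extremum(d, i))
            val.append(seg.max())
        elif not want_max and seg.min() < 0:
            i = lo + int(np.argmin(seg))
            idx.append(_refine_extremum(d, i))
            val.append(-seg.min())
    return np.asarray(idx, dtype=float), np.asarray(val, dtype=float)


def detect_initial_contacts(
    v: np.ndarray, fs: float, config: RunConfig | None = None
) -> np.ndarray:
    """Detect initial-contact times (s) from the raw vertical acceleration.

    Raises :class:`InsufficientGaitError` when fewer than five plausible
    steps are found or when step intervals are too irregular to be gait.
    """
    config = config or RunConfig(fs=fs)
    d = event_signal(v, fs, config)
    if np.allclose(d, 0.0):
        raise InsufficientGaitError("flat event signal; no gait detected")
    n_zc = np.count_nonzero(np.diff(np.signbit(d)))
    if n_zc < 5:
        raise InsufficientGaitError(f"only {n_zc} zero-crossings in event signal")

    want_max = config.ic_polarity == "positive"
    idx, mag = _segment_extrema(d, want_max=want_max)
    if len(idx) == 0:
        raise InsufficientGaitError("no candidate extrema")
    keep = mag >= _MIN_PEAK_FRACTION * np.percentile(mag, 25)
    idx = idx[keep]
    if len(idx) < 5:
        raise InsufficientGaitError(f"only {len(idx)} candidate steps detected")

    # discard events within half a mean step of either edge
    mean_step = float(np.mean(np.diff(idx)))
    lo, hi = 0.5 * mean_step, len(v) - 1 - 0.5 * mean_step
    idx = idx[(idx >= lo) & (idx <= hi)]
    if len(idx) < 5:
        raise InsufficientGaitError(f"only {len(idx)} steps after edge trimming")

    intervals = np.diff(idx)
    cv = float(np.std(intervals) / np.mean(intervals))
    if cv > _MAX_STEP_CV:
        raise InsufficientGaitError(
            f"step intervals too irregular for gait (CV={cv:.2f} > {_MAX_STEP_CV})"
        )
    return idx / fs


def assign_sides(
    ic_times: np.ndarray,
    ml: np.ndarray,
    fs: float,
    ml_left_positive: bool = True,
) -> tuple[list[str], list[str]]:
    """Label each initial contact left/right from medio-lateral polarity.

    The medio-lateral acceleration is averaged over (most of) one step
    after each contact -- a window over which stride-symmetric (even
    harmonic) sway integrates to about zero, leaving the step-alternating
    component.  Alternation is enforced and, when more than 20 % of steps
    contradict a strictly alternating pattern, a side-ambiguity warning is
    emitted and labels fall back to pure alternation anchored on the
    majority phase.

    Returns ``(labels, warnings)``.
    """
    ic_times = np.asarray(ic_times, dtype=float)
    if len(ic_times) < 2:
        raise InsufficientGaitError("need at least 2 initial contacts to assign sides")
    warnings: list[str] = []
    mean_step = float(np.mean(np.diff(ic_times)))
    win = max(1, int(round(0.9 * mean_step * fs)))
    ml = np.asarray(ml, dtype=float)
    ml = ml - np.mean(ml)

    polarity = np.zeros(len(ic_times))
    for k, t in enumerate(ic_times):
        i0 = int(round(t * fs))
        seg = ml[i0 : i0 + win]
        polarity[k] = np.mean(seg) if len(seg) else 0.0

    if np.allclose(polarity, 0.0):
        warnings.append("side-ambiguity: ML axis flat; labels assigned by alternation")
        first_left = True
    else:
        signs = np.sign(polarity)
        # fraction of consecutive pairs that do NOT alternate
        bad = np.mean(signs[:-1] == signs[1:])
        if bad > 0.20:
            warnings.append(
                f"side-ambiguity: {bad:.0%} of steps non-alternating; "
                "labels assigned by strict alternation from the first step"
            )
        # majority vote for the phase: which parity is predominantly positive
        even_mean = np.mean(polarity[0::2])
        odd_mean = np.mean(polarity[1::2])
        first_positive = even_mean >= odd_mean
        first_left = first_positive == ml_left_positive
    labels = []
    for k in range(len(ic_times)):
        left = first_left if k % 2 == 0 else not first_left
        labels.append("left" if left else "right")
    for w in warnings:
        logger.warning(w)
    return labels, warnings


def detect_final_contacts(
    v: np.ndarray,
    fs: float,
    ic_times: np.ndarray,
    ic_sides: list[str],
    config: RunConfig | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Locate one final contact between each pair of initial contacts.

    Final contacts cannot be resolved on the 3.2 Hz event signal (the
    toe-off trough sits closer to the neighbouring contact peak than that
    band can separate), so this heuristic works on a lightly filtered copy
    of the vertical acceleration (zero-phase Butterworth at
    ``fc_cutoff_hz``): the final contact in ``(IC_i, IC_{i+1})`` is its
    deepest negative trough, and belongs to the foot contralateral to
    ``IC_i`` (whose stance began one step earlier).  Intervals without a
    negative trough are skipped with a warning.

    Returns ``(fc_times, fc_sides, warnings)``.
    """
    config = config or RunConfig(fs=fs)
    sos = signal.butter(4, config.fc_cutoff_hz, btype="lowpass", fs=fs, output="sos")
    smooth = signal.sosfiltfilt(sos, signal.detrend(np.asarray(v, float), type="linear"))
    sign = 1.0 if config.ic_polarity == "positive" else -1.0
    smooth = sign * smooth
    warnings: list[str] = []
    fc_times, fc_sides = [], []
    other = {"left": "right", "right": "left"}
    for i in range(len(ic_times) - 1):
        lo = int(round(ic_times[i] * fs)) + 1
        hi = int(round(ic_times[i + 1] * fs))
        hi = lo + max(2, int(round(_FC_SEARCH_FRACTION * (hi - lo))))
        seg = smooth[lo:hi]
        if len(seg) == 0 or seg.min() >= 0:
            warnings.append(f"no final-contact trough between ICs {i} and {i + 1}")
            continue
        j = lo + int(np.argmin(seg))
        fc_times.append(_refine_extremum(smooth, j) / fs)
        fc_sides.append(other[ic_sides[i]])
    for w in warnings:
        logger.warning(w)
    return np.asarray(fc_times), fc_sides, warnings


def segment_and_trim(
    ic_times: np.ndarray,
    config: RunConfig | None = None,
) -> tuple[list[tuple[float, float]], int]:
    """Build stride windows (same-foot IC to IC), trim head/tail, enforce minimum.

    Strides are anchored on the first detected foot: window ``k`` spans
    ``IC[2k] .. IC[2k+2]``.  The first and last ``trim_strides`` windows are
    removed and at least ``min_strides`` must remain.

    Returns ``(stride_windows, n_detected_strides)``.
    """
    config = config or RunConfig()
    ic_times = np.asarray(ic_times, dtype=float)
    n_strides = (len(ic_times) - 1) // 2
    windows = [(float(ic_times[2 * k]), float(ic_times[2 * k + 2])) for k in range(n_strides)]
    t = config.trim_strides
    retained = windows[t : len(windows) - t if t else None]
    if len(retained) < config.min_strides:
        raise InsufficientStridesError(len(retained), config.min_strides)
    return retained, n_strides


def detect_events(trace: AccelTrace, config: RunConfig | None = None) -> GaitEvents:
    """Full event chain: ICs, sides, FCs and trimmed stride windows."""
    config = config or RunConfig(fs=trace.fs)
    ic_times = detect_initial_contacts(trace.v, trace.fs, config)
    ic_sides, w1 = assign_sides(ic_times, trace.ml, trace.fs)
    fc_times, fc_sides, w2 = detect_final_contacts(trace.v, trace.fs, ic_times, ic_sides, config)
    windows, n_detected = segment_and_trim(ic_times, config)
    return GaitEvents(
        ic_times=ic_times,
        ic_sides=ic_sides,
        fc_times=fc_times,
        fc_sides=fc_sides,
        stride_windows=windows,
        n_detected_strides=n_detected,
        warnings=w1 + w2,
    )


# ---------------------------------------------------------------------------
# temporal parameters
# ---------------------------------------------------------------------------

def temporal_parameters(
    events: GaitEvents,
    walk_distance: float = 30.0,
    speed_mode: str = "corridor",
) -> TemporalParams:
    """Per-side temporal means over the retained strides, plus gait speed.

    stance(side) = FC(side) - preceding IC(side); swing = stride - stance;
    initial double support after IC(side) = contralateral FC - IC(side);
    single support(side) = contralateral swing.  Gait speed defaults to
    walk distance over the full (untrimmed) IC span.
    """
    if not events.stride_windows:
        raise InsufficientStridesError(0, 1)
    t_lo = events.stride_windows[0][0]
    t_hi = events.stride_windows[-1][1]

    ic_t, ic_s = events.ic_times, events.ic_sides
    fc_t, fc_s = events.fc_times, events.fc_sides

    stride_times: dict[str, list[float]] = {"left": [], "right": []}
    for side in ("left", "right"):
        ts = np.array([t for t, s in zip(ic_t, ic_s) if s == side])
        ts = ts[(ts >= t_lo - 1e-9) & (ts <= t_hi + 1e-9)]
        stride_times[side] = list(np.diff(ts))

    stance: dict[str, list[float]] = {"left": [], "right": []}
    dsup: dict[str, list[float]] = {"left": [], "right": []}
    other = {"left": "right", "right": "left"}
    for t_fc, s_fc in zip(fc_t, fc_s):
        if not (t_lo - 1e-9 <= t_fc <= t_hi + 1e-9):
            continue
        prior = [t for t, s in zip(ic_t, ic_s) if s == s_fc and t < t_fc]
        if prior:
            stance[s_fc].append(t_fc - prior[-1])
        # the same FC terminates the double support opened by the last
        # contralateral IC
        prior_contra = [t for t, s in zip(ic_t, ic_s) if s == other[s_fc] and t < t_fc]
        if prior_contra:
            dsup[other[s_fc]].append(t_fc - prior_contra[-1])

    def _mean(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else float("nan")

    stride_mean = _mean(stride_times["left"] + stride_times["right"])
    stance_m = {s: _mean(stance[s]) for s in ("left", "right")}
    stride_m = {s: _mean(stride_times[s]) for s in ("left", "right")}
    swing_m = {s: stride_m[s] - stance_m[s] for s in ("left", "right")}
    dsup_m = {s: _mean(dsup[s]) for s in ("left", "right")}
    ssup_m = {s: swing_m[other[s]] for s in ("left", "right")}

    # corridor distance over the full (untrimmed) contact span; a per-stride
    # spatial estimate would need a sensor-fusion step-length model, which is
    # out of scope, so every mode currently reduces to the corridor estimate
    duration = float(ic_t[-1] - ic_t[0])
    speed = walk_distance / duration
    if not 0 < speed < 3:
        logger.warning("gait speed %.2f m/s outside the 0-3 m/s sanity bound", speed)
    return TemporalParams(
        stride_time=stride_mean,
        gait_speed=speed,
        stance=stance_m,
        swing=swing_m,
        double_support=dsup_m,
        single_support=ssup_m,
    )


def paretic_value(params: TemporalParams, param: str, paretic_side: str) -> tuple[float, float]:
    """Return (paretic, non-paretic) mean durations for one parameter."""
    if paretic_side not in ("left", "right"):
        raise LabellingError("paretic side unknown; cannot produce paretic-referenced values")
    other = "right" if paretic_side == "left" else "left"
    d = getattr(params, param)
    return d[paretic_side], d[other]
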