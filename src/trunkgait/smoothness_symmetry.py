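"""Movement smoothness (log-dimensionless jerk) and temporal symmetry indexes.

The log-dimensionless jerk of an acceleration segment is

    ldlj = -ln[ (t2 - t1) / a_peak^2 * integral_{t1}^{t2} (da/dt)^2 dt ]

with ``a_peak = max |a|`` over the segment: a scale-free, negative number
that moves toward zero for smoother movement.  The first time derivative of
acceleration (jerk) makes the argument dimensionless, which the peak-based
normalization requires.

The symmetry index of a temporal gait parameter is the paretic minus
non-paretic mean over their average, in percent; it is antisymmetric under
side swap and bounded in (-200, 200).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .errors import DomainError, LabellingError
from .gait_events import GaitEvents, TemporalParams, paretic_value
from .io_config import AccelTrace, RunConfig

logger = logging.getLogger("trunkgait")

SI_PARAMS = ("stance", "swing", "double_support", "single_support")


def ldlj(
    a: np.ndarray,
    fs: float,
    t1: float | None = None,
    t2: float | None = None,
    cutoff: float = 20.0,
    order: int = 4,
    prefilter: bool = True,
) -> float:
    """Log-dimensionless jerk of an acceleration segment.

    The whole signal is low-pass filtered (zero-phase Butterworth, 20 Hz
    default) before the segment ``[t1, t2]`` is cut; jerk uses central
    differences and the integral the trapezoid rule.
    """
    a = np.asarray(a, dtype=float)
    if prefilter:
        sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
        a = signal.sosfiltfilt(sos, a)
    i0 = 0 if t1 is None else int(round(t1 * fs))
    i1 = len(a) if t2 is None else int(round(t2 * fs)) + 1
    seg = a[i0:i1]
    if len(seg) < 3:
        raise DomainError("segment too short for a jerk estimate")
    a_peak = float(np.max(np.abs(seg)))
    if a_peak == 0:
        raise DomainError("degenerate segment: a_peak = 0")
    dt = 1.0 / fs
    jerk = np.gradient(seg, dt)
    integral = float(np.trapezoid(jerk ** 2, dx=dt))
    duration = (len(seg) - 1) * dt
    return -float(np.log(duration / a_peak ** 2 * integral))


def symmetry_index(v_paretic: float, v_nonparetic: float) -> float:
    """Percent symmetry index (Vp - Vnp) / (0.5 (Vp + Vnp)) * 100."""
    if not (v_paretic > 0 and v_nonparetic > 0):
        raise DomainError("symmetry index needs strictly positive durations")
    return (v_paretic - v_nonparetic) / (0.5 * (v_paretic + v_nonparetic)) * 100.0


def walk_smoothness_symmetry(
    trace: AccelTrace,
    events: GaitEvents,
    temporal: TemporalParams,
    paretic_side: str = "none",
    config: RunConfig | None = None,
) -> dict[str, float]:
    """LDLJ per axis over the retained-stride span plus the four SIs.

    Symmetry indexes are omitted (NaN, with a warning) when the paretic
    side is unknown, as for healthy subjects.
    """
    config = config or RunConfig(fs=trace.fs)
    t1 = events.stride_windows[0][0]
    t2 = events.stride_windows[-1][1]
    out: dict[str, float] = {}
    for ax in ("V", "ML", "AP"):
        out[f"ldlj_{ax.lower()}"] = ldlj(
            trace.axis(ax), trace.fs, t1, t2,
            cutoff=config.ldlj_cutoff_hz, order=config.ldlj_order,
        )
    names = {"stance": "si_stance", "swing": "si_swing",
             "double_support": "si_double", "single_support": "si_single"}
    if paretic_side in ("left", "right"):
        for param, col in names.items():
            try:
                vp, vnp = paretic_value(temporal, param, paretic_side)
                out[col] = symmetry_index(vp, vnp)
            except (DomainError, LabellingError) as exc:
                logger.warning("SI %s unavailable: %s", param, exc)
                out[col] = float("nan")
    else:
        logger.info("paretic side unknown for %s; symmetry indexes omitted",
                    trace.subject_id)
        for col in names.values():
            out[col] = float("nan")
    return out
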