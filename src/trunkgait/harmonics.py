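"""Per-stride harmonic ratios of trunk acceleration.

Each retained stride is Fourier-analysed on its exact window, so the first
20 multiples of the stride frequency fall exactly on DFT bins.  For the
anterior-posterior and vertical axes the harmonic ratio is the summed
amplitude of the first ten even harmonics over the first ten odd ones
(even harmonics are stride-symmetric: two steps per stride); the
medio-lateral axis uses the reciprocal convention (odd over even), because
medio-lateral sway alternates with each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import EmptyResultError
from .gait_events import GaitEvents
from .io_config import AccelTrace, RunConfig

logger = logging.getLogger("trunkgait")

#: denominator floor and result cap for degenerate spectra
EPS_FLOOR = 1e-12
HR_CAP = 1e6

#: minimum stride length (samples) for a 20-harmonic spectrum
MIN_STRIDE_SAMPLES = 40


@dataclass
class HarmonicSpectrum:
    """Amplitudes of the first ``n`` stride-frequency harmonics of one stride."""

    stride_id: int
    axis: str
    amplitudes: np.ndarray  # index k-1 holds harmonic k, k = 1..n

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < 0):
            raise ValueError("harmonic amplitudes must be non-negative")


@dataclass
class HRResult:
    """Per-stride harmonic ratios and their walk-level mean/SD per axis."""

    per_stride: dict[str, np.ndarray]
    mean: dict[str, float]
    sd: dict[str, float]
    n_strides: int


def stride_spectrum(segment: np.ndarray, n_harmonics: int = 20,
                    stride_id: int = 0, axis: str = "V") -> HarmonicSpectrum | None:
    """DFT amplitudes at the first ``n_harmonics`` multiples of the stride frequency.

    The segment is one stride, analysed at its native length (no zero
    padding, no taper) so harmonic ``k`` sits exactly on bin ``k``.
    Amplitudes are sinusoid amplitudes (2|X_k|/N).  Returns ``None`` (with a
    warning) for strides shorter than ``2 * n_harmonics`` samples, which
    cannot resolve the requested harmonics.
    """
    segment = np.asarray(segment, dtype=float)
    n = len(segment)
    if n < 2 * n_harmonics:
        logger.warning("stride %d (%s): %d samples < %d; skipped",
                       stride_id, axis, n, 2 * n_harmonics)
        return None
    spec = np.fft.rfft(segment - np.mean(segment))
    amps = 2.0 * np.abs(spec[1 : n_harmonics + 1]) / n
    return HarmonicSpectrum(stride_id=stride_id, axis=axis, amplitudes=amps)


def harmonic_ratio(spectrum: HarmonicSpectrum | np.ndarray, axis: str) -> float:
    """Harmonic ratio of one stride spectrum under the per-axis convention.

    AP/V: sum of even-harmonic amplitudes over sum of odd; ML: odd over
    even.  The denominator is floored at ``EPS_FLOOR`` and the result capped
    at ``HR_CAP`` so degenerate spectra stay finite.
    """
    amps = spectrum.amplitudes if isinstance(spectrum, HarmonicSpectrum) else np.asarray(spectrum, float)
    odd = float(np.sum(amps[0::2]))   # harmonics 1, 3, 5, ...
    even = float(np.sum(amps[1::2]))  # harmonics 2, 4, 6, ...
    if axis.upper() == "ML":
        num, den = odd, even
    else:
        num, den = even, odd
    return min(num / max(den, EPS_FLOOR), HR_CAP)


def _filter_axis(x: np.ndarray, fs: float, config: RunConfig) -> np.ndarray:
    if config.hr_filter_kind == "none":
        return np.asarray(x, dtype=float)
    sos = signal.butter(4, config.hr_cutoff_hz, btype=config.hr_filter_kind,
                        fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def walk_hr(trace: AccelTrace, events: GaitEvents, config: RunConfig | None = None) -> HRResult:
    """Harmonic ratios per stride and axis, averaged over the walk.

    The whole trace is filtered once (20 Hz low-pass by default) before
    stride segmentation; strides too short for the spectrum are excluded
    from the averages.
    """
    config = config or RunConfig(fs=trace.fs)
    per_stride: dict[str, list[float]] = {"AP": [], "ML": [], "V": []}
    filtered = {a: _filter_axis(trace.axis(a), trace.fs, config) for a in ("AP", "ML", "V")}
    n_used = 0
    for sid, (t0, t1) in enumerate(events.stride_windows):
        i0, i1 = int(round(t0 * trace.fs)), int(round(t1 * trace.fs))
        used = False
        for ax in ("AP", "ML", "V"):
            spec = stride_spectrum(filtered[ax][i0:i1], config.n_harmonics, sid, ax)
            if spec is None:
                continue
            per_stride[ax].append(harmonic_ratio(spec, ax))
            used = True
        n_used += used
    if n_used == 0:
        raise EmptyResultError("all strides skipped; no harmonic ratios computed")
    arr = {ax: np.asarray(v) for ax, v in per_stride.items()}
    return HRResult(
        per_stride=arr,
        mean={ax: float(np.mean(v)) for ax, v in arr.items()},
        sd={ax: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for ax, v in arr.items()},
        n_strides=n_used,
    )
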