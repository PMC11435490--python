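"""Synthetic lumbar-acceleration walks with analytic ground truth.

Signal family
-------------
Each axis of a walk is a stride-locked periodic template, warped stride by
stride in time (stride-time variability), scaled per stride (amplitude
jitter) and corrupted with additive white noise.  The template of one
stride (phase ``phi`` in [0, 1)) is

    f(phi) = sum_k a_k cos(2 pi k phi) + sum_k b_k sin(2 pi k phi) + bumps

with even-harmonic cosines, odd harmonics and wrapped-Gaussian bumps:
positive ones at the two initial contacts (phases 0 and 0.5 + delta) and,
on the vertical axis, negative valleys at the two final contacts.  Because
the harmonic amplitudes of this template are known in closed form (Gaussian
bumps have analytic Fourier coefficients), the ground-truth harmonic ratio
is exact, and one template parameter per axis is solved by bisection to hit
the requested ratio (vertical axis: the left/right contact-transient
asymmetry plus one high odd harmonic; ML and AP: the odd-sine scale).
Step-timing asymmetry ``delta`` and per-side stance fractions give exact
ground-truth event times and symmetry indexes.

Group presets are calibrated to the published cohort structure: mean
harmonic ratios per axis, gait speeds, and noise/variability levels that
order the short-term Lyapunov exponent across groups (sLLE ground truth is
ordinal by design).  SII subjects draw NLR >= 5 with probability 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_config import AccelTrace, SubjectRecord, write_accel_csv, write_cohort_manifest

_TWO_PI = 2.0 * np.pi

# fixed template shapes (relative amplitudes per harmonic index).  On the
# vertical axis the odd harmonics are cosines: symmetric about both step
# times, so asymmetric (odd) power does not displace the filtered-signal
# peaks the event detector relies on.
_EVEN_SHAPE = {2: 1.0, 4: 0.35, 6: 0.12}
# small symmetric-about-the-contacts odd cosines; the bulk of the V-axis odd
# power comes from left/right bump-height asymmetry (see _calibrate_v), which
# concentrates asymmetric power at the events without tilting the FC valleys
_ODD_FLOOR_V = {1: 0.06, 3: 0.05}
# the remaining odd power sits in one high harmonic: above the final-contact
# filter band (>= 10 Hz for stride times of 1.0-1.3 s) but inside the 20 Hz
# harmonic-ratio band, so it affects no event localization
_ODD_HIGH_V = 13
_ODD_SHAPE_ML = {1: 1.0, 3: 0.30, 5: 0.15}
_EVEN_SHAPE_ML = {2: 1.0, 4: 0.40}
_ODD_SHAPE_AP = {1: 0.45, 3: 0.30, 5: 0.20}

_IC_WIDTH = 0.045   # stride fractions; IC bumps narrow (impact transients),
_FC_WIDTH = 0.050   # FC valleys slightly wider
_IC_BUMP_V = 2.0    # m/s^2, positive, at initial contacts (vertical axis)
_FC_BUMP_V = 3.0    # m/s^2, negative valley, at final contacts (vertical axis)
_IC_BUMP_AP = 0.35

# the asymmetric (odd-harmonic) V-axis power is an antisymmetric pair of
# narrow transients at the two initial contacts: +beta at the left step,
# -beta at the right.  Such a pair has zero even-harmonic content, vanishes
# at the mid-step dips and at the toe-off valleys, and moves no extremum --
# it only makes one heel strike stronger than the other.
_ASYM_WIDTH = 0.020
_ASYM_BUMP_V = 2.0
_MAX_ASYM = 1.2

_AXIS_SCALE = {"V": 1.0, "ML": 0.8, "AP": 0.9}

# after harmonic-ratio calibration each axis template is rescaled to a fixed
# RMS (m/s^2): every downstream index is amplitude-invariant, and a constant
# noise-to-signal ratio keeps the stability exponent's response to the
# timing-noise knob independent of the harmonic-ratio target
_AXIS_RMS = {"V": 1.2, "ML": 0.9, "AP": 1.0}


@dataclass
class SyntheticSpec:
    """Full parameterization of one synthetic walk."""

    stride_time: float = 1.1
    n_strides: int = 26
    fs: float = 100.0
    hr_v: float = 2.0
    hr_ml: float = 1.8
    hr_ap: float = 1.9
    delta: float = 0.0            # step-timing asymmetry, fraction of a stride
    stance_left: float = 0.60     # stance fraction of the left foot
    stance_right: float = 0.60
    stride_cv: float = 0.0        # SD of stride time / stride time
    amp_jitter: float = 0.0       # SD of the per-stride amplitude factor
    shape_jitter: float = 0.0     # SD of per-stride, per-harmonic perturbations
    timing_jitter: float = 0.0    # SD (stride fraction) of within-stride phase
                                  # wobble, pinned at the contacts; the main
                                  # knob driving trajectory divergence
    baseline_jitter: float = 0.0  # SD of a per-stride DC offset (m/s^2); a
                                  # time-static floor the noise diverges from
    noise_sigma: dict = field(default_factory=lambda: {"V": 0.0, "ML": 0.0, "AP": 0.0})
    noise_corr: float = 10.0      # AR(1) correlation time of the noise, samples
    gait_speed: float = 0.75      # m/s, sets the walk distance
    paretic_side: str = "none"
    subject_id: str = "synthetic"
    timepoint: str = "T0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_time <= 0:
            raise ValueError("stride_time must be positive")
        if self.stride_cv < 0 or self.amp_jitter < 0 or self.shape_jitter < 0:
            raise ValueError("variability parameters must be non-negative")
        if abs(self.delta) >= 0.2:
            raise ValueError("|delta| must be < 0.2 strides")
        for s in (self.stance_left, self.stance_right):
            if not 0.5 + abs(self.delta) < s < 0.9:
                raise ValueError("stance fractions must lie in (0.5 + |delta|, 0.9)")
            # each toe-off must trail the contralateral contact by enough for
            # the valley to be a separable feature of the band-limited signal
            if s - 0.5 - abs(self.delta) < 0.085:
                raise ValueError(
                    "double support < 0.085 strides: toe-off valley would not "
                    "be detectable; increase stance fraction or reduce delta")
        if self.n_strides < 5:
            raise ValueError("need at least 5 strides")


@dataclass
class GroundTruth:
    """Exact event times and index values implied by a :class:`SyntheticSpec`."""

    ic_times: np.ndarray
    ic_sides: list[str]
    fc_times: np.ndarray
    fc_sides: list[str]
    hr: dict[str, float]
    si: dict[str, float]
    gait_speed: float
    stride_time: float
    n_strides: int
    walk_distance: float


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _bump_positions(spec: SyntheticSpec, axis: str, asym: float = 0.0,
                    fc_shift: tuple[float, float] = (0.0, 0.0),
                    ) -> list[tuple[float, float, float]]:
    """(phase, height, width) of the wrapped-Gaussian bumps for one axis.

    ``asym`` is the amplitude of the antisymmetric contact-transient pair
    on the vertical axis (stronger left heel strike, weaker right);
    ``fc_shift`` nudges the (left, right) toe-off valley centres so that
    the detectable valley of the band-limited signal coincides with the
    programmed final-contact truth.
    """
    ic_l, ic_r = 0.0, 0.5 + spec.delta
    if axis == "V":
        fc_l = spec.stance_left + fc_shift[0]             # left FC, in (ic_r, 1)
        fc_r = (ic_r + spec.stance_right) % 1.0 + fc_shift[1]  # right FC, in (0, ic_r)
        bumps = [(ic_l, _IC_BUMP_V, _IC_WIDTH), (ic_r, _IC_BUMP_V, _IC_WIDTH),
                 (fc_l, -_FC_BUMP_V, _FC_WIDTH), (fc_r, -_FC_BUMP_V, _FC_WIDTH)]
        if asym > 0:
            bumps += [(ic_l, asym * _ASYM_BUMP_V, _ASYM_WIDTH),
                      (ic_r, -asym * _ASYM_BUMP_V, _ASYM_WIDTH)]
        return bumps
    if axis == "AP":
        return [(ic_l, _IC_BUMP_AP, _IC_WIDTH), (ic_r, _IC_BUMP_AP, _IC_WIDTH)]
    return []


def _axis_coeffs(spec: SyntheticSpec, axis: str) -> tuple[dict, dict]:
    """(even shape, odd shape) for the sine-styled ML and AP axes."""
    scale = _AXIS_SCALE[axis]
    if axis == "ML":
        return ({k: v * scale for k, v in _EVEN_SHAPE_ML.items()},
                {k: v * scale for k, v in _ODD_SHAPE_ML.items()})
    return ({k: v * scale for k, v in _EVEN_SHAPE.items()},
            {k: v * scale for k, v in _ODD_SHAPE_AP.items()})


def template_harmonics(
    cos_terms: dict, sin_terms: dict,
    bumps: list[tuple[float, float, float]], n: int = 20
) -> np.ndarray:
    """Exact amplitudes of harmonics 1..n of the stride template.

    The complex Fourier coefficient at harmonic ``k`` of a unit-period
    template is ``(a_k - i b_k)/2`` from the sinusoids plus
    ``h w sqrt(2 pi) exp(-2 pi^2 k^2 w^2) exp(-2 pi i k p)`` per wrapped
    Gaussian of height ``h``, centre ``p`` and width ``w``; the measured
    amplitude is twice its modulus.
    """
    return np.array([
        2.0 * abs(template_coeff(cos_terms, sin_terms, bumps, k))
        for k in range(1, n + 1)
    ])


def template_coeff(cos_terms: dict, sin_terms: dict,
                   bumps: list[tuple[float, float, float]], k: int) -> complex:
    """Complex Fourier coefficient of the template at harmonic ``k``."""
    coeff = complex(cos_terms.get(k, 0.0), -sin_terms.get(k, 0.0)) / 2.0
    for p, h, w in bumps:
        coeff += (h * w * np.sqrt(_TWO_PI)
                  * np.exp(-2.0 * np.pi ** 2 * k ** 2 * w ** 2)
                  * np.exp(-1j * _TWO_PI * k * p))
    return coeff


def _hr_of_amps(amps: np.ndarray, axis: str) -> float:
    odd = float(np.sum(amps[0::2]))
    even = float(np.sum(amps[1::2]))
    if axis == "ML":
        return odd / even
    return even / odd


def _calibrate_axis(spec: SyntheticSpec, axis: str) -> tuple[dict, dict, list, float]:
    """Solve one free parameter so the stride template hits the HR target.

    Returns ``(cos_terms, sin_terms, bumps, achieved_hr)``.  All solves are
    bisections on a strictly monotone bracketed function; the vertical axis
    solves the left/right bump asymmetry (clamped, so extreme targets yield
    the closest achievable ratio, reported in ``achieved_hr``), the other
    axes solve the odd-sine scale.
    """
    if axis == "V":
        return _calibrate_v(spec)
    even, odd = _axis_coeffs(spec, axis)
    bumps = _bump_positions(spec, axis)
    target = spec.hr_ml if axis == "ML" else spec.hr_ap

    def hr_for(s: float) -> float:
        od = {k: v * s for k, v in odd.items()}
        return _hr_of_amps(template_harmonics(even, od, bumps), axis)

    increasing = axis == "ML"  # ML ratio = odd/even grows with the odd scale
    lo, hi = 1e-9, 1.0
    for _ in range(80):
        if (hr_for(hi) >= target) == increasing or hr_for(hi) == target:
            break
        hi *= 2.0
        if hi > 1e9:
            raise ValueError(f"cannot reach HR target {target} on axis {axis}")
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        if (hr_for(mid) < target) == increasing:
            lo = mid
        else:
            hi = mid
    s = 0.5 * (lo + hi)
    return dict(even), {k: v * s for k, v in odd.items()}, bumps, hr_for(s)


def _calibrate_v(spec: SyntheticSpec,
                 fc_shift: tuple[float, float] = (0.0, 0.0),
                 ) -> tuple[dict, dict, list, float]:
    """Vertical axis: solve the contact-transient asymmetry for the HR target.

    The FC valleys pull the phase of the second stride harmonic (the one
    the event detector rides on) away from the initial contacts; a small
    k=2 sine term cancels the imaginary part of the total k=2 coefficient,
    re-anchoring the filtered-signal peaks at the truth ICs.  The
    antisymmetric transient pair carries no even power, so the trim does
    not depend on the solved asymmetry.  Very low targets that exceed the
    asymmetry range are topped up with one high odd harmonic that lies
    above every event-detection band but inside the 20 Hz analysis band.
    """
    scale = _AXIS_SCALE["V"]
    cos_terms = {k: v * scale for k, v in _EVEN_SHAPE.items()}
    for k, v in _ODD_FLOOR_V.items():
        cos_terms[k] = cos_terms.get(k, 0.0) + v * scale
    # cancel the imaginary parts of harmonics 1..3 (the detection band):
    # the contact-transient pair is purely real there, so the trim depends
    # only on the fixed bumps and can be computed once
    base_bumps = _bump_positions(spec, "V", 0.0, fc_shift)
    sin_terms = {k: 2.0 * template_coeff(cos_terms, {}, base_bumps, k).imag
                 for k in (1, 2, 3)}

    def hr_for(a: float) -> float:
        bumps = _bump_positions(spec, "V", a, fc_shift)
        return _hr_of_amps(template_harmonics(cos_terms, sin_terms, bumps), "V")

    lo, hi = 0.0, _MAX_ASYM  # hr_for is decreasing in the asymmetry
    if spec.hr_v >= hr_for(lo):
        a = lo
    elif spec.hr_v <= hr_for(hi):
        a = hi
    else:
        for _ in range(90):
            mid = 0.5 * (lo + hi)
            if hr_for(mid) > spec.hr_v:
                lo = mid
            else:
                hi = mid
        a = 0.5 * (lo + hi)
    bumps = _bump_positions(spec, "V", a, fc_shift)

    if spec.hr_v < hr_for(a) - 1e-9:
        def hr_high(s: float) -> float:
            ct = dict(cos_terms)
            ct[_ODD_HIGH_V] = ct.get(_ODD_HIGH_V, 0.0) + s
            return _hr_of_amps(template_harmonics(ct, sin_terms, bumps), "V")

        s_lo, s_hi = 0.0, 1.0
        while hr_high(s_hi) > spec.hr_v and s_hi < 1e6:
            s_hi *= 2.0
        for _ in range(90):
            mid = 0.5 * (s_lo + s_hi)
            if hr_high(mid) > spec.hr_v:
                s_lo = mid
            else:
                s_hi = mid
        s = 0.5 * (s_lo + s_hi)
        achieved = hr_high(s)
        cos_terms = dict(cos_terms)
        cos_terms[_ODD_HIGH_V] = cos_terms.get(_ODD_HIGH_V, 0.0) + s
        return cos_terms, sin_terms, bumps, achieved
    return cos_terms, sin_terms, bumps, hr_for(a)


def _solve_v_axis(spec: SyntheticSpec, fs: float) -> tuple[dict, dict, list, float]:
    """Calibrate the vertical template and place its toe-off valleys.

    The valley the detector sees on the band-limited signal is pulled away
    from the valley centre by the surrounding template, with a
    stance-dependent gain.  This fixed-point loop shifts the generated
    valley centres until the detectable minima of the (periodically
    band-limited) template coincide with the programmed truth, so the
    recorded ground truth is what an ideal run of the detector returns.
    """
    truth_l = spec.stance_left
    truth_r = (0.5 + spec.delta + spec.stance_right) % 1.0
    shift = [0.0, 0.0]
    best_shift, best_err = (0.0, 0.0), np.inf
    for _ in range(6):
        out = _calibrate_v(spec, tuple(shift))
        det_l, det_r = _detected_fc_phases(spec, out[0], out[1], out[2], fs)
        err_l = (det_l - truth_l + 0.5) % 1.0 - 0.5
        err_r = (det_r - truth_r + 0.5) % 1.0 - 0.5
        err = max(abs(err_l), abs(err_r))
        if err < best_err:
            best_shift, best_err = tuple(shift), err
        if err < 5e-4:
            return out
        if err > 0.05 or err > 2.0 * best_err:
            break  # the solve left the valley's basin; keep the best shift
        shift[0] = float(np.clip(shift[0] - 0.8 * err_l, -0.05, 0.05))
        shift[1] = float(np.clip(shift[1] - 0.8 * err_r, -0.05, 0.05))
    return _calibrate_v(spec, best_shift)


def _detected_fc_phases(spec: SyntheticSpec, cos_terms: dict, sin_terms: dict,
                        bumps: list, fs: float) -> tuple[float, float]:
    """Valley phases the real final-contact detector finds on the template.

    The noise-free stride template is tiled and passed through the actual
    detection code with truth contact times; the middle strides give the
    detected left/right valley phases free of edge effects.
    """
    from .gait_events import detect_final_contacts

    n_rep = 8
    n = max(int(round(spec.stride_time * fs)), 64)
    phi = (np.arange(n_rep * n) / n) % 1.0
    x = _eval_template(phi, cos_terms, sin_terms, bumps)
    ic_times, ic_sides = [], []
    for k in range(1, n_rep - 1):
        ic_times += [k * n / fs, (k + 0.5 + spec.delta) * n / fs]
        ic_sides += ["left", "right"]
    fc_times, fc_sides, _ = detect_final_contacts(
        x, fs, np.asarray(ic_times), ic_sides)
    det = {"left": [], "right": []}
    for t, s in zip(fc_times, fc_sides):
        det[s].append((t * fs / n) % 1.0)
    if not det["left"] or not det["right"]:
        return spec.stance_left, (0.5 + spec.delta + spec.stance_right) % 1.0
    # use circular medians of the mid-signal detections
    def _circ_med(vals: list[float], ref: float) -> float:
        arr = (np.asarray(vals) - ref + 0.5) % 1.0 - 0.5 + ref
        return float(np.median(arr)) % 1.0
    return (_circ_med(det["left"], spec.stance_left),
            _circ_med(det["right"], 0.5 + spec.delta + spec.stance_right))


def _eval_template(phi: np.ndarray, cos_terms: dict, sin_terms: dict,
                   bumps: list[tuple[float, float, float]]) -> np.ndarray:
    out = np.zeros_like(phi)
    for k, a in cos_terms.items():
        out += a * np.cos(_TWO_PI * k * phi)
    for k, b in sin_terms.items():
        out += b * np.sin(_TWO_PI * k * phi)
    for p, h, w in bumps:
        for image in (-1.0, 0.0, 1.0):  # wrap neighbours; w << 1 so 3 suffice
            out += h * np.exp(-((phi - p + image) ** 2) / (2.0 * w ** 2))
    return out


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------

def _ar1_noise(rng: np.random.Generator, n: int, corr: float) -> np.ndarray:
    """Unit-variance AR(1) noise with the given correlation time (samples).

    Temporally correlated motor noise is what drives measurable trajectory
    divergence: initially close strides decorrelate over roughly ``corr``
    samples, inside the short-term fit window of the stability index.
    """
    if corr <= 0:
        return rng.standard_normal(n)
    rho = float(np.exp(-1.0 / corr))
    out = np.empty(n)
    out[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - rho ** 2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov[i - 1]
    return out


_LEAD = 0.35       # strides of signal before the first truth IC
_LEAD_END = 0.20   # strides after the start of the trailing pad stride; short
                   # enough that the detector's edge rule discards its IC peak


def generate_trace(spec: SyntheticSpec) -> tuple[AccelTrace, GroundTruth]:
    """Generate one walk and its exact ground truth.

    The trace carries ``_LEAD`` strides of extra signal at each end so the
    detector's edge-discard rule never eats a truth event.  Noise,
    stride-time variability and amplitude jitter are applied after the
    truth is recorded.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_strides
    fs, T = spec.fs, spec.stride_time

    # stride durations: strides -1 .. n (two padding strides at nominal T)
    z = np.clip(rng.standard_normal(n), -3, 3)
    durations = np.concatenate(([T], T * (1.0 + spec.stride_cv * z), [T]))
    starts = np.concatenate(([0.0], np.cumsum(durations)))  # stride j starts at starts[j]
    # truth stride k (0-based) is generation stride k+1
    t0_offset = starts[1] - _LEAD * T
    # starts[-2] is the onset of the trailing pad stride (its IC peak must
    # fall inside the detector's edge-discard zone)
    total = starts[-2] + _LEAD_END * T - t0_offset

    n_samples = int(np.floor(total * fs))
    t = np.arange(n_samples) / fs + t0_offset  # generation time axis

    # map each sample to its generation stride and phase
    stride_of = np.searchsorted(starts, t, side="right") - 1
    stride_of = np.clip(stride_of, 0, len(durations) - 1)
    phi = (t - starts[stride_of]) / durations[stride_of]

    if spec.timing_jitter > 0:
        # within-stride phase wobble: a Brownian bridge per stride (zero at
        # both contacts, so event times stay exact), shared by all axes
        wobble = np.zeros_like(phi)
        for j in range(len(durations)):
            sel = np.flatnonzero(stride_of == j)
            nj = len(sel)
            if nj < 3:
                continue
            walk = np.cumsum(rng.standard_normal(nj)) / np.sqrt(nj)
            s = phi[sel]
            bridge = walk - s * walk[-1]
            wobble[sel] = spec.timing_jitter * bridge
        phi = phi + wobble

    jitter = 1.0 + spec.amp_jitter * np.clip(rng.standard_normal(len(durations)), -3, 3)
    jitter[0] = jitter[-1] = 1.0
    gain = jitter[stride_of]

    axes: dict[str, np.ndarray] = {}
    hr_truth: dict[str, float] = {}
    for axis in ("AP", "ML", "V"):
        if axis == "V":
            cos_terms, sin_terms, bumps, hr_exact = _solve_v_axis(spec, fs)
        else:
            cos_terms, sin_terms, bumps, hr_exact = _calibrate_axis(spec, axis)
        grid = np.arange(2048) / 2048.0
        rms = float(np.std(_eval_template(grid, cos_terms, sin_terms, bumps)))
        gain_rms = _AXIS_RMS[axis] / rms
        cos_terms = {k: v * gain_rms for k, v in cos_terms.items()}
        sin_terms = {k: v * gain_rms for k, v in sin_terms.items()}
        bumps = [(p, h * gain_rms, w) for p, h, w in bumps]
        if spec.shape_jitter > 0:
            # every stride gets an independent perturbation of each harmonic
            # and bump: stride-to-stride waveform distances then concentrate
            # at a stable floor, which the noise term diverges away from
            base = np.empty(n_samples)
            for j in range(len(durations)):
                sel = stride_of == j
                if not np.any(sel):
                    continue
                pert = lambda d: {
                    k: v * (1.0 + spec.shape_jitter * rng.standard_normal())
                    for k, v in d.items()
                }
                b = [(p, h * (1.0 + spec.shape_jitter * rng.standard_normal()), w)
                     for p, h, w in bumps]
                base[sel] = _eval_template(phi[sel], pert(cos_terms),
                                           pert(sin_terms), b)
            base *= gain
        else:
            base = _eval_template(phi, cos_terms, sin_terms, bumps) * gain
        if spec.baseline_jitter > 0:
            offsets_per_stride = spec.baseline_jitter * rng.standard_normal(len(durations))
            base = base + offsets_per_stride[stride_of]
        base += spec.noise_sigma.get(axis, 0.0) * _ar1_noise(
            rng, n_samples, spec.noise_corr)
        axes[axis] = base
        hr_truth[axis] = hr_exact

    # ---- ground-truth events (trace clock: t=0 at first sample) ----------
    ic_times, ic_sides, fc_times, fc_sides = [], [], [], []
    for k in range(n):
        s0, dur = starts[k + 1], durations[k + 1]
        ic_times += [s0 - t0_offset, s0 + (0.5 + spec.delta) * dur - t0_offset]
        ic_sides += ["left", "right"]
        fc_l = s0 + spec.stance_left * dur - t0_offset
        fc_r = s0 + ((0.5 + spec.delta) + spec.stance_right) * dur - t0_offset
        fc_times += [fc_l, fc_r]
        fc_sides += ["left", "right"]
    order = np.argsort(fc_times)
    fc_times = np.asarray(fc_times)[order]
    fc_sides = [fc_sides[i] for i in order]

    duration_walk = float(ic_times[-2 * 1] - ic_times[0]) if n > 1 else T
    # last *left* IC minus first left IC spans (n-1) strides; use full IC span
    duration_walk = float(ic_times[-1] - ic_times[0])
    walk_distance = spec.gait_speed * duration_walk

    si = _truth_symmetry(spec)
    truth = GroundTruth(
        ic_times=np.asarray(ic_times),
        ic_sides=ic_sides,
        fc_times=fc_times,
        fc_sides=fc_sides,
        hr=hr_truth,
        si=si,
        gait_speed=spec.gait_speed,
        stride_time=T,
        n_strides=n,
        walk_distance=walk_distance,
    )
    trace = AccelTrace(
        subject_id=spec.subject_id,
        ap=axes["AP"], ml=axes["ML"], v=axes["V"],
        fs=fs, timepoint=spec.timepoint, walk_distance=walk_distance,
    )
    return trace, truth


def _truth_symmetry(spec: SyntheticSpec) -> dict[str, float]:
    """Exact symmetry indexes implied by the stance fractions and delta."""
    if spec.paretic_side not in ("left", "right"):
        return {k: float("nan") for k in ("stance", "swing", "double_support", "single_support")}
    st = {"left": spec.stance_left, "right": spec.stance_right}
    sw = {s: 1.0 - st[s] for s in st}
    ds = {"left": st["right"] + spec.delta - 0.5,
          "right": st["left"] - spec.delta - 0.5}
    ss = {"left": sw["right"], "right": sw["left"]}
    p = spec.paretic_side
    np_ = "right" if p == "left" else "left"

    def _si(d: dict) -> float:
        return (d[p] - d[np_]) / (0.5 * (d[p] + d[np_])) * 100.0

    return {"stance": _si(st), "swing": _si(sw),
            "double_support": _si(ds), "single_support": _si(ss)}


# ---------------------------------------------------------------------------
# group presets and cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupPreset:
    """Distributional parameters for one study group."""

    name: str
    hr_v: tuple[float, float]
    hr_ml: tuple[float, float]
    hr_ap: tuple[float, float]
    gait_speed: tuple[float, float]
    stride_time: tuple[float, float] = (1.15, 0.07)
    stance_asym_sd: float = 0.02      # SD of the left/right stance-fraction gap
    delta_sd: float = 0.01
    stride_cv: float = 0.01
    amp_jitter: float = 0.02
    timing_jitter: tuple[float, float] = (0.004, 0.001)  # (mean, sd); the
    # within-stride phase-noise level that sets the stability exponent
    noise: dict = field(default_factory=lambda: {"V": 0.03, "ML": 0.03, "AP": 0.03})
    nlr: tuple[float, float] | None = None  # (mean, sd); None for HS
    n_strides: tuple[int, int] = (25, 30)


#: presets anchored to the published group means: harmonic ratios per axis,
#: gait speed, and noise/variability levels increasing HS -> IC -> SII so the
#: stability exponent orders the same way.
COHORT_PRESETS: dict[str, GroupPreset] = {
    "HS": GroupPreset(
        name="HS",
        hr_v=(2.01, 0.30), hr_ml=(1.87, 0.28), hr_ap=(1.95, 0.32),
        gait_speed=(0.78, 0.19),
        stance_asym_sd=0.013, delta_sd=0.003,
        stride_cv=0.008, amp_jitter=0.010,
        timing_jitter=(0.0042, 0.0006),
        noise={"V": 0.030, "ML": 0.030, "AP": 0.030},
        nlr=None,
    ),
    "IC": GroupPreset(
        name="IC",
        hr_v=(1.68, 0.30), hr_ml=(1.50, 0.22), hr_ap=(1.64, 0.30),
        gait_speed=(0.72, 0.21),
        stance_asym_sd=0.028, delta_sd=0.006,
        stride_cv=0.010, amp_jitter=0.015,
        timing_jitter=(0.0062, 0.0008),
        noise={"V": 0.033, "ML": 0.033, "AP": 0.033},
        nlr=(2.70, 0.98),
    ),
    "SII": GroupPreset(
        name="SII",
        hr_v=(1.36, 0.30), hr_ml=(1.24, 0.14), hr_ap=(1.41, 0.32),
        gait_speed=(0.66, 0.26),
        stance_asym_sd=0.030, delta_sd=0.008,
        stride_cv=0.012, amp_jitter=0.020,
        timing_jitter=(0.0078, 0.0010),
        noise={"V": 0.036, "ML": 0.036, "AP": 0.036},
        nlr=(6.68, 2.28),
    ),
}

#: multiplicative/additive changes applied to draw a matched T1 walk
_T1_IMPROVEMENT = {"hr_gain": 1.22, "noise_gain": 0.85, "speed_delta": 0.20}


def _draw_nlr(rng: np.random.Generator, preset: GroupPreset) -> float | None:
    if preset.nlr is None:
        return None
    mean, sd = preset.nlr
    if preset.name == "SII":
        # 5 + Gamma, so NLR >= 5 holds with probability 1
        excess_mean, excess_sd = mean - 5.0, sd
        shape = (excess_mean / excess_sd) ** 2
        scale = excess_mean / shape
        return float(5.0 + rng.gamma(shape, scale))
    # IC: Gamma matched to (mean, sd), truncated below the threshold
    shape = (mean / sd) ** 2
    scale = mean / shape
    for _ in range(100):
        val = float(rng.gamma(shape, scale))
        if 0.3 <= val < 4.95:
            return val
    return 4.5


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    for _ in range(100):
        v = float(rng.normal(mean, sd))
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


def draw_subject_spec(
    preset: GroupPreset,
    subject_id: str,
    rng: np.random.Generator,
    timepoint: str = "T0",
    paretic_side: str | None = None,
) -> SyntheticSpec:
    """Draw one walk specification from a group preset."""
    improve = timepoint == "T1"
    g_hr = _T1_IMPROVEMENT["hr_gain"] if improve else 1.0
    g_noise = _T1_IMPROVEMENT["noise_gain"] if improve else 1.0
    d_speed = _T1_IMPROVEMENT["speed_delta"] if improve else 0.0

    stance_base = 0.625
    gap = rng.normal(0.0, preset.stance_asym_sd)
    gap = float(np.clip(gap, -0.038, 0.038))
    # step-timing offsets stay small: the band-limited detector cannot place
    # peaks at 0 and 0.5 + delta simultaneously for large delta
    delta = float(np.clip(rng.normal(0.0, preset.delta_sd), -0.012, 0.012))
    if paretic_side is None:
        paretic_side = "left" if rng.random() < 0.5 else "right"
    return SyntheticSpec(
        stride_time=_trunc_normal(rng, *preset.stride_time, 1.0, 1.30),
        n_strides=int(rng.integers(preset.n_strides[0], preset.n_strides[1] + 1)),
        hr_v=_trunc_normal(rng, preset.hr_v[0] * g_hr, preset.hr_v[1], 1.05, 4.0),
        hr_ml=_trunc_normal(rng, preset.hr_ml[0] * g_hr, preset.hr_ml[1], 1.05, 4.0),
        hr_ap=_trunc_normal(rng, preset.hr_ap[0] * g_hr, preset.hr_ap[1], 1.05, 4.0),
        delta=delta,
        stance_left=stance_base + gap / 2.0,
        stance_right=stance_base - gap / 2.0,
        stride_cv=preset.stride_cv,
        amp_jitter=preset.amp_jitter,
        timing_jitter=max(rng.normal(*preset.timing_jitter) * g_noise, 0.0005),
        noise_sigma={a: s * g_noise for a, s in preset.noise.items()},
        noise_corr=0.0,
        gait_speed=_trunc_normal(rng, preset.gait_speed[0] + d_speed,
                                 preset.gait_speed[1], 0.25, 1.6),
        paretic_side=paretic_side,
        subject_id=subject_id,
        timepoint=timepoint,
        seed=int(rng.integers(0, 2 ** 31)),
    )


@dataclass
class Cohort:
    """Generated traces, manifest records and the ground-truth table."""

    records: list[SubjectRecord]
    traces: dict[tuple[str, str], AccelTrace]
    truths: dict[tuple[str, str], GroundTruth]
    truth_table: pd.DataFrame


def generate_cohort(
    n_hs: int = 42,
    n_ic: int = 32,
    n_sii: int = 14,
    presets: dict[str, GroupPreset] | None = None,
    seed: int = 0,
    timepoints: tuple[str, ...] = ("T0",),
) -> Cohort:
    """Generate a full cohort with per-subject sub-seeded reproducibility.

    Healthy subjects receive a random reference side in ``paretic_side`` so
    that symmetry indexes remain computable for controls; their NLR is
    absent.  The truth table has one row per subject and timepoint.
    """
    if n_hs + n_ic + n_sii <= 0:
        raise ValueError("cohort must contain at least one subject")
    presets = presets or COHORT_PRESETS
    counts = {"HS": n_hs, "IC": n_ic, "SII": n_sii}
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(sum(counts.values()))

    records: list[SubjectRecord] = []
    traces: dict[tuple[str, str], AccelTrace] = {}
    truths: dict[tuple[str, str], GroundTruth] = {}
    rows = []
    idx = 0
    for group in ("HS", "IC", "SII"):
        for j in range(counts[group]):
            rng = np.random.default_rng(subject_seeds[idx])
            idx += 1
            sid = f"{group.lower()}{j + 1:03d}"
            nlr = _draw_nlr(rng, presets[group])
            paretic = "left" if rng.random() < 0.5 else "right"
            scores = {}
            if group != "HS":
                scores = {
                    "nihss": float(np.clip(round(rng.normal(5.6, 3.3)), 0, 25)),
                    "bi": float(np.clip(round(rng.normal(54.6, 20.4) / 5) * 5, 0, 100)),
                    "fim": float(np.clip(round(rng.normal(85.4, 19.7)), 18, 126)),
                    "tinetti": float(np.clip(round(rng.normal(17.4, 8.0)), 0, 28)),
                }
            for tp in timepoints:
                spec = draw_subject_spec(presets[group], sid, rng, timepoint=tp,
                                         paretic_side=paretic)
                trace, truth = generate_trace(spec)
                traces[(sid, tp)] = trace
                truths[(sid, tp)] = truth
                records.append(SubjectRecord(
                    subject_id=sid, group=group, nlr=nlr, paretic_side=paretic,
                    timepoint=tp, trace_path=f"{sid}_{tp}.csv", **scores,
                ))
                rows.append({
                    "subject_id": sid, "group": group, "timepoint": tp,
                    "nlr": nlr, "paretic_side": paretic,
                    "hr_v": truth.hr["V"], "hr_ml": truth.hr["ML"], "hr_ap": truth.hr["AP"],
                    "si_stance": truth.si["stance"], "si_swing": truth.si["swing"],
                    "si_double": truth.si["double_support"],
                    "si_single": truth.si["single_support"],
                    "gait_speed": truth.gait_speed,
                    "stride_time": truth.stride_time,
                    "n_strides": truth.n_strides,
                    "noise_ml": spec.noise_sigma["ML"],
                })
    return Cohort(records=records, traces=traces, truths=truths,
                  truth_table=pd.DataFrame(rows))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write trace CSVs, the manifest and the truth table to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (sid, tp), trace in cohort.traces.items():
        write_accel_csv(trace, out / f"{sid}_{tp}.csv")
    write_cohort_manifest(cohort.records, out / "manifest.csv")
    cohort.truth_table.to_csv(out / "truth.csv", index=False)
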