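"""Trace / manifest I/O and run configuration.

File formats
------------
Trace CSV
    Columns ``time, acc_ap, acc_ml, acc_v`` (remappable via
    :attr:`RunConfig.column_map`).  ``time`` is seconds, monotone, uniformly
    sampled; accelerations are m/s^2 (or g with ``units="g"``).
Cohort manifest CSV
    One row per subject/timepoint: ``subject_id, nlr, paretic_side,
    timepoint, trace_path`` plus optional clinical-score columns
    (``nihss, bi, fim, tinetti``) and an optional declared ``group`` column.
    Group membership is always derived from the neutrophil-to-lymphocyte
    ratio: NLR >= 5 -> SII, NLR < 5 -> IC, absent -> HS.  A declared group
    that contradicts the rule raises :class:`~trunkgait.errors.InconsistencyError`.
Results CSV
    RFC-4180, '.' decimal separator, UTF-8, written with a JSON sidecar
    recording the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    FormatError,
    InconsistencyError,
    SamplingError,
    SchemaError,
)

logger = logging.getLogger("trunkgait")

#: standard gravity used when converting traces stored in g
STANDARD_GRAVITY = 9.80665

#: NLR threshold defining stroke-induced immunosuppression
NLR_SII_THRESHOLD = 5.0

AXES = ("AP", "ML", "V")
GROUPS = ("HS", "IC", "SII")
TIMEPOINTS = ("T0", "T1")


def assign_group(nlr: float | None) -> str:
    """Group label as a pure function of the neutrophil-to-lymphocyte ratio.

    ``None``/NaN -> ``"HS"``; ``nlr >= 5`` -> ``"SII"`` (boundary inclusive);
    otherwise ``"IC"``.
    """
    if nlr is None or (isinstance(nlr, float) and np.isnan(nlr)):
        return "HS"
    if nlr < 0:
        raise ValueError(f"NLR must be non-negative, got {nlr}")
    return "SII" if nlr >= NLR_SII_THRESHOLD else "IC"


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial trunk acceleration record (m/s^2)."""

    subject_id: str
    ap: np.ndarray
    ml: np.ndarray
    v: np.ndarray
    fs: float = 100.0
    timepoint: str = "T0"
    walk_distance: float = 30.0

    def __post_init__(self) -> None:
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        n = len(self.v)
        if len(self.ap) != n or len(self.ml) != n:
            raise ValueError("all three axes must have equal length")
        if n < 2 * self.fs:
            raise ValueError(f"trace too short: {n} samples < 2 s at {self.fs} Hz")
        for name, a in (("ap", self.ap), ("ml", self.ml), ("v", self.v)):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"axis {name} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.v)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def axis(self, name: str) -> np.ndarray:
        """Return one axis by label ('AP', 'ML' or 'V', case-insensitive)."""
        try:
            return {"AP": self.ap, "ML": self.ml, "V": self.v}[name.upper()]
        except KeyError:
            raise KeyError(f"unknown axis {name!r}; expected one of {AXES}") from None


@dataclass
class SubjectRecord:
    """Group label, NLR, paretic side and clinical scores at one timepoint."""

    subject_id: str
    group: str
    nlr: float | None = None
    paretic_side: str = "none"
    timepoint: str = "T0"
    trace_path: str | None = None
    nihss: float | None = None
    bi: float | None = None
    fim: float | None = None
    tinetti: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.paretic_side not in ("left", "right", "none"):
            raise ValueError("paretic_side must be left/right/none")
        expected = assign_group(self.nlr)
        if expected != self.group:
            raise InconsistencyError(
                f"subject {self.subject_id}: declared group {self.group} "
                f"contradicts NLR={self.nlr} (rule gives {expected})"
            )


@dataclass
class RunConfig:
    """All fixed analysis constants of the pipeline in one place."""

    fs: float = 100.0
    min_strides: int = 20
    trim_strides: int = 2
    event_cutoff_hz: float = 3.2
    fc_cutoff_hz: float = 6.0
    fir_order: int = 128
    cwt_scale: float = 9.0
    ic_polarity: str = "positive"  # 'positive': ICs at maxima of the CWT signal
    n_harmonics: int = 20
    hr_cutoff_hz: float = 20.0
    hr_filter_kind: str = "lowpass"  # or 'highpass' (see README on the 20 Hz filter)
    delay_min: int = 7
    delay_max: int = 18
    fnn_max_dim: int = 10
    fnn_rtol: float = 15.0
    fnn_atol: float = 2.0
    points_per_stride: int = 100
    slle_strides: int = 20
    theiler: int = 100
    fit_window: float = 0.5  # fraction of a normalized stride
    ldlj_cutoff_hz: float = 20.0
    ldlj_order: int = 4
    units: str = "mps2"  # or 'g'
    strict_sampling: bool = True
    jitter_tolerance: float = 0.10  # fraction of the sampling interval
    speed_mode: str = "corridor"  # or 'per_stride'
    column_map: dict = field(
        default_factory=lambda: {
            "time": "time", "ap": "acc_ap", "ml": "acc_ml", "v": "acc_v"
        }
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        nyq = self.fs / 2.0
        for name in ("event_cutoff_hz", "fc_cutoff_hz", "hr_cutoff_hz", "ldlj_cutoff_hz"):
            if not 0 < getattr(self, name) < nyq:
                raise ConfigError(f"{name}={getattr(self, name)} must lie in (0, fs/2)")
        if self.min_strides < 1 or self.trim_strides < 0:
            raise ConfigError("min_strides >= 1 and trim_strides >= 0 required")
        if not (1 <= self.delay_min <= self.delay_max):
            raise ConfigError("need 1 <= delay_min <= delay_max")
        if self.fnn_max_dim < 2:
            raise ConfigError("fnn_max_dim must be >= 2")
        if self.units not in ("mps2", "g"):
            raise ConfigError("units must be 'mps2' or 'g'")
        if self.ic_polarity not in ("positive", "negative"):
            raise ConfigError("ic_polarity must be 'positive' or 'negative'")
        if self.hr_filter_kind not in ("lowpass", "highpass", "none"):
            raise ConfigError("hr_filter_kind must be lowpass/highpass/none")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------

def read_accel_csv(
    path: str | Path,
    fs: float = 100.0,
    subject_id: str | None = None,
    timepoint: str = "T0",
    walk_distance: float = 30.0,
    config: RunConfig | None = None,
) -> AccelTrace:
    """Read a trace CSV, validating column presence and uniform sampling.

    The maximum allowed timing jitter is ``config.jitter_tolerance`` of one
    sampling interval; under strict sampling (the default) any larger gap
    raises :class:`~trunkgait.errors.SamplingError`, otherwise the trace is
    resampled onto a uniform grid by linear interpolation.
    """
    config = config or RunConfig(fs=fs)
    cmap = config.column_map
    df = pd.read_csv(path)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")

    t = df[cmap["time"]].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"{path}: time column not strictly increasing")
        jitter = np.max(np.abs(dt - 1.0 / fs)) * fs
        if jitter > config.jitter_tolerance:
            if config.strict_sampling:
                raise SamplingError(
                    f"{path}: sampling jitter {jitter:.3f} of one interval exceeds "
                    f"tolerance {config.jitter_tolerance}"
                )
            logger.warning("%s: resampling non-uniform trace (jitter %.3f)", path, jitter)
            grid = np.arange(t[0], t[-1] + 0.5 / fs, 1.0 / fs)
            df = pd.DataFrame(
                {
                    cmap["time"]: grid,
                    **{
                        cmap[a]: np.interp(grid, t, df[cmap[a]].to_numpy(dtype=float))
                        for a in ("ap", "ml", "v")
                    },
                }
            )

    scale = STANDARD_GRAVITY if config.units == "g" else 1.0
    return AccelTrace(
        subject_id=subject_id or Path(path).stem,
        ap=df[cmap["ap"]].to_numpy(dtype=float) * scale,
        ml=df[cmap["ml"]].to_numpy(dtype=float) * scale,
        v=df[cmap["v"]].to_numpy(dtype=float) * scale,
        fs=fs,
        timepoint=timepoint,
        walk_distance=walk_distance,
    )


def write_accel_csv(trace: AccelTrace, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a trace in the documented CSV schema (always m/s^2)."""
    cmap = (config or RunConfig()).column_map
    pd.DataFrame(
        {
            cmap["time"]: trace.time,
            cmap["ap"]: trace.ap,
            cmap["ml"]: trace.ml,
            cmap["v"]: trace.v,
        }
    ).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

_SCORE_COLS = ("nihss", "bi", "fim", "tinetti")


def read_cohort_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort manifest and derive group labels from the NLR rule."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: manifest needs a subject_id column")
    records: list[SubjectRecord] = []
    for _, row in df.iterrows():
        nlr = row.get("nlr")
        nlr = None if nlr is None or pd.isna(nlr) else float(nlr)
        derived = assign_group(nlr)
        declared = row.get("group")
        if declared is not None and not pd.isna(declared) and str(declared) != derived:
            raise InconsistencyError(
                f"{path}: subject {row['subject_id']} declared {declared} but "
                f"NLR={nlr} implies {derived}"
            )
        kwargs = {}
        for col in _SCORE_COLS:
            val = row.get(col)
            kwargs[col] = None if val is None or pd.isna(val) else float(val)
        side = row.get("paretic_side", "none")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=derived,
                nlr=nlr,
                paretic_side="none" if pd.isna(side) else str(side),
                timepoint=str(row.get("timepoint", "T0")),
                trace_path=None if pd.isna(row.get("trace_path")) else str(row.get("trace_path")),
                **kwargs,
            )
        )
    return records


def write_cohort_manifest(records: Sequence[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def write_results_table(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write result rows as CSV plus a JSON run-metadata sidecar.

    All rows must share one column set; heterogeneous rows raise
    :class:`~trunkgait.errors.SchemaError`.  An empty row list produces a
    header-only file and logs a warning.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            cols = set(rows[0].keys())
            for r in rows[1:]:
                if set(r.keys()) != cols:
                    raise SchemaError("heterogeneous columns across result rows")
        df = pd.DataFrame(rows)
    if df.empty:
        logger.warning("writing empty results table to %s", path)
    path = Path(path)
    df.to_csv(path, index=False)
    config = config or RunConfig()
    sidecar = {
        "config_hash": config.config_hash(),
        "seed": seed if seed is not None else config.seed,
        "n_rows": int(len(df)),
        "columns": list(df.columns),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=2))
    return df
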