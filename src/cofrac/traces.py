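"""Fluorescent elution traces from size-exclusion chromatography.

A trace is the inline fluorescence signal of labeled lipoprotein particles as
they elute from the column train, sampled against elution volume.  This module
reads traces, peak-normalizes them for cross-sample comparison, averages
technical replicates into a mean ± SD band, integrates the signal into the
1-ml collection fractions used for downstream proteomics, and fits the linear
signal-vs-phospholipid-mass calibration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, TraceParseError

log = logging.getLogger(__name__)

__all__ = [
    "ElutionTrace",
    "TraceBundle",
    "FractionSeries",
    "MassCalibration",
    "read_trace",
    "normalize_to_peak",
    "average_replicates",
    "bin_to_fractions",
    "calibrate_mass",
]


@dataclass(frozen=True)
class ElutionTrace:
    """A sampled fluorescence signal (arbitrary units) vs. elution volume (ml).

    Volumes must be strictly increasing and the signal finite.
    """

    volume_ml: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.volume_ml, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "volume_ml", v)
        object.__setattr__(self, "signal", s)
        if v.ndim != 1 or s.ndim != 1:
            raise InputError("trace arrays must be one-dimensional")
        if len(v) != len(s):
            raise InputError(
                f"volume ({len(v)}) and signal ({len(s)}) lengths differ"
            )
        if len(v) == 0:
            raise InputError("trace is empty")
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(s)):
            raise InputError("trace contains non-finite values")
        if np.any(np.diff(v) <= 0):
            raise InputError("elution volumes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.volume_ml)

    def with_signal(self, signal: np.ndarray, label: str | None = None) -> "ElutionTrace":
        return ElutionTrace(self.volume_ml, signal,
                            self.label if label is None else label)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"volume_ml": self.volume_ml, "signal": self.signal}).to_csv(
            path, index=False, float_format="%.17g"
        )


@dataclass(frozen=True)
class TraceBundle:
    """Technical replicates on a common grid with their pointwise mean and SD.

    The SD is the sample (n−1) standard deviation, rendered in figures as the
    shaded band around the averaged trace.
    """

    traces: tuple[ElutionTrace, ...]
    mean: ElutionTrace
    sd: np.ndarray

    def __post_init__(self):
        if np.any(self.sd < 0):
            raise InputError("SD must be nonnegative")


@dataclass(frozen=True)
class FractionSeries:
    """Per-fraction integrated signal (signal units × ml) for 1-ml fractions."""

    fraction_ids: np.ndarray
    signal: np.ndarray
    fraction_volume: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "fraction_ids",
                           np.asarray(self.fraction_ids, dtype=int))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if len(self.fraction_ids) != len(self.signal):
            raise InputError("fraction ids and signal lengths differ")
        if len(self.fraction_ids) > 1 and np.any(np.diff(self.fraction_ids) != 1):
            raise InputError("fraction ids must be consecutive")

    def __len__(self) -> int:
        return len(self.fraction_ids)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"fraction_id": self.fraction_ids, "signal": self.signal}).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )


def read_trace(path: str | Path, *, volume_col: str = "volume_ml",
               signal_col: str = "signal", sep: str = ",",
               label: str | None = None) -> ElutionTrace:
    """Read a two-column trace CSV (header ``volume_ml,signal``).

    Malformed (non-numeric) rows raise :class:`TraceParseError` naming the
    offending line; non-monotone volumes are rejected by the trace invariant.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"trace file not found: {path}")
    raw = pd.read_csv(path, sep=sep, dtype=str)
    for col in (volume_col, signal_col):
        if col not in raw.columns:
            raise TraceParseError(f"missing column {col!r} in {path}")
    vol = pd.to_numeric(raw[volume_col], errors="coerce")
    sig = pd.to_numeric(raw[signal_col], errors="coerce")
    bad = vol.isna() | sig.isna()
    if bad.any():
        # +2: one for the header row, one for 1-based file lines
        first = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise TraceParseError(f"non-numeric value in {path}", line=first)
    try:
        return ElutionTrace(vol.to_numpy(), sig.to_numpy(),
                            label=path.stem if label is None else label)
    except InputError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc


def normalize_to_peak(trace: ElutionTrace) -> ElutionTrace:
    """Scale the signal so its most intense point equals 1.

    Used to compare elution profiles across biofluids; point-to-point signal
    ratios (the shape) are unchanged.
    """
    peak = float(np.max(trace.signal))
    if peak <= 0:
        raise InputError("cannot peak-normalize: maximum signal is not positive")
    return trace.with_signal(trace.signal / peak)


def average_replicates(traces: Sequence[ElutionTrace], *,
                       resample: bool = False,
                       grid_rtol: float = 1e-9) -> TraceBundle:
    """Average replicate traces pointwise; SD is the sample (n−1) SD.

    Replicates must share the volume grid; with ``resample=True`` traces are
    linearly interpolated onto the first trace's grid (run-to-run jitter).
    A single replicate yields zero SD (warned).
    """
    if len(traces) == 0:
        raise InputError("no traces to average")
    grid = traces[0].volume_ml
    aligned = [traces[0].signal]
    for t in traces[1:]:
        if len(t) == len(grid) and np.allclose(t.volume_ml, grid, rtol=grid_rtol, atol=0):
            aligned.append(t.signal)
        elif resample:
            aligned.append(np.interp(grid, t.volume_ml, t.signal))
        else:
            raise InputError(
                "replicate grids differ; pass resample=True to interpolate"
            )
    arr = np.vstack(aligned)
    mean = arr.mean(axis=0)
    if arr.shape[0] == 1:
        log.warning("single replicate: SD band is zero")
        sd = np.zeros_like(mean)
    else:
        sd = arr.std(axis=0, ddof=1)
    return TraceBundle(
        traces=tuple(ElutionTrace(grid, a, t.label) for a, t in zip(aligned, traces)),
        mean=ElutionTrace(grid, mean, label="mean"),
        sd=sd,
    )


def bin_to_fractions(trace: ElutionTrace, start_volume: float,
                     fraction_volume: float = 1.0,
                     first_id: int = 23) -> FractionSeries:
    """Integrate the trace into consecutive collection fractions.

    Fraction ``first_id + k`` covers the half-open volume interval
    ``[start + k·v, start + (k+1)·v)``; a sample exactly on a boundary belongs
    to the later fraction.  Each bin is the trapezoidal integral of the signal
    with interpolated values at the bin edges, so the binned total conserves
    the trace integral over the covered range.  Only fractions that lie fully
    inside the trace are returned.
    """
    if fraction_volume <= 0:
        raise InputError("fraction_volume must be positive")
    v, s = trace.volume_ml, trace.signal
    lo, hi = float(v[0]), float(v[-1])
    eps = 1e-9 * fraction_volume
    k0 = int(np.ceil((lo - start_volume) / fraction_volume - eps))
    k0 = max(k0, 0)
    ids, vals = [], []
    k = k0
    while start_volume + (k + 1) * fraction_volume <= hi + eps:
        a = start_volume + k * fraction_volume
        b = a + fraction_volume
        inside = v[(v > a) & (v < b)]
        xs = np.concatenate(([a], inside, [b]))
        ys = np.interp(xs, v, s)
        ids.append(first_id + k)
        vals.append(float(np.trapezoid(ys, xs)))
        k += 1
    return FractionSeries(np.asarray(ids, dtype=int), np.asarray(vals),
                          fraction_volume=fraction_volume)


@dataclass(frozen=True)
class MassCalibration:
    """OLS calibration of integrated fluorescence vs. phospholipid mass (μg)."""

    slope: float
    intercept: float
    r_squared: float
    stderr: float

    def predict(self, mass_ug):
        return self.slope * np.asarray(mass_ug, dtype=float) + self.intercept


def calibrate_mass(mass_ug: Sequence[float],
                   total_signal: Sequence[float]) -> MassCalibration:
    """Fit the linear signal-vs-mass relationship of a dilution series."""
    x = np.asarray(mass_ug, dtype=float)
    y = np.asarray(total_signal, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise InputError("need at least two (mass, signal) points")
    if np.ptp(x) == 0:
        raise InputError("all masses identical: calibration line undefined")
    res = stats.linregress(x, y)
    return MassCalibration(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue ** 2),
                           stderr=float(res.stderr))
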