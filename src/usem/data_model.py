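"""Containers and I/O for ROI time series and task-input vectors.

The observed data for every model in this package is a p-variate BOLD
time series sampled at a fixed repetition time (TR).  Means are fixed at
zero throughout the model family, so series are centered before any
covariance computation.  Task-condition indicator vectors are convolved
with a canonical double-gamma hemodynamic response function (HRF) before
entering a model as external input.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "RoiTimeSeries",
    "InputSeries",
    "HrfKernel",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "center",
    "hrf_double_gamma",
    "convolve_input",
    "DEFAULT_HRF_PARAMETERS",
]


class TimeSeriesParseError(ValueError):
    """A cell could not be parsed or the table is ragged."""


@dataclass(frozen=True)
class RoiTimeSeries:
    """A p-variate ROI time series (one row per ROI, one column per TR).

    ``values`` has shape ``(p, T)``.  The same container also carries
    one-step-ahead prediction errors when models are validated.
    """

    values: np.ndarray
    labels: tuple[str, ...]
    tr_seconds: float = 2.0
    centered: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D (p, T) array")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        p, T = vals.shape
        if p < 1:
            raise ValueError("need at least one ROI series")
        if T <= p:
            raise ValueError(f"time series too short: T={T} must exceed p={p}")
        if len(self.labels) != p:
            raise ValueError("number of labels must equal number of series")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(vals)):
            raise ValueError("time series contains non-finite values")
        if self.centered:
            mx = np.abs(vals.mean(axis=1)).max()
            if mx > 1e-10:
                raise ValueError(f"centered flag set but max |mean| = {mx:g}")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class InputSeries:
    """External task-input vectors, raw and (optionally) HRF-convolved."""

    raw: np.ndarray
    convolved: np.ndarray | None = None
    kernel_id: str = ""

    def __post_init__(self) -> None:
        raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        object.__setattr__(self, "raw", raw)
        if not np.all(np.isfinite(raw)):
            raise ValueError("input series contains non-finite values")
        if self.convolved is not None:
            conv = np.atleast_2d(np.asarray(self.convolved, dtype=float))
            if conv.shape != raw.shape:
                raise ValueError("convolved input must match raw shape")
            object.__setattr__(self, "convolved", conv)

    @property
    def n_u(self) -> int:
        return self.raw.shape[0]

    @property
    def T(self) -> int:
        return self.raw.shape[1]

    @property
    def effective(self) -> np.ndarray:
        """Convolved values when present, raw otherwise."""
        return self.raw if self.convolved is None else self.convolved


#: Conventional double-gamma parameterization (seconds): response peaks
#: near 5 s, the undershoot near 15 s, with a 1:6 undershoot ratio.
DEFAULT_HRF_PARAMETERS: Mapping[str, float] = {
    "peak_delay": 6.0,
    "undershoot_delay": 16.0,
    "peak_dispersion": 1.0,
    "undershoot_dispersion": 1.0,
    "ratio": 1.0 / 6.0,
    "onset": 0.0,
}


@dataclass(frozen=True)
class HrfKernel:
    """Sampled HRF kernel (first sample at time zero, unit peak)."""

    samples: np.ndarray
    tr_seconds: float
    duration_seconds: float
    parameters: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HRF_PARAMETERS))

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if not np.all(np.isfinite(s)):
            raise ValueError("kernel contains non-finite values")
        if s.max() <= 0:
            raise ValueError("kernel peak must be positive")

    @property
    def kernel_id(self) -> str:
        pars = ",".join(f"{k}={v:g}" for k, v in sorted(self.parameters.items()))
        return f"double-gamma({pars})@{self.tr_seconds:g}s"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": "hrf_kernel",
            "tr_seconds": self.tr_seconds,
            "duration_seconds": self.duration_seconds,
            "parameters": dict(self.parameters),
            "samples": self.samples.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return math.isfinite(float(token))


def read_roi_timeseries(
    path: str | Path,
    orientation: str = "rows-are-time",
    delimiter: str | None = None,
    tr_seconds: float = 2.0,
) -> RoiTimeSeries:
    """Read a TSV/CSV table of ROI time series.

    ``orientation`` is ``"rows-are-time"`` (T rows x p columns, the
    common ROI-extraction export) or ``"rows-are-roi"``.  An optional
    single header row supplies the ROI labels; otherwise labels default
    to ``ROI1..ROIp``.  The delimiter is auto-detected from {tab, comma}
    when not given.
    """
    if orientation not in ("rows-are-time", "rows-are-roi"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TimeSeriesParseError(f"{path}: empty file")
    delim = delimiter or _sniff_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise TimeSeriesParseError(
                f"{path}: ragged table, row {i + 1} has {len(row)} cells, expected {width}"
            )
    header: list[str] | None = None
    if not all(_is_number(c) for c in rows[0]):
        header = [c.strip() for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise TimeSeriesParseError(f"{path}: header row but no data")
    data = np.empty((len(rows), width), dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if not _is_number(cell):
                raise TimeSeriesParseError(
                    f"{path}: non-numeric cell {cell!r} at data row {i + 1}, column {j + 1}"
                )
            data[i, j] = float(cell)
    if orientation == "rows-are-time":
        values = data.T
    else:
        values = data
    p = values.shape[0]
    if header is not None:
        if orientation == "rows-are-roi":
            # header of a ROI-per-row table labels time columns; ignore it
            labels = tuple(f"ROI{i + 1}" for i in range(p))
        else:
            labels = tuple(header)
    else:
        labels = tuple(f"ROI{i + 1}" for i in range(p))
    return RoiTimeSeries(values=values, labels=labels, tr_seconds=tr_seconds)


def write_roi_timeseries(ts: RoiTimeSeries, path: str | Path, delimiter: str = "\t") -> None:
    """Write a time series as a T x p table with a label header row."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(ts.labels)
        for t in range(ts.T):
            writer.writerow([repr(float(v)) for v in ts.values[:, t]])


def center(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Subtract each series' sample mean (means are fixed at zero).

    Idempotent: re-centering an already-centered series returns it
    unchanged.
    """
    if ts.centered:
        return ts
    vals = ts.values - ts.values.mean(axis=1, keepdims=True)
    return replace(ts, values=vals, centered=True)


def hrf_double_gamma(
    tr_seconds: float,
    duration_seconds: float = 32.0,
    parameters: Mapping[str, float] | None = None,
) -> HrfKernel:
    """Canonical double-gamma HRF sampled at the TR, normalized to unit peak.

    The kernel is the difference of two gamma densities: a positive
    response (peak delay / dispersion) minus ``ratio`` times an
    undershoot (undershoot delay / dispersion), shifted by ``onset``.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if duration_seconds < 2 * tr_seconds:
        raise ValueError("kernel duration must cover at least two TRs")
    pars = dict(DEFAULT_HRF_PARAMETERS)
    if parameters:
        unknown = set(parameters) - set(pars)
        if unknown:
            raise ValueError(f"unknown HRF parameters: {sorted(unknown)}")
        pars.update(parameters)
    n = int(math.ceil(duration_seconds / tr_seconds))
    t = np.arange(n) * tr_seconds - pars["onset"]
    kernel = hrf_double_gamma_continuous(t, pars)
    peak = kernel.max()
    if peak <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return HrfKernel(
        samples=kernel / peak,
        tr_seconds=tr_seconds,
        duration_seconds=duration_seconds,
        parameters=pars,
    )


def hrf_double_gamma_continuous(t: np.ndarray, pars: Mapping[str, float]) -> np.ndarray:
    """Evaluate the unnormalized gamma-difference expression at times ``t``."""
    t = np.asarray(t, dtype=float)
    a1 = pars["peak_delay"] / pars["peak_dispersion"]
    a2 = pars["undershoot_delay"] / pars["undershoot_dispersion"]
    pos = _gamma_dist.pdf(t, a1, scale=pars["peak_dispersion"])
    neg = _gamma_dist.pdf(t, a2, scale=pars["undershoot_dispersion"])
    out = pos - pars["ratio"] * neg
    return np.where(t < 0, 0.0, out)


def convolve_input(u: InputSeries, kernel: HrfKernel) -> InputSeries:
    """Causal discrete convolution of each input row, truncated to length T."""
    T = u.T
    conv = np.empty_like(u.raw)
    for i in range(u.n_u):
        conv[i] = np.convolve(u.raw[i], kernel.samples)[:T]
    return InputSeries(raw=u.raw, convolved=conv, kernel_id=kernel.kernel_id)
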