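"""Capillary-electrophoresis QC: size calibration, integrity %, average size.

The integrity metric is an openly specified analogue of instrument smear
analysis: the percentage of (trapezoidal) trace area falling inside a
main-peak size window, together with the area-weighted mean fragment size.
Migration-time traces are mapped to the size axis by piecewise-linear
interpolation in log(size), since electrophoretic mobility is approximately
linear in log(length).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Electropherogram",
    "IntegrityResult",
    "CalibrationError",
    "calibrate_sizes",
    "baseline_correct",
    "integrity_percent",
    "read_trace_csv",
    "write_trace_csv",
    "read_marker_table",
]

#: main-peak window (nt) bracketing an intact ~2.9 kb mRNA peak
DEFAULT_MAIN_PEAK_WINDOW = (2100.0, 3300.0)
#: sizes below this are treated as marker/primer territory and excluded
DEFAULT_MIN_SIZE = 100.0


class CalibrationError(ValueError):
    """Size calibration is underdetermined or non-monotone."""


@dataclass
class Electropherogram:
    """An ordered fluorescence trace on a migration-time or size axis."""

    sample_name: str
    axis: np.ndarray
    signal: np.ndarray
    axis_kind: str = "migration_time"  # {"migration_time", "size_nt"}
    markers: list[tuple[float, float]] = field(default_factory=list)  # (size nt, axis)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.axis.shape != self.signal.shape:
            raise ValueError("axis and signal lengths differ")
        if self.axis.size >= 2 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("trace axis must be strictly increasing")
        if self.axis_kind not in {"migration_time", "size_nt"}:
            raise ValueError(f"unknown axis kind {self.axis_kind!r}")

    def to_frame(self) -> pd.DataFrame:
        col = "size_nt" if self.axis_kind == "size_nt" else "migration_time"
        return pd.DataFrame({col: self.axis, "signal": self.signal})


@dataclass
class IntegrityResult:
    """Main-peak integrity summary of a sized trace."""

    sample_name: str
    integrity_percent: float
    average_size_nt: float
    window: tuple[float, float]
    in_window_area: float
    total_area: float
    min_size_nt: float = DEFAULT_MIN_SIZE

    def __post_init__(self) -> None:
        if not (0.0 <= self.integrity_percent <= 100.0 + 1e-9):
            raise ValueError("integrity must be within 0..100%")
        if self.in_window_area > self.total_area * (1 + 1e-9):
            raise ValueError("in-window area exceeds total area")

    def to_dict(self) -> dict:
        return {
            "sample": self.sample_name,
            "integrity_percent": self.integrity_percent,
            "average_size_nt": self.average_size_nt,
            "main_peak_window_nt": list(self.window),
            "in_window_area": self.in_window_area,
            "total_area": self.total_area,
            "min_size_nt": self.min_size_nt,
            "calibration": "piecewise linear in log(size)",
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def calibrate_sizes(
    trace: Electropherogram, markers: list[tuple[float, float]]
) -> Electropherogram:
    """Convert a migration-time trace to the fragment-size axis.

    ``markers`` are (size nt, migration time) anchor points from a co-run
    sizing ladder; interpolation is piecewise linear in log(size) vs time,
    linearly extrapolated beyond the outermost markers.
    """
    if len(markers) < 2:
        raise CalibrationError("need >= 2 size markers for calibration")
    mk = sorted(markers, key=lambda m: m[1])
    times = np.array([t for _, t in mk], dtype=float)
    sizes = np.array([s for s, _ in mk], dtype=float)
    if np.any(np.diff(times) <= 0) or np.any(np.diff(sizes) <= 0):
        raise CalibrationError(
            "markers must be strictly monotone: larger fragments, later times"
        )
    log_size = np.log(sizes)
    slopes = np.diff(log_size) / np.diff(times)
    t = trace.axis
    out = np.interp(t, times, log_size)
    out = np.where(t < times[0], log_size[0] + slopes[0] * (t - times[0]), out)
    out = np.where(t > times[-1], log_size[-1] + slopes[-1] * (t - times[-1]), out)
    return Electropherogram(
        sample_name=trace.sample_name,
        axis=np.exp(out),
        signal=trace.signal.copy(),
        axis_kind="size_nt",
        markers=list(mk),
    )


def baseline_correct(trace: Electropherogram, window_points: int = 101) -> Electropherogram:
    """Rolling-minimum baseline subtraction (window in trace points)."""
    if window_points < 1 or window_points % 2 == 0:
        raise ValueError("window_points must be a positive odd number")
    s = pd.Series(trace.signal)
    base = s.rolling(window_points, center=True, min_periods=1).min().to_numpy()
    return Electropherogram(
        sample_name=trace.sample_name,
        axis=trace.axis.copy(),
        signal=np.clip(trace.signal - base, 0, None),
        axis_kind=trace.axis_kind,
        markers=list(trace.markers),
    )


def integrity_percent(
    sized_trace: Electropherogram,
    cutoff_lo: float = DEFAULT_MAIN_PEAK_WINDOW[0],
    cutoff_hi: float = DEFAULT_MAIN_PEAK_WINDOW[1],
    min_size: float = DEFAULT_MIN_SIZE,
) -> IntegrityResult:
    """Integrity % and average fragment size of a baseline-corrected trace.

    integrity = 100 x (trapezoidal area within [cutoff_lo, cutoff_hi]) /
    (total area above ``min_size``); average size is the area-weighted mean
    over the full trace above ``min_size``. The ``min_size`` floor keeps a
    co-run small alignment marker out of the denominator.
    """
    if sized_trace.axis_kind != "size_nt":
        raise ValueError("trace must be size-calibrated first (see calibrate_sizes)")
    if not cutoff_lo < cutoff_hi:
        raise ValueError("cutoff_lo must be < cutoff_hi")
    x, y = sized_trace.axis, sized_trace.signal
    keep = x >= min_size
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("trace has too few points above min_size")
    total = float(np.trapezoid(y, x))
    if total <= 0:
        raise ValueError("zero total trace area")
    in_win = float(_window_area(x, y, cutoff_lo, cutoff_hi))
    avg = float(np.trapezoid(y * x, x) / total)
    return IntegrityResult(
        sample_name=sized_trace.sample_name,
        integrity_percent=100.0 * min(in_win / total, 1.0),
        average_size_nt=avg,
        window=(cutoff_lo, cutoff_hi),
        in_window_area=in_win,
        total_area=total,
        min_size_nt=min_size,
    )


def _window_area(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area of (x, y) restricted to [lo, hi], with edge
    interpolation so the window boundary cuts segments exactly."""
    lo = max(lo, x[0])
    hi = min(hi, x[-1])
    if lo >= hi:
        return 0.0
    grid = np.unique(np.concatenate([x[(x > lo) & (x < hi)], [lo, hi]]))
    yg = np.interp(grid, x, y)
    return float(np.trapezoid(yg, grid))


# ---------------------------------------------------------------------------
# I/O


def read_trace_csv(
    path: str | Path, sample_name: str | None = None, axis_kind: str = "migration_time"
) -> Electropherogram:
    """Two-column CSV (axis value, signal), with or without a header."""
    df = pd.read_csv(path, header=None, comment="#")
    if isinstance(df.iloc[0, 0], str):
        df = df.iloc[1:].astype(float)
    arr = df.to_numpy(dtype=float)
    return Electropherogram(
        sample_name=sample_name or Path(path).stem,
        axis=arr[:, 0],
        signal=arr[:, 1],
        axis_kind=axis_kind,
    )


def write_trace_csv(trace: Electropherogram, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_marker_table(path: str | Path) -> list[tuple[float, float]]:
    """Marker TSV with columns size_nt and axis value (e.g. migration time)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    size_col = "size_nt" if "size_nt" in df.columns else df.columns[0]
    axis_col = [c for c in df.columns if c != size_col][0]
    return [(float(r[size_col]), float(r[axis_col])) for _, r in df.iterrows()]


def plot_electropherogram(
    trace: Electropherogram,
    path: str | Path,
    window: tuple[float, float] | None = DEFAULT_MAIN_PEAK_WINDOW,
) -> None:
    """Static trace figure with the main-peak window shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trace.axis, trace.signal, lw=0.8, color="tab:blue")
    if window and trace.axis_kind == "size_nt":
        ax.axvspan(window[0], window[1], color="tab:orange", alpha=0.15)
    ax.set_xlabel("size (nt)" if trace.axis_kind == "size_nt" else "migration time")
    ax.set_ylabel("fluorescence (AU)")
    ax.set_title(trace.sample_name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
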