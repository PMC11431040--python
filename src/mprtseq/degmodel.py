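"""Baseline-referenced hotspot detection and degradation statistics.

The baseline is the rescaled average degradation line

    IA(N) = A * (1 + q)**N

where A is the regime's total average degradation reactivity (taken from
the full stress-gradient test), q is a small dimensionless rescale factor
and N the 1-based nucleotide position along the assembled profile. A
position is *high intensity* when its reactivity strictly exceeds the
baseline at that position. Hotspots are runs of high-intensity positions
(gap-merged) that appear in every required stress condition — by default in
both freeze-thaw and 37 degC heating, so only sequences sensitive to
degradation per se, not to one stress artefact, are called.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reactivity import ReactivityProfile

__all__ = [
    "DegradationBaseline",
    "HotspotCall",
    "FREEZE_THAW_BASELINE",
    "HEAT_BASELINE",
    "baseline_at",
    "classify_high_intensity",
    "find_hotspots",
    "fold_change",
    "composition_stats",
    "write_hotspots_bed",
    "write_hotspots_json",
]


@dataclass(frozen=True)
class DegradationBaseline:
    """Parameters of the rescaled average line IA(N) = A (1+q)^N."""

    A: float
    q: float
    regime: str = ""

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError("total average reactivity A must be > 0")
        if self.q < 0:
            raise ValueError("rescale factor q must be >= 0")

    def at(self, N: int | np.ndarray) -> float | np.ndarray:
        return baseline_at(self, N)


#: regime parameter sets from the full stress-gradient experiments
FREEZE_THAW_BASELINE = DegradationBaseline(A=3.5, q=0.000001, regime="freeze_thaw")
HEAT_BASELINE = DegradationBaseline(A=8.8, q=0.00035, regime="heat_37C")


def baseline_at(baseline: DegradationBaseline, N: int | np.ndarray):
    """Evaluate IA(N) = A (1+q)^N at integer position(s) N >= 0."""
    N_arr = np.asarray(N)
    if np.any(N_arr < 0):
        raise ValueError("position index N must be >= 0")
    out = baseline.A * (1.0 + baseline.q) ** N_arr
    return float(out) if np.isscalar(N) or N_arr.ndim == 0 else out


def classify_high_intensity(
    profile: ReactivityProfile, baseline: DegradationBaseline
) -> np.ndarray:
    """Boolean mask: reactivity(i) strictly above the baseline at i.

    Ties at exactly the baseline are low ("higher than" is strict); missing
    positions are False.
    """
    L = len(profile)
    thresholds = baseline_at(baseline, np.arange(1, L + 1))
    with np.errstate(invalid="ignore"):
        mask = profile.values > thresholds
    mask[profile.mask_missing] = False
    return mask


@dataclass
class HotspotCall:
    """A degradation-sensitive sequence interval (1-based inclusive)."""

    start: int
    end: int
    high_positions: dict[str, list[int]] = field(default_factory=dict)
    sequence: str = ""
    fold_changes: dict[str, float] = field(default_factory=dict)
    motif: "object | None" = None  # MotifSummary, filled by the structure layer

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("hotspot start must be <= end")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def width(self) -> int:
        return self.end - self.start + 1

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "sequence": self.sequence,
            "high_positions": {k: list(v) for k, v in self.high_positions.items()},
            "fold_changes": dict(self.fold_changes),
            "motif": self.motif.to_dict() if self.motif is not None else None,
        }


def _gap_merged_runs(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Merge True positions within <= max_gap of each other into runs
    (1-based inclusive intervals clipped to the outermost True positions)."""
    highs = np.flatnonzero(mask) + 1
    runs: list[tuple[int, int]] = []
    for p in highs:
        if runs and p - runs[-1][1] - 1 <= max_gap:
            runs[-1] = (runs[-1][0], int(p))
        else:
            runs.append((int(p), int(p)))
    return runs


def find_hotspots(
    mask_by_condition: Mapping[str, np.ndarray],
    min_high: int = 2,
    max_gap: int = 3,
    require_all_conditions: bool = True,
    sequence: str | None = None,
) -> list[HotspotCall]:
    """Call hotspots from per-condition high-intensity masks.

    Per condition, high positions within ``max_gap`` of each other merge
    into runs; overlapping runs from different conditions merge into one
    candidate call. A call is kept only if every required condition
    contributes at least ``min_high`` high positions (all conditions when
    ``require_all_conditions``, else any one); the call span is clipped to
    the outermost member high positions. Calls come back sorted by start
    and never overlap.
    """
    if not mask_by_condition:
        raise ValueError("empty condition set")
    conditions = sorted(mask_by_condition)
    lengths = {len(np.asarray(mask_by_condition[c])) for c in conditions}
    if len(lengths) != 1:
        raise ValueError("condition masks differ in length")

    runs = {
        c: _gap_merged_runs(np.asarray(mask_by_condition[c], dtype=bool), max_gap)
        for c in conditions
    }
    # connected components of overlapping runs across conditions
    all_runs = sorted(
        (s, e, c) for c, rs in runs.items() for (s, e) in rs
    )
    components: list[list[tuple[int, int, str]]] = []
    for s, e, c in all_runs:
        if components and s <= max(r[1] for r in components[-1]):
            components[-1].append((s, e, c))
        else:
            components.append([(s, e, c)])

    calls: list[HotspotCall] = []
    for comp in components:
        lo = min(r[0] for r in comp)
        hi = max(r[1] for r in comp)
        members: dict[str, list[int]] = {}
        for c in conditions:
            m = np.asarray(mask_by_condition[c], dtype=bool)
            pos = [int(p) for p in np.flatnonzero(m[lo - 1 : hi]) + lo]
            members[c] = pos
        counts = [len(members[c]) for c in conditions]
        ok = all(n >= min_high for n in counts) if require_all_conditions else any(
            n >= min_high for n in counts
        )
        if not ok:
            continue
        observed = sorted(p for pos in members.values() for p in pos)
        start, end = observed[0], observed[-1]
        seq = sequence[start - 1 : end] if sequence else ""
        calls.append(
            HotspotCall(start=start, end=end, high_positions=members, sequence=seq)
        )
    return sorted(calls, key=lambda h: h.start)


def fold_change(
    profile: ReactivityProfile, start: int, end: int, reference_average: float
) -> float:
    """Mean reactivity over [start, end] divided by a reference average.

    The reference is explicit (a regime's total average or a local window
    average) — it is never inferred from the profile.
    """
    if not reference_average > 0:
        raise ValueError("reference_average must be > 0")
    if start > end:
        raise ValueError("window start must be <= end")
    return profile.window_mean(start, end) / reference_average


def composition_stats(
    mask: np.ndarray, sequence: str, bases: Sequence[str] = "CGAU"
) -> dict:
    """Base composition of high-intensity positions.

    Returns {"count": n, "proportions": {base: fraction}}; with zero high
    positions the proportions are None (flagged undefined).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != len(sequence):
        raise ValueError("mask and sequence lengths differ")
    highs = [sequence[i] for i in np.flatnonzero(mask)]
    n = len(highs)
    if n == 0:
        return {"count": 0, "proportions": None}
    props = {b: highs.count(b) / n for b in bases}
    return {"count": n, "proportions": props}


# ---------------------------------------------------------------------------
# export


def write_hotspots_bed(
    calls: list[HotspotCall],
    path: str | Path,
    chrom: str = "mrna",
    zero_based: bool = False,
) -> None:
    """BED-like TSV; 1-based inclusive by default, BED6 0-based half-open
    with ``zero_based=True``."""
    rows = []
    for i, h in enumerate(calls, 1):
        if zero_based:
            rows.append((chrom, h.start - 1, h.end, f"hotspot_{i}", 0, "+"))
        else:
            rows.append((chrom, h.start, h.end, f"hotspot_{i}", h.sequence, "+"))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_hotspots_json(calls: list[HotspotCall], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([h.to_dict() for h in calls], indent=2) + "\n"
    )
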