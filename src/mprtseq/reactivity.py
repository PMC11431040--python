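"""From per-primer RT-stop peak tables to one assembled reactivity profile.

Each primer reads its own template section (between adjacent primer pairing
positions); a sized cDNA peak of length k maps to the RT stop — and hence
the chain break — at template position ``pairing_start - k``. Sections are
assembled into a single 1..L profile, box-plot normalized (mean of the 8%
of values below the top 2%), and referenced to an untreated control by
subtraction with clamping at zero.

Missing values (NaN) mark positions no primer reads: primer footprints, the
region 3' of the last pairing start (e.g. the poly(A) tail), and any
configured exclusion margin next to a primer.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .construct import MrnaConstruct, RtPrimer, SectionMap

logger = logging.getLogger(__name__)

__all__ = [
    "ReactivityProfile",
    "NormalizationError",
    "AssemblyConflictError",
    "peaks_to_positions",
    "normalize_profile",
    "subtract_control",
    "assemble_sections",
    "mean_reactivity",
]


class NormalizationError(ValueError):
    """Normalization factor cannot be computed (e.g. all-zero section)."""


class AssemblyConflictError(ValueError):
    """Two primers claim the same template position after clipping."""


@dataclass
class ReactivityProfile:
    """Per-nucleotide reactivity vector (1-based positions, NaN = unread).

    ``section`` records which primer's read each position came from;
    ``normalization`` maps section name -> divisor applied (empty if raw);
    ``clamped`` counts negatives clamped to zero during control subtraction.
    """

    values: np.ndarray
    treatment: str = ""
    section: np.ndarray | None = None
    normalization: dict[str, float] = field(default_factory=dict)
    clamped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.section is None:
            self.section = np.full(self.values.size, "", dtype=object)
        else:
            self.section = np.asarray(self.section, dtype=object)
        if self.section.size != self.values.size:
            raise ValueError("section provenance length differs from values")

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, position: int) -> float:
        return float(self.values[position - 1])

    @property
    def mask_missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def n_observed(self) -> int:
        return int(np.sum(~self.mask_missing))

    def window_mean(self, start: int, end: int) -> float:
        if not 1 <= start <= end <= len(self):
            raise IndexError(f"window {start}..{end} outside profile 1..{len(self)}")
        window = self.values[start - 1 : end]
        if np.all(np.isnan(window)):
            raise ValueError(f"window {start}..{end} has no observed positions")
        return float(np.nanmean(window))

    def copy_with(self, values: np.ndarray, **kwargs) -> "ReactivityProfile":
        out = ReactivityProfile(
            values=values,
            treatment=kwargs.get("treatment", self.treatment),
            section=self.section.copy(),
            normalization=dict(kwargs.get("normalization", self.normalization)),
            clamped=kwargs.get("clamped", self.clamped),
        )
        return out

    def to_frame(self, construct: MrnaConstruct | None = None) -> pd.DataFrame:
        pos = np.arange(1, len(self) + 1)
        df = pd.DataFrame(
            {
                "position": pos,
                "base": list(construct.sequence) if construct is not None else "",
                "reactivity": self.values,
                "section": self.section,
                "treatment": self.treatment,
            }
        )
        return df

    def write_tsv(self, path: str | Path, construct: MrnaConstruct | None = None) -> None:
        self.to_frame(construct).to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_wig(self, path: str | Path, chrom: str = "mrna") -> None:
        """Wiggle-like export for genome-browser-style viewing."""
        with open(path, "w") as fh:
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            for v in self.values:
                fh.write("NA\n" if math.isnan(v) else f"{v:.6g}\n")


def peaks_to_positions(peak_table, primer: RtPrimer) -> dict[int, float]:
    """Map sized cDNA peaks to template RT-stop positions.

    A peak of cDNA length k read by a primer pairing at ``pairing_start``
    stops at template position ``pairing_start - k``; intensities landing on
    the same position are summed.
    """
    out: dict[int, float] = {}
    for k, intensity in zip(peak_table.lengths, peak_table.intensities):
        k = int(k)
        if k >= primer.pairing_start:
            raise IndexError(
                f"cDNA length {k} >= pairing start {primer.pairing_start} "
                f"for primer {primer.name}: stop would fall off the template"
            )
        pos = primer.pairing_start - k
        out[pos] = out.get(pos, 0.0) + float(intensity)
    return out


def _boxplot_factor(values: np.ndarray, name: str) -> float:
    """Mean of the 8% of values directly below the top 2% (model-free
    normalization scale; with 100 values this is the mean of ranks 3-10
    from the top)."""
    vals = np.sort(values)[::-1]
    n = vals.size
    n_excl = max(1, math.ceil(0.02 * n))
    n_avg = max(1, math.ceil(0.08 * n))
    band = vals[n_excl : n_excl + n_avg]
    if band.size == 0 or float(band.mean()) <= 0:
        raise NormalizationError(
            f"cannot normalize section {name!r}: no positive signal in the "
            "2-8% reference band"
        )
    return float(band.mean())


def normalize_profile(
    raw: ReactivityProfile,
    per_section: bool = True,
    factors: Mapping[str, float] | None = None,
) -> ReactivityProfile:
    """Box-plot (2%/8%) normalization, per section by default.

    Pass ``factors`` (section -> divisor, or {"global": divisor}) to reuse a
    previously computed scale — e.g. a control sample's factors — so that
    treated samples stay on a common, dose-comparable scale.
    """
    obs = ~raw.mask_missing
    if int(obs.sum()) < 10:
        raise NormalizationError("need >= 10 observed positions to normalize")
    values = raw.values.copy()
    applied: dict[str, float] = {}
    if per_section:
        for name in dict.fromkeys(s for s in raw.section[obs]):
            sel = obs & (raw.section == name)
            f = (
                float(factors[name])
                if factors is not None
                else _boxplot_factor(values[sel], str(name))
            )
            values[sel] = values[sel] / f
            applied[str(name)] = f
    else:
        f = (
            float(factors["global"])
            if factors is not None
            else _boxplot_factor(values[obs], "global")
        )
        values[obs] = values[obs] / f
        applied["global"] = f
    return raw.copy_with(values, normalization=applied)


def subtract_control(
    treated: ReactivityProfile, control: ReactivityProfile
) -> ReactivityProfile:
    """Per-position treated minus control; negatives clamp to 0 (degradation
    cannot be negative) and the clamp count is logged; missing propagates."""
    if len(treated) != len(control):
        raise ValueError(
            f"profile lengths differ: {len(treated)} vs {len(control)}"
        )
    diff = treated.values - control.values
    neg = diff < 0
    n_clamped = int(np.sum(neg))
    if n_clamped:
        logger.info(
            "subtract_control: clamped %d negative positions to 0", n_clamped
        )
    diff[neg] = 0.0
    out = treated.copy_with(diff, clamped=n_clamped)
    return out


def assemble_sections(
    per_primer_maps: Mapping[str, Mapping[int, float]],
    section_map: SectionMap,
    length: int,
    primers: list[RtPrimer] | None = None,
    treatment: str = "",
    exclusion_margin: int = 0,
) -> ReactivityProfile:
    """Merge per-primer position->intensity maps into one 1..L profile.

    Each primer contributes only positions inside its own section
    (out-of-section contributions at section joints are discarded, since
    each ~500 nt window belongs to exactly one primer); unread positions —
    primer footprints, anything 3' of the last pairing start, and an
    optional ``exclusion_margin`` of first-extended nucleotides next to each
    pairing site — are NaN. Positions read by a primer but with no recorded
    stop are 0.
    """
    values = np.full(length, np.nan)
    section = np.full(length, "", dtype=object)
    written = np.zeros(length, dtype=bool)

    readable = np.zeros(length, dtype=bool)
    owner: dict[str, tuple[int, int]] = {}
    for sec in section_map:
        owner[sec.primer] = (sec.covered_start, sec.covered_end)
        readable[sec.covered_start - 1 : sec.covered_end] = True
    if section_map.uncovered_start <= length:
        readable[section_map.uncovered_start - 1 :] = False
    for primer in primers or []:
        readable[primer.pairing_start - 1 : primer.pairing_end] = False
        if exclusion_margin > 0:
            lo = max(1, primer.pairing_start - exclusion_margin)
            values[lo - 1 : primer.pairing_start - 1] = np.nan
            readable[lo - 1 : primer.pairing_start - 1] = False

    for sec in section_map:
        idx = slice(sec.covered_start - 1, sec.covered_end)
        sel = readable[idx]
        values[idx] = np.where(sel, 0.0, np.nan)
        section[idx] = np.where(sel, sec.primer, "")

    for name, pos_map in per_primer_maps.items():
        if name not in owner:
            raise AssemblyConflictError(f"primer {name!r} has no section")
        lo, hi = owner[name]
        for pos, intensity in pos_map.items():
            if not lo <= pos <= hi:
                continue  # joint overlap: belongs to another primer's section
            if not readable[pos - 1]:
                continue  # footprint or excluded margin
            if written[pos - 1]:
                raise AssemblyConflictError(
                    f"position {pos} written by two primers (second: {name!r})"
                )
            values[pos - 1] = float(intensity)
            written[pos - 1] = True

    return ReactivityProfile(values=values, treatment=treatment, section=section)


def mean_reactivity(profile: ReactivityProfile | np.ndarray) -> float:
    """Arithmetic mean over observed (non-missing) positions."""
    values = profile.values if isinstance(profile, ReactivityProfile) else np.asarray(profile, dtype=float)
    obs = ~np.isnan(values)
    if not obs.any():
        raise ValueError("profile has no observed positions")
    return float(values[obs].mean())
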