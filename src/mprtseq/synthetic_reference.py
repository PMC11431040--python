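"""Synthetic reference fixture: a GFP-Luc-style 2896-nt mRNA construct.

The real mRNA studied with this method is not publicly deposited, so this
module generates a *synthetic* stand-in that carries everything the
pipeline's worked examples and tests need, deterministically and in code:

* a 2896-nt RNA whose element map matches the published construct layout
  (5' UTR 1-52, Luc 53-1702, linker 1703-1768, GFP 1769-2485, stop codons
  2486-2491, 3' UTR 2492-2786, poly(A) 2787-2896);
* the six RT primers at their published pairing positions;
* the published degradation-sensitive motifs planted at their published
  coordinates (GCUUCAGCC ending in GCC 1986-1988, CUCGCCGACC ending in
  CGACC 2308-2312, UUCGU at 2438-2442, UUGGU at 2750-2754, plus the
  single-nucleotide sites G2569, G2577, U2751 within them, and C1483);
* a synthetic secondary structure placing each shared hotspot on the
  5' strand of a bulge-stem-loop hairpin;
* deterministic per-regime reactivity profiles whose background sits below
  the regime baseline and whose hotspot windows reproduce the published
  fold changes over the regime reference averages.

Everything else about the sequence is random (fixed internal seed) and has
no biological meaning.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .construct import MrnaConstruct, RtPrimer, build_section_map
from .degmodel import DegradationBaseline, FREEZE_THAW_BASELINE, HEAT_BASELINE
from .reactivity import ReactivityProfile
from .structure import SecondaryStructure, parse_dotbracket

__all__ = [
    "ReferenceBundle",
    "reference_construct",
    "reference_primers",
    "reference_structure",
    "reference_profiles",
    "reference_bundle",
    "SHARED_HOTSPOT_SPANS",
]

_SEED = 20240916
CONSTRUCT_LENGTH = 2896

ELEMENTS = [
    ("5' UTR", 1, 52),
    ("Luc", 53, 1702),
    ("linker", 1703, 1768),
    ("GFP", 1769, 2485),
    ("stop codons", 2486, 2491),
    ("3' UTR", 2492, 2786),
    ("poly(A)", 2787, 2896),
]

PRIMER_POSITIONS = [
    ("RT1", 554, 573),
    ("RT2", 1036, 1053),
    ("RT3", 1561, 1578),
    ("RT4", 2065, 2082),
    ("RT5", 2493, 2510),
    ("RT6", 2771, 2788),
]

#: motifs planted into the synthetic sequence, (sequence, start position)
_MOTIFS = [
    ("GCUUCAGCC", 1980),   # shared hotspot 1; GCC = 1986-1988
    ("CUCGCCGACC", 2303),  # shared hotspot 2; CGACC = 2308-2312
    ("UUCGU", 2438),       # shared hotspot 3
    ("UUGGU", 2750),       # shared hotspot 4; UUGG = 2750-2753
    ("C", 1483),
    ("G", 2569),
    ("UAGGU", 2574),
]

#: the four intervals sensitive in both stress regimes
SHARED_HOTSPOT_SPANS = [(1986, 1988), (2307, 2312), (2438, 2442), (2750, 2753)]

#: hairpins planted in the synthetic structure: 7-bp outer stem, 1-nt 5'
#: bulge, 4-bp inner stem, 4-nt apical loop (27 nt total)
_HAIRPIN = "(((((((" + "." + "((((" + "...." + "))))" + ")))))))"
_HAIRPIN_STARTS = [120, 900, 1620, 1984, 2306, 2437, 2748]

#: per-regime hotspot reactivities: position range -> value, chosen so each
#: window mean equals (regime reference average) x (observed fold change)
_FREEZE_SPIKES = {
    (1986, 1988): 15.8 * 3.5,   # GCC
    (2308, 2312): 11.3 * 3.5,   # CGACC
    (2438, 2440): 9.1 * 3.5,    # UUC
    (2569, 2569): 134.6 * 3.5,  # G
    (2577, 2577): 19.6 * 3.5,   # G
    (2751, 2751): 56.9 * 3.5,   # U
    (2750, 2750): 30.0,
    (2752, 2753): 30.0,
}
_HEAT_SPIKES = {
    (1483, 1483): 25.1 * 14.8,  # C in Luc
    (1986, 1988): 14.0 * 17.7,  # GCC
    (2307, 2312): 8.0 * 19.8,   # CCGACC
    (2438, 2442): 100.0,        # UUCGU
    (2574, 2578): 9.0 * 21.7,   # UAGGU
    (2750, 2753): 22.1 * 23.1,  # UUGG
}


def reference_primers() -> list[RtPrimer]:
    return [RtPrimer(n, s, e, labeled_5prime=True) for n, s, e in PRIMER_POSITIONS]


def reference_construct() -> MrnaConstruct:
    """Deterministic synthetic 2896-nt construct with planted motifs."""
    rng = np.random.default_rng(_SEED)
    bases = np.array(list("ACGU"))
    seq = rng.choice(bases, size=CONSTRUCT_LENGTH, p=[0.24, 0.27, 0.27, 0.22])
    polya_start = ELEMENTS[-1][1]
    seq[polya_start - 1 :] = "A"
    for motif, start in _MOTIFS:
        seq[start - 1 : start - 1 + len(motif)] = list(motif)
    return MrnaConstruct(
        name="synthetic_GFP-Luc_mRNA",
        sequence="".join(seq),
        elements=list(ELEMENTS),
        primers=reference_primers(),
    )


def reference_structure() -> SecondaryStructure:
    """Synthetic secondary structure over the folded body (1..2786).

    Mostly single-stranded, with bulge-stem-loop hairpins planted so each
    shared hotspot sits on the 5' strand of an outer stem that carries a
    mid-stem bulge and terminates in an apical loop.
    """
    body_len = ELEMENTS[-1][1] - 1  # exclude the unpaired poly(A) tail
    chars = ["."] * body_len
    for start in _HAIRPIN_STARTS:
        chars[start - 1 : start - 1 + len(_HAIRPIN)] = list(_HAIRPIN)
    return parse_dotbracket("".join(chars))


def _background_profile(
    construct: MrnaConstruct, high: float, treatment: str, rng: np.random.Generator
) -> ReactivityProfile:
    L = len(construct)
    section_map = construct.section_map()
    values = np.full(L, np.nan)
    section = np.full(L, "", dtype=object)
    for sec in section_map:
        idx = slice(sec.covered_start - 1, sec.covered_end)
        values[idx] = rng.uniform(0.0, high, sec.covered_end - sec.covered_start + 1)
        section[idx] = sec.primer
    for p in construct.primers:
        values[p.pairing_start - 1 : p.pairing_end] = np.nan
        section[p.pairing_start - 1 : p.pairing_end] = ""
    values[section_map.uncovered_start - 1 :] = np.nan
    section[section_map.uncovered_start - 1 :] = ""
    return ReactivityProfile(values=values, treatment=treatment, section=section)


def reference_profiles() -> dict[str, ReactivityProfile]:
    """Deterministic normalized, control-subtracted profiles per regime."""
    construct = reference_construct()
    rng = np.random.default_rng(_SEED + 1)
    profiles = {}
    for regime, baseline, spikes, bg_high in [
        ("freeze_thaw", FREEZE_THAW_BASELINE, _FREEZE_SPIKES, 3.0),
        ("heat_37C", HEAT_BASELINE, _HEAT_SPIKES, 7.5),
    ]:
        prof = _background_profile(construct, bg_high, regime, rng)
        for (start, end), value in spikes.items():
            prof.values[start - 1 : end] = value
        profiles[regime] = prof
    return profiles


@dataclass
class ReferenceBundle:
    """Everything the worked examples need, generated deterministically."""

    construct: MrnaConstruct
    structure: SecondaryStructure
    profiles: dict[str, ReactivityProfile]
    baselines: dict[str, DegradationBaseline]

    @property
    def section_map(self):
        return build_section_map(self.construct.primers, len(self.construct))


def reference_bundle() -> ReferenceBundle:
    return ReferenceBundle(
        construct=reference_construct(),
        structure=reference_structure(),
        profiles=reference_profiles(),
        baselines={
            "freeze_thaw": FREEZE_THAW_BASELINE,
            "heat_37C": HEAT_BASELINE,
        },
    )
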