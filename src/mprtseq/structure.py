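"""Secondary-structure parsing, loop decomposition and motif context.

Consumes Vienna dot-bracket strings (nested parentheses only; pseudoknot
bracket layers are rejected, not silently mis-parsed) and classifies every
nucleotide into one of seven structural elements:

``stem_5prime`` / ``stem_3prime``
    paired position i with partner j, on the 5' (i < j) or 3' (i > j)
    strand of the helix;
``hairpin_loop``
    unpaired run closed by a single pair with no enclosed pairs;
``bulge``
    loop between two helices with unpaired bases on exactly one strand;
``internal_loop``
    loop between two helices with unpaired bases on both strands;
``multiloop``
    loop closed by three or more helices;
``exterior``
    unpaired and not enclosed by any pair.

The motif annotation answers the questions asked of degradation-sensitive
sequences: does the site lie on the 5' strand of a hairpin stem, does that
stem terminate in an apical (top) loop, and is the stem interrupted by a
mid-stem bulge between the site and the loop?
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "SecondaryStructure",
    "MotifSummary",
    "DotBracketError",
    "parse_dotbracket",
    "classify_elements",
    "annotate_hotspot_structure",
    "read_dotbracket",
    "write_dotbracket",
    "write_ct",
]

ELEMENT_LABELS = (
    "stem_5prime",
    "stem_3prime",
    "hairpin_loop",
    "bulge",
    "internal_loop",
    "multiloop",
    "exterior",
)

_PSEUDOKNOT_CHARS = set("[]{}<>") | set("abcdefghijklmnopqrstuvwxyz") | set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
)


class DotBracketError(ValueError):
    """Malformed dot-bracket text (bad character or unbalanced brackets)."""


@dataclass
class SecondaryStructure:
    """A nested secondary structure: dot-bracket text plus its pair table.

    ``pairs`` maps 1-based i -> j for every paired position (both
    directions), an involution with no position paired twice.
    """

    dotbracket: str
    pairs: dict[int, int]
    _labels: list[str] | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.dotbracket)

    def partner(self, i: int) -> int | None:
        return self.pairs.get(i)

    def pair_list(self) -> list[tuple[int, int]]:
        """Sorted (i, j) pairs with i < j."""
        return sorted((i, j) for i, j in self.pairs.items() if i < j)

    def element_labels(self) -> list[str]:
        """Per-nucleotide element label (index 0 = position 1), cached."""
        if self._labels is None:
            self._labels = classify_elements(self.pairs, len(self))
        return self._labels

    def element_at(self, position: int) -> str:
        return self.element_labels()[position - 1]


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Stack-match a dot-bracket string into a pair table.

    Raises :class:`DotBracketError` with the offending 1-based position on
    unbalanced brackets or unsupported (pseudoknot) characters.
    """
    text = text.strip()
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unmatched ')' at position {pos}")
            i = stack.pop()
            pairs[i] = pos
            pairs[pos] = i
        elif ch == ".":
            continue
        elif ch in _PSEUDOKNOT_CHARS:
            raise DotBracketError(
                f"unsupported bracket {ch!r} at position {pos}: "
                "pseudoknot layers are not handled"
            )
        else:
            raise DotBracketError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise DotBracketError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(text, pairs)


def classify_elements(pairs: dict[int, int], length: int) -> list[str]:
    """Loop-decompose a pair table into per-nucleotide element labels.

    One pass with a loop stack: every pair opens a loop that collects its
    directly-enclosed unpaired positions and child helices; on closure the
    loop is labelled by its degree (0 children = hairpin, 1 = bulge or
    internal loop depending on which strands carry unpaired bases,
    >=2 = multiloop). The root loop is the exterior.
    """
    labels = [""] * length
    # each frame: [opening position or None, unpaired positions, child pairs]
    root: list = [None, [], []]
    stack: list[list] = [root]
    for i in range(1, length + 1):
        j = pairs.get(i)
        if j is None:
            stack[-1][1].append(i)
        elif i < j:
            labels[i - 1] = "stem_5prime"
            stack[-1][2].append((i, j))
            stack.append([i, [], []])
        else:
            labels[i - 1] = "stem_3prime"
            opening, unpaired, children = stack.pop()
            label = _loop_label(opening, i, unpaired, children)
            for u in unpaired:
                labels[u - 1] = label
    for u in root[1]:
        labels[u - 1] = "exterior"
    return labels


def _loop_label(
    open_pos: int, close_pos: int, unpaired: list[int], children: list[tuple[int, int]]
) -> str:
    if not children:
        return "hairpin_loop"
    if len(children) >= 2:
        return "multiloop"
    (c_start, c_end), = children
    side5 = any(open_pos < u < c_start for u in unpaired)
    side3 = any(c_end < u < close_pos for u in unpaired)
    if side5 and side3:
        return "internal_loop"
    return "bulge"


@dataclass
class MotifSummary:
    """Structural context of a degradation-sensitive site.

    The operational rule (recorded here so downstream reports carry it):
    ``on_5prime_stem_side`` — a strict majority of the site's paired
    positions lie on the 5' strand of their helices; ``has_apical_loop`` —
    following the helix stack inward from the site (through stacked pairs,
    bulges and internal loops) ends in a hairpin loop rather than a
    multiloop; ``has_mid_stem_bulge`` — a bulge or internal loop interrupts
    that stack between the site and the apical loop, or falls within the
    site span itself. Distances are nucleotide gaps (0 = overlapping).
    """

    on_5prime_stem_side: bool
    has_apical_loop: bool
    has_mid_stem_bulge: bool
    hairpin_span: tuple[int, int] | None = None
    distance_to_loop: int | None = None
    distance_to_bulge: int | None = None

    RULE = (
        "5' side = majority of paired positions with i < partner; apical loop = "
        "inward helix-stack walk terminates in a hairpin loop; mid-stem bulge = "
        "bulge/internal loop on that walk or within the site span"
    )

    def to_dict(self) -> dict:
        return {
            "on_5prime_stem_side": self.on_5prime_stem_side,
            "has_apical_loop": self.has_apical_loop,
            "has_mid_stem_bulge": self.has_mid_stem_bulge,
            "hairpin_span": list(self.hairpin_span) if self.hairpin_span else None,
            "distance_to_loop": self.distance_to_loop,
            "distance_to_bulge": self.distance_to_bulge,
            "rule": self.RULE,
        }


def _children_of(structure: SecondaryStructure, a: int, b: int) -> list[tuple[int, int]]:
    """Pairs directly enclosed by (a, b)."""
    out = []
    i = a + 1
    while i < b:
        j = structure.pairs.get(i)
        if j is not None and j > i:
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def _span_distance(start: int, end: int, positions: list[int]) -> int | None:
    if not positions:
        return None
    return min(
        0 if start <= p <= end else min(abs(p - start), abs(p - end))
        for p in positions
    )


def annotate_hotspot_structure(
    hotspot, structure: SecondaryStructure
) -> MotifSummary:
    """Annotate a hotspot span (object with start/end, or a (start, end)
    tuple) with its helix-stack context."""
    if hasattr(hotspot, "start"):
        start, end = hotspot.start, hotspot.end
    else:
        start, end = hotspot
    if not (1 <= start <= end <= len(structure)):
        raise IndexError(
            f"hotspot {start}..{end} outside structure 1..{len(structure)}"
        )

    labels = structure.element_labels()
    span = range(start, end + 1)
    n5 = sum(labels[i - 1] == "stem_5prime" for i in span)
    n3 = sum(labels[i - 1] == "stem_3prime" for i in span)
    on_5prime = n5 > n3 and n5 > 0

    own_pairs = sorted(
        {
            (min(i, structure.pairs[i]), max(i, structure.pairs[i]))
            for i in span
            if i in structure.pairs
        }
    )
    # bulge/internal positions inside the span count as in-stack interruptions
    interruptions = [
        i for i in span if labels[i - 1] in ("bulge", "internal_loop")
    ]
    if not own_pairs:
        return MotifSummary(
            on_5prime_stem_side=False,
            has_apical_loop=False,
            has_mid_stem_bulge=bool(interruptions),
            distance_to_bulge=_span_distance(start, end, interruptions),
        )

    # walk inward from the innermost of the hotspot's own pairs
    a, b = min(own_pairs, key=lambda p: p[1] - p[0])
    has_apical = False
    apical_positions: list[int] = []
    while True:
        children = _children_of(structure, a, b)
        if not children:
            has_apical = True
            apical_positions = [i for i in range(a + 1, b) if i not in structure.pairs]
            if not apical_positions:  # zero-length hairpin loop
                apical_positions = [a + 1] if a + 1 < b else [a]
            break
        if len(children) >= 2:
            break  # stack ends in a multiloop: no apical loop
        (ca, cb), = children
        interruptions.extend(
            u for u in range(a + 1, ca) if u not in structure.pairs
        )
        interruptions.extend(
            u for u in range(cb + 1, b) if u not in structure.pairs
        )
        a, b = ca, cb

    # walk outward while the stack continues through single-branch loops,
    # to report the enclosing hairpin span
    oa, ob = max(own_pairs, key=lambda p: p[1] - p[0])
    while True:
        parent = _enclosing_pair(structure, oa, ob)
        if parent is None:
            break
        pa, pb = parent
        if len(_children_of(structure, pa, pb)) != 1:
            break
        oa, ob = pa, pb

    interruptions = sorted(set(interruptions))
    return MotifSummary(
        on_5prime_stem_side=on_5prime,
        has_apical_loop=has_apical,
        has_mid_stem_bulge=bool(interruptions),
        hairpin_span=(oa, ob),
        distance_to_loop=_span_distance(start, end, apical_positions)
        if has_apical
        else None,
        distance_to_bulge=_span_distance(start, end, interruptions),
    )


def _enclosing_pair(structure: SecondaryStructure, a: int, b: int) -> tuple[int, int] | None:
    """Innermost pair strictly enclosing (a, b)."""
    best = None
    for i, j in structure.pair_list():
        if i < a and b < j and (best is None or j - i < best[1] - best[0]):
            best = (i, j)
    return best


# ---------------------------------------------------------------------------
# I/O


def read_dotbracket(path: str | Path) -> tuple[str | None, SecondaryStructure]:
    """Read a Vienna file: optional >header, sequence line, structure line.

    Returns (sequence or None, structure); a lone structure line is accepted.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if not lines:
        raise DotBracketError(f"{path}: no structure line found")
    if len(lines) >= 2:
        seq, db = lines[0], lines[1]
        if len(seq) != len(db):
            raise DotBracketError(
                f"{path}: sequence length {len(seq)} != structure length {len(db)}"
            )
        return seq, parse_dotbracket(db)
    return None, parse_dotbracket(lines[0])


def write_dotbracket(
    path: str | Path,
    structure: SecondaryStructure,
    sequence: str | None = None,
    name: str = "structure",
) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        if sequence is not None:
            fh.write(sequence + "\n")
        fh.write(structure.dotbracket + "\n")


def write_ct(
    path: str | Path, structure: SecondaryStructure, sequence: str, name: str = "structure"
) -> None:
    """Connectivity-table (.ct) export for interoperability."""
    L = len(structure)
    if len(sequence) != L:
        raise DotBracketError("sequence and structure lengths differ")
    with open(path, "w") as fh:
        fh.write(f"{L} {name}\n")
        for i in range(1, L + 1):
            j = structure.pairs.get(i, 0)
            fh.write(f"{i} {sequence[i - 1]} {i - 1} {i + 1 if i < L else 0} {j} {i}\n")
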