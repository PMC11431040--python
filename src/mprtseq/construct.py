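"""mRNA construct model: sequence, element annotation and the RT primer panel.

Coordinates are 1-based inclusive throughout, matching the residue numbering
used on annotated mRNA maps; conversion to 0-based half-open happens only at
file boundaries (FASTA, BED export).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")


class AnnotationError(ValueError):
    """Element annotation is overlapping, gapped or malformed."""


class BoundsError(IndexError):
    """A 1-based coordinate falls outside the construct."""


class ConfigurationError(ValueError):
    """Invalid primer panel or pipeline configuration."""


@dataclass(frozen=True)
class RtPrimer:
    """A reverse-transcription primer annealing on the mRNA template.

    ``pairing_start``/``pairing_end`` are the 1-based inclusive template
    positions the primer hybridises to; the RT extends from
    ``pairing_start - 1`` towards the 5' end. ``labeled_5prime`` marks a
    5'-fluorescein (FAM) label enabling capillary detection of cDNA sizes.
    """

    name: str
    pairing_start: int
    pairing_end: int
    labeled_5prime: bool = True

    def __post_init__(self) -> None:
        if not self.pairing_start < self.pairing_end:
            raise ConfigurationError(
                f"primer {self.name}: pairing_start must be < pairing_end "
                f"(got {self.pairing_start}..{self.pairing_end})"
            )
        if self.pairing_start < 1:
            raise ConfigurationError(f"primer {self.name}: positions are 1-based")


@dataclass(frozen=True)
class Section:
    """Template interval read by one primer (1-based inclusive)."""

    primer: str
    covered_start: int
    covered_end: int

    def __contains__(self, position: int) -> bool:
        return self.covered_start <= position <= self.covered_end


@dataclass(frozen=True)
class SectionMap:
    """Disjoint per-primer template intervals tiling the readable region.

    Primer *i* reads the interval between the previous primer's pairing
    start and its own pairing start; the 5'-most primer reads from position 1.
    Everything 3' of the last primer's pairing start (e.g. a poly(A) tail)
    is unread and reported via :attr:`uncovered_start`.
    """

    sections: tuple[Section, ...]
    uncovered_start: int  # first template position no primer reads

    def __iter__(self):
        return iter(self.sections)

    def __len__(self) -> int:
        return len(self.sections)

    def section_of(self, position: int) -> Section | None:
        """Return the section owning ``position`` or None if unread."""
        for sec in self.sections:
            if position in sec:
                return sec
        return None


@dataclass
class MrnaConstruct:
    """An mRNA construct: sequence, ordered element annotation, primer panel.

    ``elements`` is an ordered list of ``(label, start, end)`` with 1-based
    inclusive coordinates. Non-poly(A) elements must tile the body of the
    molecule (positions 1 .. poly(A) start - 1) without gaps or overlaps.
    """

    name: str
    sequence: str
    elements: list[tuple[str, int, int]]
    primers: list[RtPrimer] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise AnnotationError(
                f"sequence contains non-RNA characters: {sorted(bad)}"
            )
        self._validate_elements()
        self.primers = sorted(self.primers, key=lambda p: p.pairing_start)
        for a, b in zip(self.primers, self.primers[1:]):
            if b.pairing_start <= a.pairing_end:
                raise ConfigurationError(
                    f"primer pairing intervals overlap: {a.name} and {b.name}"
                )

    def _validate_elements(self) -> None:
        L = len(self.sequence)
        for label, start, end in self.elements:
            if not (1 <= start <= end <= L):
                raise BoundsError(
                    f"element {label!r} interval {start}..{end} outside 1..{L}"
                )
        body = [e for e in self.elements if not _is_polya(e[0])]
        polya = [e for e in self.elements if _is_polya(e[0])]
        body_end = polya[0][1] - 1 if polya else L
        body_sorted = sorted(body, key=lambda e: e[1])
        cursor = 1
        for label, start, end in body_sorted:
            if start != cursor:
                kind = "overlap" if start < cursor else "gap"
                raise AnnotationError(
                    f"annotation {kind} at position {min(start, cursor)} "
                    f"(element {label!r})"
                )
            cursor = end + 1
        if body_sorted and cursor != body_end + 1:
            raise AnnotationError(
                f"non-poly(A) elements end at {cursor - 1}, expected {body_end}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        self._check_bounds(position)
        return self.sequence[position - 1]

    def element_at(self, position: int) -> str:
        """Label of the annotated element containing a 1-based position."""
        self._check_bounds(position)
        for label, start, end in self.elements:
            if start <= position <= end:
                return label
        raise AnnotationError(f"position {position} is not annotated")

    def _check_bounds(self, position: int) -> None:
        if not (1 <= position <= len(self)):
            raise BoundsError(
                f"position {position} outside construct 1..{len(self)}"
            )

    def section_map(self) -> SectionMap:
        return build_section_map(self.primers, len(self))


def _is_polya(label: str) -> bool:
    norm = label.lower().replace(" ", "").replace("-", "").replace("(", "").replace(")", "")
    return norm in {"polya", "polyatail"}


def build_section_map(primers: Sequence[RtPrimer], construct_length: int) -> SectionMap:
    """Partition the readable template into per-primer sections.

    Primer *i* covers ``previous pairing_start .. own pairing_start - 1``;
    the 5'-most primer covers ``1 .. pairing_start - 1``. Positions at or
    3' of the last pairing start are flagged uncovered.
    """
    if not primers:
        raise ConfigurationError("primer panel is empty")
    ordered = sorted(primers, key=lambda p: p.pairing_start)
    sections = []
    prev_start = 1
    for primer in ordered:
        sections.append(Section(primer.name, prev_start, primer.pairing_start - 1))
        prev_start = primer.pairing_start
    if ordered[-1].pairing_end > construct_length:
        raise BoundsError(
            f"primer {ordered[-1].name} pairs beyond construct end {construct_length}"
        )
    return SectionMap(tuple(sections), uncovered_start=ordered[-1].pairing_start)


# ---------------------------------------------------------------------------
# I/O


def load_construct(
    fasta_path: str | Path,
    annotation_table: str | Path | Iterable[tuple[str, int, int]],
    primers: Sequence[RtPrimer] = (),
) -> MrnaConstruct:
    """Load a single-record FASTA plus an element annotation table.

    ``annotation_table`` may be a TSV path (columns label/name, start, end)
    or an iterable of ``(label, start, end)`` tuples. DNA-style ``T``
    characters are transliterated to ``U`` with a logged warning.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise AnnotationError(
            f"expected exactly one FASTA record in {fasta_path}, got {len(records)}"
        )
    record = records[0]
    seq = str(record.seq).upper()
    if "T" in seq:
        logger.warning(
            "FASTA record %s contains T characters; transliterating to U", record.id
        )
        seq = seq.replace("T", "U")
    if isinstance(annotation_table, (str, Path)):
        elements = read_annotation(annotation_table)
    else:
        elements = [(str(l), int(s), int(e)) for l, s, e in annotation_table]
    return MrnaConstruct(record.id, seq, elements, list(primers))


def write_construct_fasta(construct: MrnaConstruct, path: str | Path) -> None:
    rec = SeqRecord(Seq(construct.sequence), id=construct.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_annotation(path: str | Path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    label_col = "label" if "label" in df.columns else "name"
    return [
        (str(r[label_col]), int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    ]


def write_annotation(elements: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    pd.DataFrame(elements, columns=["label", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_primer_table(path: str | Path) -> list[RtPrimer]:
    """Read a primer panel TSV (columns: name, start, end[, labeled])."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for _, r in df.iterrows():
        labeled = bool(r["labeled"]) if "labeled" in df.columns else True
        out.append(RtPrimer(str(r["name"]), int(r["start"]), int(r["end"]), labeled))
    return out


def write_primer_table(primers: Iterable[RtPrimer], path: str | Path) -> None:
    pd.DataFrame(
        [(p.name, p.pairing_start, p.pairing_end, p.labeled_5prime) for p in primers],
        columns=["name", "start", "end", "labeled"],
    ).to_csv(path, sep="\t", index=False)
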