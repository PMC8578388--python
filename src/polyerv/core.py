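"""Shared domain types and small interval utilities.

Coordinates are 0-based, half-open throughout (BED convention). A genome
assembly is represented as a plain mapping ``{chromosome name: sequence}``
over the alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default RepeatMasker-style label set marking an element as an ERV:
#: class "LTR" with one of these family labels.
ERV_FAMILIES = frozenset({"ERV1", "ERVK", "ERVL", "ERVL-MaLR"})
ERV_CLASS = "LTR"

ANNOTATION_COLUMNS = [
    "chrom", "start", "end", "element_id", "subfamily", "strand",
    "family", "class",
]


@dataclass(frozen=True)
class RepeatElement:
    """An annotated repeat interval — the atomic unit of all calls."""

    chrom: str
    start: int
    end: int
    element_id: str
    subfamily: str
    family: str
    class_: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.element_id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def is_erv(self, erv_families: frozenset[str] = ERV_FAMILIES) -> bool:
        return self.class_ == ERV_CLASS and self.family in erv_families


@dataclass
class PpreCall:
    """A potential polymorphic repeat call with its evidence trail.

    ``final`` requires both evidence streams (assembly-gap containment and
    WGS coverage asymmetry) to agree.
    """

    element: RepeatElement
    private_to: str
    evidence_assembly: bool = False
    evidence_coverage: bool = False
    final: bool = False

    def __post_init__(self) -> None:
        if self.final and not (self.evidence_assembly and self.evidence_coverage):
            raise ValueError("final call requires both evidence streams")


def elements_to_frame(elements: list[RepeatElement]) -> pd.DataFrame:
    """Convert a list of elements to the canonical BED6+2 annotation table."""
    rows = [
        (e.chrom, e.start, e.end, e.element_id, e.subfamily, e.strand,
         e.family, e.class_)
        for e in elements
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def frame_to_elements(frame: pd.DataFrame) -> list[RepeatElement]:
    return [
        RepeatElement(
            chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"]),
            element_id=str(r["element_id"]), subfamily=str(r["subfamily"]),
            family=str(r["family"]), class_=str(r["class"]),
            strand=str(r["strand"]),
        )
        for r in frame.to_dict("records")
    ]


def interval_tss_distance(start: int, end: int, tss: int) -> int:
    """Distance between a half-open interval [start, end) and a point.

    Zero when the point lies inside the interval.
    """
    return max(start - tss, tss - (end - 1), 0)


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit encode a nucleotide string; N and other ambiguity codes -> 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]
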