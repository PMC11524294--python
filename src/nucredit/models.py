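"""Domain types shared across the pipeline.

Coordinate convention: every in-memory position is 0-based; intervals are
half-open ``[start, end)``. File formats (GFF3, pileup TSV, sites TSV/VCF,
evidence TSV) carry 1-based inclusive coordinates; the conversion happens in
:mod:`nucredit.io` and nowhere else.

Alignment space is the transcript (sense) strand: reads are assumed aligned to
primary-transcript templates, so substitution labels never need
reverse-complement logic. Sequences are stored in the DNA alphabet (T); the
human-readable substitution labels use U on both sides ("C-to-U") as is
conventional for RNA editing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

BASES = ("A", "C", "G", "T")

#: the 12 ordered substitution types in RNA nomenclature, row-major over (ref, alt)
EDITING_TYPES = tuple(
    f"{_r}-to-{_a}"
    for _r in "ACGU"
    for _a in "ACGU"
    if _r != _a
)

_DNA2RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}
_RNA2DNA = {"A": "A", "C": "C", "G": "G", "U": "T"}


def type_label(ref: str, alt: str) -> str:
    """Substitution label in RNA nomenclature, e.g. ``C``,``T`` -> ``"C-to-U"``."""
    return f"{_DNA2RNA[ref]}-to-{_DNA2RNA[alt]}"


def type_to_bases(label: str) -> tuple[str, str]:
    """Inverse of :func:`type_label`: ``"C-to-U"`` -> ``("C", "T")``."""
    ref, alt = label.split("-to-")
    return _RNA2DNA[ref], _RNA2DNA[alt]


class FormatError(ValueError):
    """An input file violates the package's format contracts."""


@dataclass(frozen=True)
class TranscriptModel:
    """A primary transcript: sequence plus its 5'UTR / CDS / 3'UTR partition.

    Intervals are 0-based half-open, ordered utr5 < cds < utr3, jointly
    covering ``[0, len(sequence))``. The CDS length must be a multiple of 3.
    Empty UTRs are the empty intervals ``[0, 0)`` and ``[L, L)``.
    """

    id: str
    sequence: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if L == 0:
            raise FormatError(f"{self.id}: empty sequence")
        u5, c, u3 = self.utr5, self.cds, self.utr3
        if not (u5[0] == 0 and u5[1] == c[0] and c[1] == u3[0] and u3[1] == L):
            raise FormatError(
                f"{self.id}: regions {u5},{c},{u3} do not partition [0,{L})"
            )
        if (c[1] - c[0]) % 3 != 0:
            raise FormatError(f"{self.id}: CDS length {c[1] - c[0]} not divisible by 3")
        bad = set(self.sequence) - {"A", "C", "G", "T", "N"}
        if bad:
            raise FormatError(f"{self.id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def region_of(self, position: int) -> str:
        """Region class ('5UTR' | 'CDS' | '3UTR') containing a 0-based position."""
        if not 0 <= position < len(self.sequence):
            raise ValueError(f"{self.id}: position {position} outside [0,{len(self)})")
        if self.utr5[0] <= position < self.utr5[1]:
            return "5UTR"
        if self.cds[0] <= position < self.cds[1]:
            return "CDS"
        return "3UTR"

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds[0] : self.cds[1]]


@dataclass(frozen=True)
class PileupColumn:
    """Per-position base counts at one transcript coordinate."""

    transcript_id: str
    position: int  # 0-based
    ref: str
    counts: dict[str, int]
    mean_qual: float

    def __post_init__(self) -> None:
        if self.ref not in BASES:
            raise FormatError(f"pileup ref base {self.ref!r} not in {BASES}")
        if self.coverage < 1:
            raise FormatError(
                f"{self.transcript_id}:{self.position}: empty pileup column"
            )

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    @property
    def error_rate(self) -> float:
        """Per-base error probability implied by the column's mean Phred quality."""
        return 10.0 ** (-self.mean_qual / 10.0)


@dataclass(frozen=True)
class EvidenceCall:
    """An independent observation (e.g. an EST read base) at a transcript position."""

    transcript_id: str
    position: int  # 0-based
    observed_base: str

    def __post_init__(self) -> None:
        if self.observed_base not in BASES:
            raise FormatError(f"evidence base {self.observed_base!r} not in {BASES}")


@dataclass
class CandidateSNV:
    """A DNA-RNA difference prior to the significance decision."""

    transcript_id: str
    position: int  # 0-based
    ref: str
    alt: str
    coverage: int
    alt_count: int
    error_rate: float
    p_value: Optional[float] = None
    q_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if not 0 <= self.alt_count <= self.coverage:
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, {self.coverage}]"
            )


@dataclass
class EditingSite(CandidateSNV):
    """A candidate that survived the FDR threshold, with type label and degree.

    ``degree`` is the fraction of reads at the site carrying the edited base
    (alt_count / coverage) — the site-level penetrance of editing.
    """

    type_label: str = ""
    degree: float = 0.0

    # annotation fields, filled by nucredit.annotate
    region: Optional[str] = None  # 5UTR | CDS | 3UTR
    codon_position: Optional[int] = None  # 1 | 2 | 3
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None  # one-letter, '*' for stop
    alt_aa: Optional[str] = None
    synonymous: Optional[bool] = None


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth editing event written by the simulator."""

    transcript_id: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    true_degree: float

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base == alt_base")
        if not 0.0 <= self.true_degree <= 1.0:
            raise ValueError(f"degree {self.true_degree} outside [0,1]")


def site_fields() -> list[str]:
    """Column order of the sites table, shared by the TSV/VCF writers."""
    return [f.name for f in fields(EditingSite)]
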