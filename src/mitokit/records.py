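"""Core record types for annotated circular mitogenomes.

Coordinates are 0-based half-open on the forward (J) strand.  The circular
origin is a file artifact: an annotation may wrap the origin, in which case
``wraps_origin`` is set and ``end`` is the post-wrap coordinate (< start).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .alphabet import ALL_GENES, ALL_NAMES, CONTROL_REGION, KIND_BY_NAME

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationConflictError(ValueError):
    """A canonical gene name occurs more than once in one record."""


class CoordinateError(ValueError):
    """An annotation lies outside the record's sequence bounds."""


class GeneNotFoundError(KeyError):
    """Requested gene is not annotated in the record."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A single gene on the circular genome.

    ``strand`` is 'J' (forward, sign +) or 'N' (reverse, sign -).  ``kind``
    is one of PCG / tRNA / rRNA / control and is derived from the canonical
    name when omitted.
    """

    name: str
    start: int
    end: int
    strand: str = "J"
    kind: str = ""
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be 'J' or 'N', got {self.strand!r}")
        if not self.kind:
            object.__setattr__(self, "kind", KIND_BY_NAME.get(self.name, "other"))
        if not self.wraps_origin and self.start >= self.end:
            raise ValueError(
                f"{self.name}: start {self.start} >= end {self.end} "
                "without wraps_origin"
            )

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class MitogenomeRecord:
    """A circular mitogenome: taxon label, sequence, ordered annotations."""

    taxon: str
    sequence: str
    annotations: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        seen: set[str] = set()
        for a in self.annotations:
            if a.name in seen:
                raise AnnotationConflictError(
                    f"{self.taxon}: duplicate annotation for {a.name}"
                )
            seen.add(a.name)
            hi = max(a.start, a.end)
            if hi > len(self.sequence) or a.start < 0:
                raise CoordinateError(
                    f"{self.taxon}: {a.name} [{a.start},{a.end}) outside "
                    f"sequence of length {len(self.sequence)}"
                )
        self.annotations = sorted(self.annotations, key=lambda a: a.start)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def annotation(self, gene: str) -> GeneAnnotation:
        for a in self.annotations:
            if a.name == gene:
                return a
        raise GeneNotFoundError(gene)

    def has_gene(self, gene: str) -> bool:
        return any(a.name == gene for a in self.annotations)


def extract_gene_sequence(record: MitogenomeRecord, gene: str) -> str:
    """Coding-sense sequence of *gene*: forward slice for J-strand genes,
    reverse complement for N-strand genes, concatenated across the origin
    for wrapping annotations."""
    ann = record.annotation(gene)
    if ann.wraps_origin:
        raw = record.sequence[ann.start:] + record.sequence[: ann.end]
    else:
        raw = record.sequence[ann.start : ann.end]
    return reverse_complement(raw) if ann.strand == "N" else raw


def rotate_record(record: MitogenomeRecord, offset: int) -> MitogenomeRecord:
    """Rotate the circular origin so that old position *offset* becomes 0.

    Used to test rotation invariance of downstream statistics; annotations
    are remapped (possibly gaining/losing the wraps_origin flag).
    """
    L = record.length
    offset %= L
    seq = record.sequence[offset:] + record.sequence[:offset]
    anns = []
    for a in record.annotations:
        start, end = a.start, a.end
        if a.wraps_origin:
            end += L
        ns, ne = (start - offset) % L, (end - offset) % L
        if ne == 0:
            ne = L
        wraps = ns >= ne
        anns.append(replace(a, start=ns, end=ne, wraps_origin=wraps))
    return MitogenomeRecord(taxon=record.taxon, sequence=seq, annotations=anns)


@dataclass
class ValidationReport:
    """Outcome of structural validation of one record."""

    taxon: str
    n_genes: int
    missing: list[str]
    extra: list[str]
    warnings: list[str]

    @property
    def is_complete(self) -> bool:
        return not self.missing and not self.extra


def validate_record(
    record: MitogenomeRecord,
    max_same_strand_pcg_overlap: int = 10,
) -> ValidationReport:
    """Check the 37-gene complement and flag structural oddities.

    Missing/extra genes are errors in the report; long same-strand PCG
    overlaps and non-ATN PCG starts are warnings only.
    """
    present = [a.name for a in record.annotations if a.name != CONTROL_REGION]
    present_set = set(present)
    missing = sorted(g for g in ALL_GENES if g not in present_set)
    extra = sorted(n for n in present_set if n not in ALL_NAMES)
    warnings: list[str] = []
    if not record.has_gene(CONTROL_REGION):
        warnings.append("no A+T-rich region annotated")

    pcgs = [a for a in record.annotations if a.kind == "PCG"]
    for a, b in zip(pcgs, pcgs[1:]):
        if a.strand == b.strand and not (a.wraps_origin or b.wraps_origin):
            overlap = a.end - b.start
            if overlap > max_same_strand_pcg_overlap:
                warnings.append(
                    f"{a.name}/{b.name}: same-strand overlap of {overlap} bp"
                )
    for a in pcgs:
        s = extract_gene_sequence(record, a.name)
        if len(s) >= 3 and not (s[0:2] == "AT" and s[2] in "ACGT"):
            warnings.append(f"{a.name}: non-ATN start codon {s[:3]}")
    return ValidationReport(
        taxon=record.taxon,
        n_genes=len(present_set & set(ALL_GENES)),
        missing=missing,
        extra=extra,
        warnings=warnings,
    )
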