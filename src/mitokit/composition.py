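"""Nucleotide-composition statistics for mitogenomes.

Covers AT content, strand-asymmetry skews, per-partition summaries,
codon usage and relative synonymous codon usage (RSCU) under the
invertebrate mitochondrial code, start/stop codon inference including
partial (T- / TA-) stops, and circular intergenic spacer / gene-overlap
accounting.

Skews follow AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C);
a zero denominator yields NaN.  Ambiguity codes are excluded from all
counts used in skews and AT content.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .alphabet import CONTROL_REGION, PCGS, RRNAS, TRNAS
from .records import MitogenomeRecord, extract_gene_sequence

#: NCBI translation table 5 (invertebrate mitochondrial), the default code.
INVERTEBRATE_MITO_TABLE_ID = 5

STOP_CODONS_5 = tuple(CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE_ID].stop_codons)


@dataclass(frozen=True)
class BaseCounts:
    A: int = 0
    C: int = 0
    G: int = 0
    T: int = 0
    other: int = 0

    @property
    def total(self) -> int:
        return self.A + self.C + self.G + self.T

    def swap_at(self) -> "BaseCounts":
        return BaseCounts(A=self.T, C=self.C, G=self.G, T=self.A, other=self.other)

    def swap_gc(self) -> "BaseCounts":
        return BaseCounts(A=self.A, C=self.G, G=self.C, T=self.T, other=self.other)


def base_counts(seq: str) -> BaseCounts:
    c = Counter(seq.upper())
    acgt = c["A"] + c["C"] + c["G"] + c["T"]
    return BaseCounts(A=c["A"], C=c["C"], G=c["G"], T=c["T"], other=len(seq) - acgt)


def at_skew(counts: BaseCounts) -> float:
    denom = counts.A + counts.T
    return (counts.A - counts.T) / denom if denom else math.nan


def gc_skew(counts: BaseCounts) -> float:
    denom = counts.G + counts.C
    return (counts.G - counts.C) / denom if denom else math.nan


def at_content(counts: BaseCounts) -> float:
    """A+T percentage of unambiguous bases (0-100)."""
    return 100.0 * (counts.A + counts.T) / counts.total if counts.total else math.nan


@dataclass(frozen=True)
class CompositionSummary:
    partition: str
    length: int
    at_content: float
    at_skew: float
    gc_skew: float


def _summary(partition: str, seq: str) -> CompositionSummary:
    c = base_counts(seq)
    return CompositionSummary(
        partition=partition,
        length=len(seq),
        at_content=at_content(c),
        at_skew=at_skew(c),
        gc_skew=gc_skew(c),
    )


def composition_by_partition(record: MitogenomeRecord) -> list[CompositionSummary]:
    """Composition summaries for the whole genome, the concatenated PCG /
    tRNA / rRNA partitions (coding sense), the A+T-rich region, and the
    three PCG codon positions.

    Codon positions are taken on the coding-sense PCG concatenation in each
    gene's own reading frame, since position-specific base biases are
    reading-frame properties, not genomic-strand ones.  Missing partitions
    are omitted with a warning.
    """
    out = [_summary("whole", record.sequence)]
    pcg_seqs = [extract_gene_sequence(record, g) for g in PCGS if record.has_gene(g)]
    groups = [
        ("PCGs", "".join(pcg_seqs)),
        ("tRNAs", "".join(extract_gene_sequence(record, g) for g in TRNAS if record.has_gene(g))),
        ("rRNAs", "".join(extract_gene_sequence(record, g) for g in RRNAS if record.has_gene(g))),
        (CONTROL_REGION, extract_gene_sequence(record, CONTROL_REGION) if record.has_gene(CONTROL_REGION) else ""),
    ]
    for name, seq in groups:
        if not seq:
            warnings.warn(f"{record.taxon}: partition {name} missing, summary omitted")
            continue
        out.append(_summary(name, seq))
    if pcg_seqs:
        for pos in (0, 1, 2):
            concat = "".join(s[pos::3] for s in pcg_seqs)
            out.append(_summary(f"codon_pos_{pos + 1}", concat))
    return out


def composition_table(records: list[MitogenomeRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for s in composition_by_partition(rec):
            rows.append(
                {
                    "taxon": rec.taxon,
                    "partition": s.partition,
                    "length": s.length,
                    "at_content": s.at_content,
                    "at_skew": s.at_skew,
                    "gc_skew": s.gc_skew,
                }
            )
    return pd.DataFrame(rows)


def _coding_codons(seq: str, gene: str, taxon: str = "") -> list[str]:
    """Complete codons of a coding-sense CDS, minus the terminal stop (or
    the trailing partial stop when length is not a multiple of 3)."""
    n_full = len(seq) // 3
    codons = [seq[3 * i : 3 * i + 3] for i in range(n_full)]
    if len(seq) % 3 == 0 and codons and codons[-1] in STOP_CODONS_5:
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if c in STOP_CODONS_5:
            warnings.warn(f"{taxon}: internal stop codon {c} in {gene} at codon {i + 1}")
    return codons


def codon_usage(record: MitogenomeRecord) -> Counter:
    """Codon counts pooled over all annotated PCGs (coding sense,
    translation table 5).  Terminal stop codons and trailing partial
    codons are excluded; internal stops are counted but warned about."""
    counts: Counter = Counter()
    for gene in PCGS:
        if not record.has_gene(gene):
            continue
        seq = extract_gene_sequence(record, gene)
        counts.update(_coding_codons(seq, gene, record.taxon))
    return counts


def rscu(codon_counts: Counter | dict[str, int]) -> pd.DataFrame:
    """Relative synonymous codon usage under translation table 5.

    RSCU(c) = count(c) * degeneracy(family) / sum of counts over the
    synonymous family of c.  Families with zero total get RSCU 0 for all
    members.  Stop codons are excluded.  Returns a table with columns
    codon, aa, count, rscu (one row per sense codon, codon-sorted).
    """
    fwd = CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE_ID].forward_table
    families: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        families.setdefault(aa, []).append(codon)
    rows = []
    for aa in sorted(families):
        fam = sorted(families[aa])
        total = sum(codon_counts.get(c, 0) for c in fam)
        for c in fam:
            n = codon_counts.get(c, 0)
            value = (n * len(fam) / total) if total else 0.0
            rows.append({"codon": c, "aa": aa, "count": n, "rscu": value})
    return pd.DataFrame(rows).sort_values("codon", ignore_index=True)


def mean_rscu(records: list[MitogenomeRecord]) -> pd.DataFrame:
    """Arithmetic mean of per-taxon RSCU across records (column 'rscu')."""
    tables = [rscu(codon_usage(r)) for r in records]
    merged = tables[0][["codon", "aa"]].copy()
    merged["rscu"] = sum(t["rscu"] for t in tables) / len(tables)
    merged["count"] = sum(t["count"] for t in tables)
    return merged


def detect_start_stop(record: MitogenomeRecord, gene: str) -> tuple[str, str]:
    """Start codon and (possibly partial) stop codon of a PCG.

    A length of 1 (mod 3) ending in T is reported as the partial stop
    'T-'; 2 (mod 3) ending in TA as 'TA-'.  Both are completed to TAA by
    post-transcriptional polyadenylation in vivo.  Unknown terminal
    patterns are reported verbatim.
    """
    seq = extract_gene_sequence(record, gene)
    start = seq[:3]
    rem = len(seq) % 3
    if rem == 0:
        stop = seq[-3:]
    elif rem == 1:
        stop = "T-" if seq.endswith("T") else seq[-1]
    else:
        stop = "TA-" if seq.endswith("TA") else seq[-2:]
    return start, stop


@dataclass
class SpacerOverlapReport:
    """Intergenic spacers and gene overlaps on the circular genome."""

    spacers: list[tuple[str, str, int]] = field(default_factory=list)
    overlaps: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def total_spacer_bp(self) -> int:
        return sum(s[2] for s in self.spacers)

    @property
    def n_spacer_locations(self) -> int:
        return len(self.spacers)

    @property
    def total_overlap_bp(self) -> int:
        return sum(o[2] for o in self.overlaps)


def spacers_and_overlaps(record: MitogenomeRecord) -> SpacerOverlapReport:
    """Gap accounting between consecutive annotations on the ring.

    The A+T-rich region is itself an annotation (its span is neither a
    spacer nor an overlap); a positive gap between neighbours is a spacer,
    a negative one an overlap.  Totals are invariant under rotation of the
    circular origin.
    """
    anns = sorted(record.annotations, key=lambda a: a.start)
    report = SpacerOverlapReport()
    L = record.length
    n = len(anns)
    for i, prev in enumerate(anns):
        nxt = anns[(i + 1) % n]
        prev_end = prev.start + prev.length(L)
        nxt_start = nxt.start + (L if i == n - 1 else 0)
        gap = nxt_start - prev_end
        if gap > 0:
            report.spacers.append((prev.name, nxt.name, gap))
        elif gap < 0:
            report.overlaps.append((prev.name, nxt.name, -gap))
    return report


def spacer_overlap_table(records: list[MitogenomeRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rep = spacers_and_overlaps(rec)
        for kind, entries in (("spacer", rep.spacers), ("overlap", rep.overlaps)):
            for a, b, length in entries:
                rows.append({"taxon": rec.taxon, "kind": kind, "upstream": a, "downstream": b, "length": length})
    return pd.DataFrame(rows)
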