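"""Partitioned supermatrix assembly.

Builds the four dataset variants used in partitioned phylogenetics of
mitogenomes from per-gene alignments:

* ``P123RNA`` — 13 PCGs, all codon positions, plus 22 tRNAs and 2 rRNAs;
* ``P12RNA`` — PCGs with 3rd codon positions removed;
* ``P123RNAexc3genes`` / ``P12RNAexc3genes`` — additionally dropping the
  fast-evolving atp8, nad4l and nad6.

Partition blocks are defined by gene and codon position (one block per PCG
codon position retained, one per RNA gene): 13*3 + 22 + 2 = 63 blocks with
all positions, 13*2 + 22 + 2 = 50 without third positions.  Alignment
computation is upstream; this module consumes aligned inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .alphabet import PCGS, RRNAS, TRNAS

VARIANTS = ("P123RNA", "P12RNA", "P123RNAexc3genes", "P12RNAexc3genes")
EXCLUDED_GENES = ("atp8", "nad4l", "nad6")

#: canonical concatenation order: PCGs alphabetical, then tRNAs, then rRNAs
CANONICAL_GENE_ORDER: tuple[str, ...] = PCGS + TRNAS + RRNAS


class FrameError(ValueError):
    """A PCG alignment length is not a multiple of 3."""


@dataclass(frozen=True)
class Block:
    """One charset: 1-based inclusive start/end with a site stride."""

    name: str
    type: str  # PCG_pos1 | PCG_pos2 | PCG_pos3 | tRNA | rRNA
    start: int
    end: int
    stride: int = 1

    def sites(self) -> list[int]:
        """0-based site indices covered by the block."""
        return list(range(self.start - 1, self.end, self.stride))


@dataclass
class PartitionScheme:
    blocks: list[Block] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def total_sites(self) -> int:
        return sum(len(b.sites()) for b in self.blocks)


@dataclass
class Supermatrix:
    taxa: tuple[str, ...]
    sequences: dict[str, str]
    scheme: PartitionScheme
    variant: str
    gene_spans: dict[str, tuple[int, int]] = field(default_factory=dict)  # 0-based half-open

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def _variant_genes(variant: str) -> list[str]:
    genes = list(CANONICAL_GENE_ORDER)
    if variant.endswith("exc3genes"):
        genes = [g for g in genes if g not in EXCLUDED_GENES]
    return genes


def _drop_third_positions(seq: str) -> str:
    return "".join(c for i, c in enumerate(seq) if i % 3 != 2)


def trim_to_frame(per_gene_alignments: dict[str, dict[str, str]]) -> dict[str, dict[str, str]]:
    """Trim trailing partial codons from PCG alignments.

    Genes with partial (T- / TA-) stop codons end 1-2 columns short of a
    full codon; codon-aware concatenation requires whole codons, so the
    incomplete terminal codon is dropped.  RNA alignments pass through.
    """
    out: dict[str, dict[str, str]] = {}
    for gene, aln in per_gene_alignments.items():
        if gene in PCGS and aln:
            length = len(next(iter(aln.values())))
            cut = length - length % 3
            out[gene] = {t: s[:cut] for t, s in aln.items()}
        else:
            out[gene] = dict(aln)
    return out


def concatenate(
    per_gene_alignments: dict[str, dict[str, str]],
    variant: str = "P123RNA",
) -> Supermatrix:
    """Concatenate per-gene alignments into one supermatrix variant.

    Genes are joined in the canonical order (PCGs alphabetical, tRNAs,
    rRNAs); taxa missing from a gene are padded with gaps (with a warning);
    codon-position masks assume reading frame 0 for every PCG.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    genes = [g for g in _variant_genes(variant) if g in per_gene_alignments]
    taxa = tuple(sorted({t for g in genes for t in per_gene_alignments[g]}))
    drop3 = variant.startswith("P12RNA")
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    spans: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene in genes:
        aln = per_gene_alignments[gene]
        length = len(next(iter(aln.values())))
        is_pcg = gene in PCGS
        if is_pcg and length % 3 != 0:
            raise FrameError(f"{gene}: alignment length {length} is not a multiple of 3")
        for t, seq in aln.items():
            if len(seq) != length:
                raise ValueError(f"{gene}: ragged alignment (taxon {t})")
        out_len = length - length // 3 if (is_pcg and drop3) else length
        for t in taxa:
            seq = aln.get(t)
            if seq is None:
                warnings.warn(f"{gene}: taxon {t} missing, padded with gaps")
                seq = "-" * length
            parts[t].append(_drop_third_positions(seq) if (is_pcg and drop3) else seq)
        spans[gene] = (offset, offset + out_len)
        offset += out_len
    sm = Supermatrix(
        taxa=taxa,
        sequences={t: "".join(parts[t]) for t in taxa},
        scheme=PartitionScheme(),
        variant=variant,
        gene_spans=spans,
    )
    sm.scheme = build_scheme(sm)
    return sm


def build_scheme(supermatrix: Supermatrix) -> PartitionScheme:
    """Partition blocks of a supermatrix: one per retained PCG codon
    position and one per RNA gene."""
    drop3 = supermatrix.variant.startswith("P12RNA")
    blocks: list[Block] = []
    for gene, (lo, hi) in supermatrix.gene_spans.items():
        if gene in PCGS:
            stride = 2 if drop3 else 3
            n_pos = 2 if drop3 else 3
            for pos in range(n_pos):
                blocks.append(
                    Block(
                        name=f"{gene}_pos{pos + 1}",
                        type=f"PCG_pos{pos + 1}",
                        start=lo + pos + 1,
                        end=hi,
                        stride=stride,
                    )
                )
        else:
            kind = "rRNA" if gene in RRNAS else "tRNA"
            blocks.append(Block(name=gene, type=kind, start=lo + 1, end=hi, stride=1))
    return PartitionScheme(blocks=blocks)


def write_partitions(scheme: PartitionScheme, path, dialect: str = "nexus_charset") -> None:
    """Emit charset definitions (1-based inclusive, stride as ``\\N``)."""
    if not scheme.blocks:
        raise ValueError("empty partition scheme")
    lines = []
    if dialect == "nexus_charset":
        lines.append("#nexus")
        lines.append("begin sets;")
        for b in scheme.blocks:
            stride = f"\\{b.stride}" if b.stride > 1 else ""
            lines.append(f"  charset {b.name} = {b.start}-{b.end}{stride};")
        lines.append("end;")
    elif dialect == "raxml_style":
        for b in scheme.blocks:
            stride = f"\\{b.stride}" if b.stride > 1 else ""
            lines.append(f"DNA, {b.name} = {b.start}-{b.end}{stride}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_partitions(path) -> PartitionScheme:
    """Parse nexus charset or RAxML-style partition lines (round-trip of
    write_partitions)."""
    import re

    pat = re.compile(
        r"^\s*(?:charset\s+|DNA,\s*)(\S+)\s*=\s*(\d+)-(\d+)(?:\\(\d+))?\s*;?\s*$"
    )
    blocks = []
    for line in open(path):
        m = pat.match(line)
        if not m:
            continue
        name, start, end, stride = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
        if "_pos" in name:
            btype = "PCG_" + name.rsplit("_", 1)[1]
        elif name in RRNAS:
            btype = "rRNA"
        elif name in TRNAS:
            btype = "tRNA"
        else:
            btype = "other"
        blocks.append(Block(name=name, type=btype, start=start, end=end, stride=int(stride or 1)))
    return PartitionScheme(blocks=blocks)


def write_supermatrix_fasta(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for t in sm.taxa:
            fh.write(f">{t.replace(' ', '_')}\n{sm.sequences[t]}\n")


def write_supermatrix_phylip(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.length}\n")
        for t in sm.taxa:
            fh.write(f"{t.replace(' ', '_')}  {sm.sequences[t]}\n")


def read_fasta_alignment(path) -> dict[str, str]:
    """Plain aligned-FASTA reader returning taxon -> sequence."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in open(path):
        line = line.strip()
        if line.startswith(">"):
            if name is not None:
                out[name] = "".join(chunks)
            name = line[1:].split()[0].replace("_", " ")
            chunks = []
        elif line:
            chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_fasta_alignment(aln: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for t, seq in aln.items():
            fh.write(f">{t.replace(' ', '_')}\n{seq}\n")


def split_codon_positions(aln: dict[str, str]) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Split a frame-0 PCG alignment into its three codon-position tracks."""
    outs: tuple[dict[str, str], ...] = ({}, {}, {})
    for t, seq in aln.items():
        for pos in range(3):
            outs[pos][t] = seq[pos::3]
    return outs
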