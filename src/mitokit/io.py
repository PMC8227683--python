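"""Reading and writing annotated mitogenomes.

GenBank flat files are the primary interchange format (via Biopython); a
(FASTA + 5-column feature table) pair is supported as a plain-text
alternative.  All coordinates are converted between GenBank's 1-based
inclusive convention and the internal 0-based half-open convention on read
and write.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

from .alphabet import (
    CONTROL_REGION,
    GENE_SYNONYMS,
    KIND_BY_NAME,
    TRNA_BY_AA3,
    TRNA_BY_ANTICODON,
    TRNA_BY_CODON_FAMILY,
)
from .records import GeneAnnotation, MitogenomeRecord


class UnknownGeneError(ValueError):
    """A feature name could not be mapped to a canonical gene identifier."""


_TRNA_RE = re.compile(r"^trna[-_ ]?([a-z]{3})\s*(?:\((\w{3})\))?$")
_TRNA_SHORT_RE = re.compile(r"^trn([a-z])([12])?$", re.IGNORECASE)
_ANTICODON_SEQ_RE = re.compile(r"seq:([acgtu]{3})", re.IGNORECASE)


def _anticodon_from_qualifiers(qualifiers: Mapping[str, str]) -> str | None:
    raw = qualifiers.get("anticodon", "")
    if not raw:
        return None
    m = _ANTICODON_SEQ_RE.search(raw)
    token = m.group(1) if m else raw.strip("() ")
    token = token.upper().replace("U", "T")
    return token if len(token) == 3 and set(token) <= set("ACGT") else None


def normalize_gene_name(raw: str, qualifiers: Mapping[str, str] | None = None) -> str:
    """Map an annotation dialect name to one of the 39 canonical names.

    Disambiguation of the Leu/Ser isoacceptor pairs follows the precedence
    explicit name (trnL1 etc.) > anticodon qualifier > codon-recognised
    note > error, since GenBank dialects vary in which they provide.
    """
    qualifiers = qualifiers or {}
    key = raw.strip().lower().replace("--", "-")

    if key in GENE_SYNONYMS:
        return GENE_SYNONYMS[key]

    # explicit canonical spellings, incl. trnL1/trnS2 style
    m = _TRNA_SHORT_RE.match(key)
    if m:
        letter, iso = m.group(1).upper(), m.group(2)
        name = f"trn{letter}{iso or ''}"
        if name in KIND_BY_NAME:
            return name
        if letter in "LS" and iso is None:
            return _resolve_isoacceptor(letter, raw, qualifiers)

    m = _TRNA_RE.match(key)
    if m:
        aa3, codon_note = m.group(1), m.group(2)
        name = TRNA_BY_AA3.get(aa3)
        if name is None:
            raise UnknownGeneError(f"unrecognised tRNA amino acid in {raw!r}")
        if not name.endswith("?"):
            return name
        if codon_note:
            fam = codon_note.upper().replace("U", "T") + ""
            for note_key in (codon_note.upper(), fam):
                if note_key in TRNA_BY_CODON_FAMILY:
                    return TRNA_BY_CODON_FAMILY[note_key]
        return _resolve_isoacceptor(name[3], raw, qualifiers)

    raise UnknownGeneError(f"cannot map feature name {raw!r} to a canonical gene")


def _resolve_isoacceptor(letter: str, raw: str, qualifiers: Mapping[str, str]) -> str:
    anticodon = _anticodon_from_qualifiers(qualifiers)
    if anticodon and anticodon in TRNA_BY_ANTICODON:
        name = TRNA_BY_ANTICODON[anticodon]
        if name[3] == letter:
            return name
    note = (qualifiers.get("note", "") + " " + qualifiers.get("codon_recognized", "")).upper()
    for fam, name in TRNA_BY_CODON_FAMILY.items():
        if fam in note and name[3] == letter:
            return name
    raise UnknownGeneError(
        f"ambiguous isoacceptor {raw!r}: need an anticodon or codon-recognised "
        "qualifier to split L1/L2 or S1/S2"
    )


_FEATURE_KEYS = {"CDS", "tRNA", "rRNA", "misc_feature", "D-loop"}


def _feature_name(feature: SeqFeature) -> str:
    quals = {k: v[0] for k, v in feature.qualifiers.items() if v}
    for key in ("gene", "product", "note"):
        if key in quals:
            try:
                return normalize_gene_name(quals[key], quals)
            except UnknownGeneError:
                continue
    if feature.type in ("misc_feature", "D-loop"):
        return CONTROL_REGION
    raise UnknownGeneError(
        f"feature {feature.type} at {feature.location} has no mappable name"
    )


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read one annotated mitogenome from a GenBank flat file.

    Complement features become strand N; a join() across the origin becomes
    a wraps_origin annotation.  Raises on duplicate canonical names or
    out-of-bounds coordinates (via MitogenomeRecord validation).
    """
    seqrec = SeqIO.read(str(path), "genbank")
    L = len(seqrec.seq)
    anns: list[GeneAnnotation] = []
    for feature in seqrec.features:
        if feature.type not in _FEATURE_KEYS:
            continue
        name = _feature_name(feature)
        strand = "N" if feature.location.strand == -1 else "J"
        parts = sorted(feature.location.parts, key=lambda p: int(p.start))
        if len(parts) > 1 and int(parts[-1].end) == L and int(parts[0].start) == 0:
            start, end, wraps = int(parts[-1].start), int(parts[0].end), True
        else:
            start, end, wraps = int(feature.location.start), int(feature.location.end), False
        anns.append(
            GeneAnnotation(name=name, start=start, end=end, strand=strand, wraps_origin=wraps)
        )
    taxon = seqrec.annotations.get("organism") or seqrec.name or seqrec.id
    return MitogenomeRecord(taxon=taxon, sequence=str(seqrec.seq), annotations=anns)


_GB_KEY_BY_KIND = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control": "misc_feature"}


def to_seqrecord(record: MitogenomeRecord) -> SeqRecord:
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.taxon.replace(" ", "_")[:16] or "mitogenome",
        name=record.taxon.replace(" ", "_")[:16] or "mitogenome",
        description=f"{record.taxon} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": record.taxon,
        },
    )
    L = record.length
    strand_of = {"J": 1, "N": -1}
    for a in record.annotations:
        s = strand_of[a.strand]
        if a.wraps_origin:
            loc = CompoundLocation(
                [SimpleLocation(a.start, L, strand=s), SimpleLocation(0, a.end, strand=s)]
            )
        else:
            loc = SimpleLocation(a.start, a.end, strand=s)
        quals: dict[str, list[str]] = {"gene": [a.name]}
        if a.kind == "PCG":
            quals["transl_table"] = ["5"]
        if a.name == CONTROL_REGION:
            quals = {"note": ["A+T-rich region"], "gene": [CONTROL_REGION]}
        seqrec.features.append(
            SeqFeature(loc, type=_GB_KEY_BY_KIND.get(a.kind, "misc_feature"), qualifiers=quals)
        )
    return seqrec


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    SeqIO.write(to_seqrecord(record), str(path), "genbank")


def write_feature_table(record: MitogenomeRecord, fasta_path: str | Path, table_path: str | Path) -> None:
    """Write a (FASTA, 5-column feature table) pair.

    Table columns: start, end (1-based inclusive; swapped for N strand,
    NCBI style), feature key, qualifier key, qualifier value.  A wrapping
    feature is written as two coordinate lines.
    """
    with open(fasta_path, "w") as fh:
        fh.write(f">{record.taxon.replace(' ', '_')}\n")
        for i in range(0, record.length, 70):
            fh.write(record.sequence[i : i + 70] + "\n")
    L = record.length
    with open(table_path, "w") as fh:
        fh.write(f">Feature {record.taxon.replace(' ', '_')}\n")
        for a in record.annotations:
            key = _GB_KEY_BY_KIND.get(a.kind, "misc_feature")
            segs = [(a.start + 1, L), (1, a.end)] if a.wraps_origin else [(a.start + 1, a.end)]
            for i, (s1, e1) in enumerate(segs):
                lo, hi = (e1, s1) if a.strand == "N" else (s1, e1)
                fh.write(f"{lo}\t{hi}\t{key if i == 0 else ''}\n".rstrip("\n") + "\n")
            fh.write(f"\t\t\tgene\t{a.name}\n")


def read_feature_table(fasta_path: str | Path, table_path: str | Path) -> MitogenomeRecord:
    seqrec = SeqIO.read(str(fasta_path), "fasta")
    L = len(seqrec.seq)
    anns: list[GeneAnnotation] = []
    taxon = seqrec.id.replace("_", " ")
    segs: list[tuple[int, int, str]] = []
    name: str | None = None

    def flush() -> None:
        nonlocal segs, name
        if not segs or name is None:
            segs, name = [], None
            return
        strand = segs[0][2]
        if len(segs) == 2:  # wraps origin
            (s1, e1, _), (s2, e2, _) = segs
            start, end, wraps = s1 - 1, e2, True
        else:
            s1, e1, _ = segs[0]
            start, end, wraps = s1 - 1, e1, False
        anns.append(GeneAnnotation(name=normalize_gene_name(name), start=start, end=end, strand=strand, wraps_origin=wraps))
        segs, name = [], None

    for line in Path(table_path).read_text().splitlines():
        if line.startswith(">Feature"):
            taxon = line.split(None, 1)[1].replace("_", " ") if " " in line else taxon
            continue
        cols = line.split("\t")
        if len(cols) >= 2 and cols[0].strip():
            if len(cols) >= 3 and cols[2].strip():
                flush()
            a, b = int(cols[0]), int(cols[1])
            strand = "N" if a > b else "J"
            segs.append((min(a, b), max(a, b), strand))
        elif len(cols) >= 5 and cols[3] == "gene":
            name = cols[4]
            flush()
    flush()
    return MitogenomeRecord(taxon=taxon, sequence=str(seqrec.seq), annotations=anns)


def annotation_summary(record: MitogenomeRecord) -> pd.DataFrame:
    """Per-gene table (1-based inclusive coordinates) for TSV emission."""
    rows = []
    for a in record.annotations:
        rows.append(
            {
                "gene": a.name,
                "start": a.start + 1,
                "end": a.end,
                "strand": a.strand,
                "length": a.length(record.length),
                "kind": a.kind,
                "wraps_origin": a.wraps_origin,
            }
        )
    return pd.DataFrame(rows)
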