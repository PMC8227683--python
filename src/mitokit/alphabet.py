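"""Canonical gene alphabet for insect mitochondrial genomes.

The 37-gene complement (13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus the
A+T-rich control region, with the ancestral pancrustacean arrangement used as
the reference frame for rearrangement inference.

Strand convention: ``J`` is the majority strand (sign +), ``N`` the minority
strand (sign -).  Gene orders are anchored at cox1 in J orientation.
"""

from __future__ import annotations

# Protein-coding genes, alphabetical (this is also the canonical
# concatenation order used by the dataset builder).
PCGS: tuple[str, ...] = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)

TRNAS: tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNAS: tuple[str, ...] = ("rrnL", "rrnS")

CONTROL_REGION = "AT_rich"

ALL_GENES: tuple[str, ...] = PCGS + TRNAS + RRNAS
ALL_NAMES: tuple[str, ...] = ALL_GENES + (CONTROL_REGION,)

KIND_BY_NAME: dict[str, str] = (
    {g: "PCG" for g in PCGS}
    | {g: "tRNA" for g in TRNAS}
    | {g: "rRNA" for g in RRNAS}
    | {CONTROL_REGION: "control"}
)

#: Ancestral pancrustacean gene arrangement (the Daphnia pulex / ancestral
#: insect ground plan), anchored at cox1, as (gene, strand) with strand
#: 'J' (+) or 'N' (-).  The A+T-rich region sits between rrnS and trnI and is
#: excluded from gene orders.
ANCESTRAL_ARRANGEMENT: tuple[tuple[str, str], ...] = (
    ("cox1", "J"), ("trnL2", "J"), ("cox2", "J"), ("trnK", "J"),
    ("trnD", "J"), ("atp8", "J"), ("atp6", "J"), ("cox3", "J"),
    ("trnG", "J"), ("nad3", "J"), ("trnA", "J"), ("trnR", "J"),
    ("trnN", "J"), ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"),
    ("nad5", "N"), ("trnH", "N"), ("nad4", "N"), ("nad4l", "N"),
    ("trnT", "J"), ("trnP", "N"), ("nad6", "J"), ("cob", "J"),
    ("trnS2", "J"), ("nad1", "N"), ("trnL1", "N"), ("rrnL", "N"),
    ("trnV", "N"), ("rrnS", "N"), ("trnI", "J"), ("trnQ", "N"),
    ("trnM", "J"), ("nad2", "J"), ("trnW", "J"), ("trnC", "N"),
    ("trnY", "N"),
)

#: Rearrangement hotspot clusters recurrent in hymenopteran mitogenomes.
HOTSPOT_CLUSTERS: dict[str, frozenset[str]] = {
    "IQM": frozenset({"trnI", "trnQ", "trnM"}),
    "ARNS1EF": frozenset({"trnA", "trnR", "trnN", "trnS1", "trnE", "trnF"}),
    "WCY": frozenset({"trnW", "trnC", "trnY"}),
}

#: Anticodons of the standard invertebrate mitochondrial tRNA set
#: (DNA alphabet).  Used to disambiguate the two leucine and two serine
#: isoacceptors: trnL1 recognises CUN, trnL2 UUR, trnS1 AGN, trnS2 UCN.
ANTICODON_BY_TRNA: dict[str, str] = {
    "trnA": "TGC", "trnR": "TCG", "trnN": "GTT", "trnD": "GTC",
    "trnC": "GCA", "trnE": "TTC", "trnQ": "TTG", "trnG": "TCC",
    "trnH": "GTG", "trnI": "GAT", "trnL1": "TAG", "trnL2": "TAA",
    "trnK": "CTT", "trnM": "CAT", "trnF": "GAA", "trnP": "TGG",
    "trnS1": "GCT", "trnS2": "TGA", "trnT": "TGT", "trnV": "TAC",
    "trnW": "TCA", "trnY": "GTA",
}

TRNA_BY_ANTICODON: dict[str, str] = {v: k for k, v in ANTICODON_BY_TRNA.items()}

#: Codon-family notes used by some GenBank dialects to disambiguate
#: isoacceptors, e.g. product "tRNA-Leu" with note "(UUR)".
TRNA_BY_CODON_FAMILY: dict[str, str] = {
    "CUN": "trnL1", "UUR": "trnL2", "AGN": "trnS1", "UCN": "trnS2",
    "CTN": "trnL1", "TTR": "trnL2", "TCN": "trnS2",
}

#: One-letter and three-letter amino-acid spellings to tRNA names
#: (unambiguous isoacceptors only; Leu/Ser need a qualifier).
_AA3_BY_TRNA = {
    "trnA": "ala", "trnR": "arg", "trnN": "asn", "trnD": "asp",
    "trnC": "cys", "trnE": "glu", "trnQ": "gln", "trnG": "gly",
    "trnH": "his", "trnI": "ile", "trnK": "lys", "trnM": "met",
    "trnF": "phe", "trnP": "pro", "trnT": "thr", "trnW": "trp",
    "trnV": "val", "trnY": "tyr",
}
TRNA_BY_AA3: dict[str, str] = {v: k for k, v in _AA3_BY_TRNA.items()}
TRNA_BY_AA3["leu"] = "trnL?"  # ambiguous without anticodon/codon note
TRNA_BY_AA3["ser"] = "trnS?"

#: Synonym table for non-tRNA features across common annotation dialects.
GENE_SYNONYMS: dict[str, str] = {
    # cytochrome c oxidase
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cytochrome c oxidase subunit 1": "cox1",
    "cytochrome c oxidase subunit i": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cytochrome c oxidase subunit 2": "cox2",
    "cytochrome c oxidase subunit ii": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cytochrome c oxidase subunit 3": "cox3",
    "cytochrome c oxidase subunit iii": "cox3",
    # cytochrome b
    "cob": "cob", "cytb": "cob", "cyt b": "cob", "cytochrome b": "cob",
    "cob/cytb": "cob", "cytochrome b apoenzyme": "cob",
    # NADH dehydrogenase
    "nad1": "nad1", "nd1": "nad1", "nadh dehydrogenase subunit 1": "nad1",
    "nad2": "nad2", "nd2": "nad2", "nadh dehydrogenase subunit 2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nadh dehydrogenase subunit 3": "nad3",
    "nad4": "nad4", "nd4": "nad4", "nadh dehydrogenase subunit 4": "nad4",
    "nad4l": "nad4l", "nd4l": "nad4l",
    "nadh dehydrogenase subunit 4l": "nad4l",
    "nad5": "nad5", "nd5": "nad5", "nadh dehydrogenase subunit 5": "nad5",
    "nad6": "nad6", "nd6": "nad6", "nadh dehydrogenase subunit 6": "nad6",
    # ATP synthase
    "atp6": "atp6", "atpase6": "atp6", "atpase 6": "atp6",
    "atp synthase f0 subunit 6": "atp6",
    "atp8": "atp8", "atpase8": "atp8", "atpase 8": "atp8",
    "atp synthase f0 subunit 8": "atp8",
    # rRNAs
    "rrns": "rrnS", "s-rrna": "rrnS", "srrna": "rrnS", "12s": "rrnS",
    "12s rrna": "rrnS", "12s ribosomal rna": "rrnS",
    "small subunit ribosomal rna": "rrnS",
    "rrnl": "rrnL", "l-rrna": "rrnL", "lrrna": "rrnL", "16s": "rrnL",
    "16s rrna": "rrnL", "16s ribosomal rna": "rrnL",
    "large subunit ribosomal rna": "rrnL",
    # control region
    "at_rich": "AT_rich", "at rich region": "AT_rich",
    "a+t rich region": "AT_rich", "a+t-rich region": "AT_rich",
    "d-loop": "AT_rich", "control region": "AT_rich",
    "putative control region": "AT_rich",
}
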