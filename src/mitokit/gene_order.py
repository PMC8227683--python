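"""Mitochondrial gene orders as signed circular permutations, and inference
of the rearrangement events separating a genome from the ancestral
pancrustacean arrangement.

Event vocabulary (each gene participates in at most one event):

* ``inversion`` — in-place strand flip of a gene that keeps its position;
* ``transposition`` — relocation of a gene/contiguous block, strands kept;
* ``reverse_transposition`` — relocation with strand flip;
* ``unresolved_block`` — fallback when a comparison needs more events than
  the configured budget.

Inference maximises the *stationary backbone*: the largest set of genes
forming a common subsequence of the two orders (gene identity only, signs
free).  Every gene off the backbone is relocated by exactly one event;
backbone genes whose strand differs are inverted in place.  Ties between
equally large backbones are broken in favour of genes that retain their
ancestral index, so a gene flanked by two exchanged neighbours (the MQI
pattern) is described as an in-place inversion rather than a move.
Applying the returned events to the reference reproduces the query.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from .alphabet import ALL_GENES, CONTROL_REGION, HOTSPOT_CLUSTERS
from .records import MitogenomeRecord

SignedGene = tuple[str, int]  # (gene name, +1 for J / -1 for N)


class OrderExtractionError(ValueError):
    """Record lacks or duplicates genes required for a full gene order."""


@dataclass(frozen=True)
class GeneOrder:
    """Circular signed gene order, normalised to the cox1-anchored frame."""

    taxon: str
    order: tuple[SignedGene, ...]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.order)

    def sign_of(self, gene: str) -> int:
        for g, s in self.order:
            if g == gene:
                return s
        raise KeyError(gene)


def _normalize(order: list[SignedGene], anchor: str = "cox1") -> tuple[SignedGene, ...]:
    names = [g for g, _ in order]
    if anchor in names:
        i = names.index(anchor)
        order = order[i:] + order[:i]
    return tuple(order)


def make_gene_order(taxon: str, order: list[SignedGene]) -> GeneOrder:
    return GeneOrder(taxon=taxon, order=_normalize(list(order)))


def gene_order_of(record: MitogenomeRecord) -> GeneOrder:
    """Signed gene order of a record: annotations by start position on the
    ring, A+T-rich region excluded, rotated to the cox1 frame."""
    signed = [
        (a.name, 1 if a.strand == "J" else -1)
        for a in sorted(record.annotations, key=lambda a: a.start)
        if a.name != CONTROL_REGION
    ]
    names = [g for g, _ in signed]
    dupes = {g for g in names if names.count(g) > 1}
    missing = set(ALL_GENES) - set(names)
    if dupes or missing:
        raise OrderExtractionError(
            f"{record.taxon}: duplicated {sorted(dupes)}, missing {sorted(missing)}"
        )
    return make_gene_order(record.taxon, signed)


def ancestral_pancrustacean_order() -> GeneOrder:
    """The canonical ancestral insect/pancrustacean 37-gene arrangement."""
    from .alphabet import ANCESTRAL_ARRANGEMENT

    return make_gene_order(
        "ancestral_pancrustacean",
        [(g, 1 if s == "J" else -1) for g, s in ANCESTRAL_ARRANGEMENT],
    )


def order_to_string(order: GeneOrder) -> str:
    return " ".join(("-" if s < 0 else "") + g for g, s in order.order)


def order_from_string(taxon: str, text: str) -> GeneOrder:
    signed = []
    for tok in text.split():
        if tok.startswith("-"):
            signed.append((tok[1:], -1))
        else:
            signed.append((tok, 1))
    return make_gene_order(taxon, signed)


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str  # transposition | inversion | reverse_transposition | unresolved_block
    genes: tuple[str, ...]
    from_context: tuple[str, str] = ("", "")
    to_context: tuple[str, str] = ("", "")
    # query-frame start index of the (re)located block; replay bookkeeping,
    # not part of the event's identity
    q_start: int = dataclasses.field(default=-1, compare=False, repr=False)

    @property
    def cluster(self) -> str:
        for label, members in HOTSPOT_CLUSTERS.items():
            if set(self.genes) <= members:
                return label
        return "other"

    def signature(self) -> tuple:
        """Identity used when grouping events across taxa."""
        return (self.kind, self.genes, self.to_context)


def _backbone(ref_names: list[str], qry_names: list[str]) -> list[tuple[int, int]]:
    """Maximum common subsequence of the two name lists, as (i_ref, i_qry)
    pairs; ties broken by maximising index-preserved genes (i_ref == i_qry),
    then by preferring earlier matches (deterministic)."""
    n, m = len(ref_names), len(qry_names)
    # dp[i][j]: best (length, preserved) for suffixes i.., j..
    dp = [[(0, 0)] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, below = dp[i], dp[i + 1]
        for j in range(m - 1, -1, -1):
            best = row[j + 1] if row[j + 1] >= below[j] else below[j]
            if ref_names[i] == qry_names[j]:
                take = (below[j + 1][0] + 1, below[j + 1][1] + (1 if i == j else 0))
                if take >= best:
                    best = take
            row[j] = best
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m:
        if ref_names[i] == qry_names[j]:
            take = (dp[i + 1][j + 1][0] + 1, dp[i + 1][j + 1][1] + (1 if i == j else 0))
            if take == dp[i][j]:
                pairs.append((i, j))
                i += 1
                j += 1
                continue
        if dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return pairs


def min_relocated_oracle(ref_names: list[str], qry_names: list[str]) -> int:
    """Brute-force minimum number of relocated genes: exhaustive search over
    stationary-backbone subsets (independent of the DP implementation).
    Exponential; for small alphabets only."""
    from itertools import combinations

    n = len(ref_names)
    pos_q = {g: i for i, g in enumerate(qry_names)}
    for keep in range(n, -1, -1):
        for subset in combinations(ref_names, keep):
            q_idx = [pos_q[g] for g in subset]
            if all(a < b for a, b in zip(q_idx, q_idx[1:])):
                return n - keep
    return n


def infer_events(
    query: GeneOrder,
    reference: GeneOrder,
    max_events: int = 4,
) -> list[RearrangementEvent]:
    """Rearrangement events transforming *reference* into *query*.

    Minimises the number of relocated genes (maximum stationary backbone);
    contiguously relocated genes that stay contiguous, in order, and share
    flip status are merged into one block event.  If more than *max_events*
    events fall inside a single hotspot-sized discordant region, that region
    collapses to one ``unresolved_block``.
    """
    if set(query.genes) != set(reference.genes):
        raise OrderExtractionError("gene alphabets differ between orders")
    R, Q = list(reference.order), list(query.order)
    if R == Q:
        return []
    ref_names = [g for g, _ in R]
    qry_names = [g for g, _ in Q]
    sign_r = dict(R)
    sign_q = dict(Q)
    pairs = _backbone(ref_names, qry_names)
    backbone_genes = {ref_names[i] for i, _ in pairs}

    def ring_context(names: list[str], idx_lo: int, idx_hi: int) -> tuple[str, str]:
        n = len(names)
        return names[(idx_lo - 1) % n], names[(idx_hi + 1) % n]

    events: list[RearrangementEvent] = []
    # in-place inversions on the backbone
    for g in sorted(backbone_genes):
        if sign_r[g] != sign_q[g]:
            i, j = ref_names.index(g), qry_names.index(g)
            events.append(
                RearrangementEvent(
                    kind="inversion",
                    genes=(g,),
                    from_context=ring_context(ref_names, i, i),
                    to_context=ring_context(qry_names, j, j),
                    q_start=j,
                )
            )
    # relocated genes, grouped into blocks contiguous in both orders
    moved = [g for g in qry_names if g not in backbone_genes]
    pos_r = {g: i for i, g in enumerate(ref_names)}
    pos_q = {g: i for i, g in enumerate(qry_names)}
    blocks: list[list[str]] = []
    for g in moved:
        flip = sign_r[g] != sign_q[g]
        if blocks:
            prev = blocks[-1][-1]
            prev_flip = sign_r[prev] != sign_q[prev]
            q_adjacent = pos_q[g] == pos_q[prev] + 1
            r_adjacent = (
                pos_r[g] == pos_r[prev] + 1 if not flip else pos_r[g] == pos_r[prev] - 1
            )
            if q_adjacent and r_adjacent and flip == prev_flip:
                blocks[-1].append(g)
                continue
        blocks.append([g])
    for block in blocks:
        flip = sign_r[block[0]] != sign_q[block[0]]
        r_idx = [pos_r[g] for g in block]
        q_idx = [pos_q[g] for g in block]
        events.append(
            RearrangementEvent(
                kind="reverse_transposition" if flip else "transposition",
                genes=tuple(block),
                from_context=ring_context(ref_names, min(r_idx), max(r_idx)),
                to_context=ring_context(qry_names, min(q_idx), max(q_idx)),
                q_start=min(q_idx),
            )
        )
    if len(events) > max_events:
        discordant = [g for g in qry_names if g not in backbone_genes or sign_r[g] != sign_q[g]]
        lo = min(pos_q[g] for g in discordant)
        hi = max(pos_q[g] for g in discordant)
        return [
            RearrangementEvent(
                kind="unresolved_block",
                genes=tuple(qry_names[lo : hi + 1]),
                from_context=ring_context(ref_names, lo, hi),
                to_context=ring_context(qry_names, lo, hi),
            )
        ]
    return events


def apply_events(reference: GeneOrder, events: list[RearrangementEvent]) -> GeneOrder:
    """Replay events on the reference order.

    Relocated blocks are excised, flipped when the event is a reverse
    transposition, and reinserted after their target left-context gene;
    blocks are processed so that a block whose left context is itself a
    moved gene is inserted after it.
    """
    order = list(reference.order)
    if any(e.kind == "unresolved_block" for e in events):
        raise ValueError("cannot replay an unresolved_block event")
    for e in events:
        if e.kind == "inversion":
            order = [(g, -s if g in e.genes else s) for g, s in order]
    moves = [e for e in events if e.kind in ("transposition", "reverse_transposition")]
    excised: dict[str, list[SignedGene]] = {}
    for e in moves:
        block = [(g, s) for g, s in order if g in e.genes]
        if e.kind == "reverse_transposition":
            block = [(g, -s) for g, s in reversed(block)]
        excised[e.genes[0]] = block
        order = [(g, s) for g, s in order if g not in e.genes]
    # insert left-to-right in the query frame so each block's insertion
    # point (its query start index) already exists when it is placed
    for e in sorted(moves, key=lambda e: e.q_start):
        block = excised[e.genes[0]]
        if e.q_start >= 0:
            at = e.q_start
        else:  # hand-built event: fall back to the left-context gene
            names = [g for g, _ in order]
            left = e.to_context[0]
            at = names.index(left) + 1 if left in names else 0
        order = order[:at] + block + order[at:]
    return GeneOrder(taxon=reference.taxon, order=tuple(order))


@dataclass
class SharedEvent:
    event: RearrangementEvent
    taxa: tuple[str, ...]
    synapomorphic: bool = False


def shared_derived_events(
    orders: list[GeneOrder],
    reference: GeneOrder,
    clade: set[str] | None = None,
    max_events: int = 4,
) -> list[SharedEvent]:
    """Group identical events across taxa; with a declared clade, an event
    carried by every clade member and no one else is flagged synapomorphic."""
    by_sig: dict[tuple, list[str]] = {}
    event_of: dict[tuple, RearrangementEvent] = {}
    for order in orders:
        for e in infer_events(order, reference, max_events=max_events):
            by_sig.setdefault(e.signature(), []).append(order.taxon)
            event_of[e.signature()] = e
    out = []
    for sig, taxa in by_sig.items():
        syn = clade is not None and set(taxa) == set(clade)
        out.append(SharedEvent(event=event_of[sig], taxa=tuple(taxa), synapomorphic=syn))
    return out


def events_table(events_by_taxon: dict[str, list[RearrangementEvent]]) -> pd.DataFrame:
    rows = []
    for taxon, events in events_by_taxon.items():
        for e in events:
            rows.append(
                {
                    "taxon": taxon,
                    "kind": e.kind,
                    "genes": ",".join(e.genes),
                    "cluster": e.cluster,
                    "from_context": "|".join(e.from_context),
                    "to_context": "|".join(e.to_context),
                }
            )
    return pd.DataFrame(rows)


def derived_megabelesesinae_order(taxon: str = "derived") -> GeneOrder:
    """The derived arrangement with MQI and ANS1ERF cluster states: trnQ
    inverted with trnM/trnI exchanged around it, and trnR reverse-transposed
    upstream of trnF.  Useful as a worked example and simulation target."""
    ref = ancestral_pancrustacean_order()
    events = [
        RearrangementEvent(kind="inversion", genes=("trnQ",), to_context=("trnM", "trnI")),
        RearrangementEvent(kind="transposition", genes=("trnM",), to_context=("rrnS", "trnQ")),
        RearrangementEvent(kind="transposition", genes=("trnI",), to_context=("trnQ", "nad2")),
        RearrangementEvent(
            kind="reverse_transposition", genes=("trnR",), to_context=("trnE", "trnF")
        ),
    ]
    replayed = apply_events(ref, events)
    return GeneOrder(taxon=taxon, order=replayed.order)
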