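#!/usr/bin/env python
"""Exhaustive rearrangement-oracle sweep (long-running check).

Verifies, for EVERY signed permutation of n genes (n <= 6), that event
inference relocates exactly as few genes as brute-force search over
stationary backbones, and that replaying the inferred events reproduces
the permutation.  The test suite runs n <= 4 exhaustively plus samples at
n = 5, 6; this script covers the full 46,080-state n = 6 space.

Usage: python scripts/oracle_sweep.py [max_n]
"""

from __future__ import annotations

import sys
from itertools import permutations, product

from mitokit.gene_order import (
    GeneOrder,
    apply_events,
    infer_events,
    min_relocated_oracle,
)


def sweep(n: int) -> int:
    genes = [f"g{i}" for i in range(n)]
    ref = GeneOrder(taxon="r", order=tuple((g, 1) for g in genes))
    checked = 0
    for perm in permutations(range(n)):
        for signs in product([1, -1], repeat=n):
            qry = GeneOrder(
                taxon="q", order=tuple((genes[perm[i]], signs[i]) for i in range(n))
            )
            events = infer_events(qry, ref, max_events=2 * n)
            relocated = sum(
                len(e.genes)
                for e in events
                if e.kind in ("transposition", "reverse_transposition")
            )
            oracle = min_relocated_oracle(list(ref.genes), list(qry.genes))
            assert relocated == oracle, (qry.order, relocated, oracle)
            assert apply_events(ref, events).order == qry.order, qry.order
            checked += 1
    return checked


def main() -> None:
    max_n = int(sys.argv[1]) if len(sys.argv) > 1 else 6
    for n in range(2, max_n + 1):
        checked = sweep(n)
        print(f"n={n}: {checked} signed permutations verified")


if __name__ == "__main__":
    main()
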