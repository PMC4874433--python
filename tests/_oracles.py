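"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: lineage tracing is done
with plain Python sets over the parent table, and the exact-coalescent
transition law is obtained by enumerating every parent assignment.
"""

from __future__ import annotations

import itertools
from collections import Counter


def trace_lineage_counts(parent, generation, sample_generation):
    """Set-based ancestor traversal: distinct ancestors per look-back depth."""
    current = {i for i, g in enumerate(generation) if g == sample_generation}
    if not current:
        raise ValueError("empty sample")
    counts = [len(current)]
    for _ in range(sample_generation):
        current = {parent[i] for i in current}
        counts.append(len(current))
    return counts


def tmrca_from_counts(counts):
    for g, c in enumerate(counts):
        if c == 1:
            return g
    return None


def ancestor_count_distribution(N, j):
    """P(k distinct parents | j children) by enumerating all N**j assignments."""
    hist = Counter()
    for assignment in itertools.product(range(N), repeat=j):
        hist[len(set(assignment))] += 1
    total = N ** j
    return {k: v / total for k, v in sorted(hist.items())}
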