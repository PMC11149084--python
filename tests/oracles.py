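"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's fast paths: the k-mer dictionary is a
plain Python dict built by string slicing, and the 1-D clustering oracle
enumerates every contiguous split of the sorted values.
"""

from __future__ import annotations

import itertools

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def exact_kmer_owners(genomes, k: int) -> dict[str, set[int]]:
    """Map every k-mer (both strands, N-free) to the set of genome ids
    containing it."""
    owners: dict[str, set[int]] = {}
    for g in genomes:
        for seq in g.sequences:
            for strand in (seq, revcomp(seq)):
                for i in range(len(strand) - k + 1):
                    kmer = strand[i : i + k]
                    if "N" not in kmer:
                        owners.setdefault(kmer, set()).add(g.genome_id)
    return owners


def wcss(values: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        v = values[labels == c]
        total += float(((v - v.mean()) ** 2).sum())
    return total


def best_contiguous_split(values: np.ndarray, K: int) -> tuple[float, np.ndarray]:
    """Exhaustive minimizer of within-cluster sum of squares over contiguous
    partitions of the sorted values; the 1-D K-means optimum is contiguous.

    Returns (optimal WCSS, labels aligned to the input order, blocks numbered
    from the low end).
    """
    n = len(values)
    order = np.argsort(values, kind="stable")
    x = values[order]
    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), K - 1):
        bounds = (0, *cuts, n)
        lab_sorted = np.empty(n, dtype=int)
        for c in range(K):
            lab_sorted[bounds[c] : bounds[c + 1]] = c
        cost = wcss(x, lab_sorted)
        if cost < best[0]:
            best = (cost, lab_sorted)
    labels = np.empty(n, dtype=int)
    labels[order] = best[1]
    return best[0], labels
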