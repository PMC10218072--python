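"""Polymorphism information content (PIC) scoring.

PIC here is genotype-class based: for a locus with genotype-class frequencies
``f_g`` (missing calls excluded),

    PIC = 1 - sum_g f_g**2

which is the probability that two varieties drawn at random carry different
genotype classes at the locus (a gene-diversity-style score, maximised at
equal class frequencies, zero for monomorphic loci).

During recursive partitioning the panel is held as a :class:`Partition` --
disjoint groups of sample indices covering all samples (the current leaves of
the selection tree).  A locus's *PICsum* is its PIC recomputed inside each
leaf and summed over leaves.  A locus already used for splitting is
monomorphic inside every leaf it created, so its PICsum collapses to zero:
this is what steers the greedy selection away from redundant markers.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotype import MISSING, GenotypeMatrix


class Partition:
    """Disjoint groups of sample indices covering a panel (the tree leaves)."""

    __slots__ = ("groups", "n_samples")

    def __init__(self, groups: Sequence[np.ndarray | Sequence[int]], n_samples: int) -> None:
        groups = [np.asarray(g, dtype=np.intp) for g in groups]
        if any(len(g) == 0 for g in groups):
            raise ValueError("empty group in partition")
        concat = np.concatenate(groups) if groups else np.empty(0, dtype=np.intp)
        if len(concat) != n_samples or len(np.unique(concat)) != n_samples:
            raise ValueError("groups must disjointly cover all sample indices")
        self.groups = groups
        self.n_samples = n_samples

    @classmethod
    def single(cls, n_samples: int) -> "Partition":
        """The root partition: one leaf holding every sample."""
        return cls([np.arange(n_samples)], n_samples)

    @property
    def n_leaves(self) -> int:
        return len(self.groups)

    def is_fully_split(self) -> bool:
        """True when every leaf holds a single sample."""
        return all(len(g) == 1 for g in self.groups)

    def multi_groups(self) -> list[np.ndarray]:
        return [g for g in self.groups if len(g) > 1]

    def __repr__(self) -> str:
        return f"Partition({self.n_leaves} leaves / {self.n_samples} samples)"


def pic(genotype_counts: Mapping[int, int] | Iterable[int]) -> float:
    """PIC from genotype-class counts (missing already excluded).

    Raises ValueError when the total count is zero (frequencies undefined).
    """
    counts = (
        np.fromiter(genotype_counts.values(), dtype=float)
        if isinstance(genotype_counts, Mapping)
        else np.asarray(list(genotype_counts), dtype=float)
    )
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("PIC undefined for zero total count")
    f = counts / total
    return float(1.0 - np.sum(f * f))


def picsum_scores(matrix: GenotypeMatrix, partition: Partition) -> np.ndarray:
    """Vector of PICsum values, one per locus, for the current partition.

    For each leaf with >= 2 samples, per-locus genotype counts are tallied
    and the leaf's PIC added; leaves where a locus is entirely missing (or
    singleton leaves, whose PIC is zero by definition) contribute nothing.
    With a single root leaf this reduces to plain per-locus PIC.
    """
    calls = matrix.calls
    scores = np.zeros(matrix.n_loci, dtype=float)
    for g in partition.groups:
        if len(g) < 2:
            continue
        sub = calls[g]
        tot = (sub != MISSING).sum(axis=0).astype(float)
        sum_sq = np.zeros(matrix.n_loci, dtype=float)
        max_code = int(sub.max(initial=-1))
        for code in range(max_code + 1):
            c = (sub == code).sum(axis=0).astype(float)
            sum_sq += c * c
        nz = tot > 0
        leaf_pic = np.zeros(matrix.n_loci, dtype=float)
        leaf_pic[nz] = 1.0 - sum_sq[nz] / (tot[nz] * tot[nz])
        scores += leaf_pic
    return scores


def pic_sum(matrix: GenotypeMatrix, partition: Partition, locus_id: str) -> float:
    """PICsum of one locus under the current partition (>= 0)."""
    j = matrix.locus_col(locus_id)
    total = 0.0
    for g in partition.groups:
        col = matrix.calls[g, j]
        col = col[col != MISSING]
        if len(col) == 0:
            continue
        _, counts = np.unique(col, return_counts=True)
        total += pic(counts)
    return total


def pic_table(matrix: GenotypeMatrix) -> "np.ndarray":
    """Per-locus PIC over the whole panel (root-partition PICsum)."""
    return picsum_scores(matrix, Partition.single(matrix.n_samples))
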