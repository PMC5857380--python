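"""Bandelt–Dress split decomposition of a distance matrix.

A split is a bipartition of the strains; its isolation index measures how
strongly the distances isolate the two blocks from each other. The d-splits
(positive isolation index) form a weakly compatible system: on a tree
metric they are exactly the tree's edges with branch-length weights, while
conflicting splits produce box-like network structure — the signature of
recombination in MLST data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .trees import DistanceMatrix

__all__ = [
    "Split",
    "SplitSystem",
    "isolation_index",
    "split_decomposition",
    "split_decomposition_brute_force",
    "weakly_compatible",
    "write_nexus_splits",
    "read_nexus_splits",
]

EPSILON = 1e-9  # retention threshold on isolation indices


@dataclass(frozen=True)
class Split:
    """A weighted bipartition, canonically oriented (first label's block first)."""

    block_a: frozenset[str]
    block_b: frozenset[str]
    weight: float

    @classmethod
    def make(cls, block_a, block_b, weight, first_label) -> "Split":
        a, b = frozenset(block_a), frozenset(block_b)
        if first_label in b:
            a, b = b, a
        return cls(a, b, weight)

    @property
    def is_trivial(self) -> bool:
        return min(len(self.block_a), len(self.block_b)) == 1

    def separates(self, x: str, y: str) -> bool:
        return (x in self.block_a) != (y in self.block_a)

    def key(self) -> frozenset[frozenset[str]]:
        return frozenset((self.block_a, self.block_b))


@dataclass
class SplitSystem:
    labels: list[str]
    splits: list[Split] = field(default_factory=list)

    @property
    def fit(self) -> float:
        """Percent of the total distance represented by the split metric."""
        if self._d is None:
            raise ValueError("fit requires the source distance matrix")
        total = 0.0
        rep = 0.0
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                total += self._d.values[i, j]
                rep += self.split_distance(self.labels[i], self.labels[j])
        return 100.0 if total == 0 else 100.0 * rep / total

    _d: DistanceMatrix | None = None

    def split_distance(self, x: str, y: str) -> float:
        return sum(s.weight for s in self.splits if s.separates(x, y))

    def split_distance_matrix(self) -> DistanceMatrix:
        n = len(self.labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = self.split_distance(self.labels[i], self.labels[j])
        return DistanceMatrix(self.labels, d)

    def nontrivial(self) -> list[Split]:
        return [s for s in self.splits if not s.is_trivial]


def isolation_index(dm: DistanceMatrix, block_a: Sequence[str]) -> float:
    """Bandelt–Dress isolation index of a bipartition.

    α = ½ · min over i,j ∈ A, k,l ∈ B (repeats allowed) of
    [ max{d(i,k)+d(j,l), d(i,l)+d(j,k), d(i,j)+d(k,l)} − d(i,j) − d(k,l) ].
    """
    a_set = set(block_a)
    b_set = set(dm.labels) - a_set
    if not a_set or not b_set or a_set - set(dm.labels):
        raise ValueError("degenerate or mislabeled bipartition")
    idx = {l: i for i, l in enumerate(dm.labels)}
    A = [idx[x] for x in sorted(a_set)]
    B = [idx[x] for x in sorted(b_set)]
    d = dm.values
    best = np.inf
    b_pairs = [(k, l) for k in B for l in B if k <= l]
    bk = np.array([p[0] for p in b_pairs])
    bl = np.array([p[1] for p in b_pairs])
    dkl = d[bk, bl]
    for i in A:
        for j in A:
            if j < i:
                continue
            dij = d[i, j]
            m = np.maximum.reduce([
                d[i, bk] + d[j, bl],
                d[i, bl] + d[j, bk],
                np.full(len(b_pairs), dij) + dkl,
            ])
            val = np.min(m - dij - dkl)
            if val < best:
                best = val
    return 0.5 * float(best)


def _submatrix(dm: DistanceMatrix, labels: Sequence[str]) -> DistanceMatrix:
    idx = [dm.labels.index(l) for l in labels]
    return DistanceMatrix(list(labels), dm.values[np.ix_(idx, idx)])


def split_decomposition(dm: DistanceMatrix, epsilon: float = EPSILON) -> SplitSystem:
    """All d-splits of a distance matrix, by incremental taxon insertion.

    Every d-split of a taxon set restricts to a d-split of any subset, so
    inserting taxa one at a time and extending/filtering candidates finds
    the full system without enumerating all bipartitions.
    """
    labels = dm.labels
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    first = labels[0]
    # current splits as (frozenset, frozenset) over the first t labels
    current: list[tuple[frozenset[str], frozenset[str]]] = [
        (frozenset([labels[0]]), frozenset([labels[1]]))
    ]
    for t in range(2, n):
        x = labels[t]
        sub_labels = labels[:t + 1]
        sub = _submatrix(dm, sub_labels)
        candidates: set[frozenset[frozenset[str]]] = set()
        for a, b in current:
            candidates.add(frozenset((a | {x}, b)))
            candidates.add(frozenset((a, b | {x})))
        candidates.add(frozenset((frozenset(sub_labels[:-1]), frozenset([x]))))
        nxt = []
        for cand in candidates:
            a, b = tuple(cand)
            if isolation_index(sub, a) > epsilon:
                nxt.append((a, b))
        current = nxt
    system = SplitSystem(labels=list(labels))
    system._d = dm
    for a, b in current:
        alpha = isolation_index(dm, a)
        if alpha > epsilon:
            system.splits.append(Split.make(a, b, alpha, labels[0]))
    system.splits.sort(key=lambda s: (-s.weight, sorted(s.block_a)))
    return system


def split_decomposition_brute_force(
    dm: DistanceMatrix, epsilon: float = EPSILON
) -> SplitSystem:
    """Exhaustive d-split enumeration over all 2^(n−1)−1 bipartitions.

    Testing oracle for the incremental algorithm; practical for n ≤ 12.
    """
    labels = dm.labels
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    system = SplitSystem(labels=list(labels))
    system._d = dm
    rest = labels[1:]
    for r in range(0, len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            a = frozenset([labels[0], *combo])
            b = frozenset(labels) - a
            if not b:
                continue
            alpha = isolation_index(dm, a)
            if alpha > epsilon:
                system.splits.append(Split.make(a, b, alpha, labels[0]))
    system.splits.sort(key=lambda s: (-s.weight, sorted(s.block_a)))
    return system


def weakly_compatible(splits: Sequence[Split]) -> bool:
    """Check triple-wise weak compatibility by definition.

    Splits S1, S2, S3 fail weak compatibility iff there are taxa a, x, y, z
    with S1 grouping a with x (against y, z), S2 grouping a with y (against
    x, z) and S3 grouping a with z (against x, y). Checked exhaustively;
    intended for small systems (test oracle).
    """
    if not splits:
        return True
    labels = sorted(splits[0].block_a | splits[0].block_b)
    for s1, s2, s3 in itertools.combinations(splits, 3):
        for a in labels:
            sides = [s.block_a if a in s.block_a else s.block_b
                     for s in (s1, s2, s3)]
            for x, y, z in itertools.permutations([l for l in labels if l != a], 3):
                if (x in sides[0]) and (y not in sides[0]) and (z not in sides[0]) \
                   and (y in sides[1]) and (x not in sides[1]) and (z not in sides[1]) \
                   and (z in sides[2]) and (x not in sides[2]) and (y not in sides[2]):
                    return False
    return True


# ---------------------------------------------------------------------------
# NEXUS splits block (SplitsTree-compatible)


def write_nexus_splits(system: SplitSystem, path: str | Path) -> None:
    labels = system.labels
    n = len(labels)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={n};\nTAXLABELS\n")
        for l in labels:
            fh.write(f"    '{l}'\n")
        fh.write(";\nEND;\n\nBEGIN SPLITS;\n")
        fh.write(f"DIMENSIONS NTAX={n} NSPLITS={len(system.splits)};\n")
        fh.write("FORMAT LABELS=NO WEIGHTS=YES;\nMATRIX\n")
        for s in system.splits:
            side = s.block_a if labels[0] in s.block_a else s.block_b
            idxs = sorted(labels.index(x) + 1 for x in side)
            fh.write(f"    {s.weight:.10g}\t{' '.join(map(str, idxs))},\n")
        fh.write(";\nEND;\n")


def read_nexus_splits(path: str | Path) -> SplitSystem:
    labels: list[str] = []
    splits: list[Split] = []
    mode = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            up = line.upper()
            if up.startswith("TAXLABELS"):
                mode = "taxa"
                continue
            if up.startswith("MATRIX"):
                mode = "splits"
                continue
            if line == ";" or up.startswith("END"):
                mode = None
                continue
            if mode == "taxa" and line:
                labels.append(line.strip("'\""))
            elif mode == "splits" and line:
                body = line.rstrip(",").split()
                weight = float(body[0])
                side = frozenset(labels[int(i) - 1] for i in body[1:])
                other = frozenset(labels) - side
                splits.append(Split.make(side, other, weight, labels[0]))
    return SplitSystem(labels=labels, splits=splits)
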