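"""Distance matrices, UPGMA/neighbor-joining trees, bootstrap, Newick.

Distance-based trees summarise strain diversity: UPGMA dendrograms over
allelic-profile mismatch counts, and neighbor joining over p-distances of
the concatenated five-locus sequences (a distance substitute for full
maximum-likelihood inference, whose trees can be built externally from the
exported alignments). All tie-breaks are lowest-index-first so outputs are
run-to-run deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .iupac import bases
from .profiles import StrainProfile
from .scheme import MlstScheme

__all__ = [
    "DistanceMatrix",
    "Clade",
    "allelic_profile_distance",
    "profile_distance_matrix",
    "p_distance",
    "p_distance_matrix",
    "concatenate_loci",
    "upgma",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
]


class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    def __init__(self, labels: Sequence[str], values) -> None:
        self.labels = list(labels)
        v = np.asarray(values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not fit {n} labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        self.values = (v + v.T) / 2
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(pair[0]), self.labels.index(pair[1]))
        return float(self.values[i, j])

    # -- PHYLIP square format ------------------------------------------------
    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self)}\n")
            for label, row in zip(self.labels, self.values):
                cells = " ".join(f"{x:.10g}" for x in row)
                fh.write(f"{label}  {cells}\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            tokens = fh.read().split()
        n = int(tokens[0])
        labels, rows, pos = [], [], 1
        for _ in range(n):
            labels.append(tokens[pos])
            rows.append([float(t) for t in tokens[pos + 1:pos + 1 + n]])
            pos += 1 + n
        return cls(labels, rows)


@dataclass
class Clade:
    """A rooted tree node; leaves carry names, internals optional support."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths."""
        out: dict[str, float] = {}

        def walk(node: Clade, acc: float) -> None:
            if node.is_leaf:
                out[node.name] = acc + node.length
            else:
                for c in node.children:
                    walk(c, acc + node.length)

        walk(self, -self.length)  # exclude the root's own (zero) branch
        return out

    def cophenetic(self, labels: Sequence[str]) -> np.ndarray:
        """Pairwise path-length distances between leaves."""
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: Clade) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: node.length}
            acc: dict[str, float] = {}
            for child in node.children:
                sub = walk(child)
                for a, da in acc.items():
                    for b, db in sub.items():
                        d[idx[a], idx[b]] = d[idx[b], idx[a]] = da + db
                acc.update(sub)
            return {k: v + node.length for k, v in acc.items()}

        walk(self)
        return d

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: Clade, top: bool) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c, False) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{int(round(node.support))}"
            if top:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.10g}"

        return fmt(self, True) + ";"


# ---------------------------------------------------------------------------
# distances


def allelic_profile_distance(a: StrainProfile, b: StrainProfile) -> int:
    """Number of loci at which two profiles carry different genotypes."""
    if len(a.genotypes) != len(b.genotypes):
        raise ValueError("profiles come from different schemes")
    return sum(x != y for x, y in zip(a.genotypes, b.genotypes))


def profile_distance_matrix(profiles: Sequence[StrainProfile]) -> DistanceMatrix:
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = allelic_profile_distance(profiles[i], profiles[j])
    return DistanceMatrix([p.strain_id for p in profiles], d)


def p_distance(a: str, b: str, ambiguity_policy: str = "fractional") -> float:
    """Proportion of mismatched sites between equal-length sequences.

    ``fractional``: an ambiguous site contributes 1 − |Sa∩Sb| / |Sa∪Sb| for
    the IUPAC base sets, so A vs R counts half a difference. ``skip``:
    sites with any ambiguity are excluded entirely.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    num = 0.0
    den = 0
    for x, y in zip(a.upper(), b.upper()):
        sx, sy = bases(x), bases(y)
        if ambiguity_policy == "skip" and (len(sx) > 1 or len(sy) > 1):
            continue
        den += 1
        num += 1.0 - len(sx & sy) / len(sx | sy)
    if den == 0:
        raise ValueError("no comparable sites")
    return num / den


def p_distance_matrix(
    labels: Sequence[str],
    seqs: Sequence[str],
    ambiguity_policy: str = "fractional",
) -> DistanceMatrix:
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(seqs[i], seqs[j], ambiguity_policy)
    return DistanceMatrix(labels, d)


def concatenate_loci(
    fragments: Mapping[str, str],
    scheme: MlstScheme,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Concatenate one strain's fragments in scheme order.

    Returns the concatenated sequence and per-locus 1-based inclusive
    coordinate spans within it, for downstream site bookkeeping.
    """
    parts = []
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for locus in scheme:
        if locus.name not in fragments:
            raise KeyError(f"missing locus {locus.name}")
        frag = fragments[locus.name]
        if len(frag) != locus.fragment_size:
            raise ValueError(
                f"{locus.name}: fragment length {len(frag)} != scheme "
                f"fragment size {locus.fragment_size}"
            )
        parts.append(frag)
        offsets[locus.name] = (pos + 1, pos + len(frag))
        pos += len(frag)
    return "".join(parts), offsets


# ---------------------------------------------------------------------------
# tree building


def upgma(dm: DistanceMatrix) -> Clade:
    """Average-linkage (UPGMA) rooted ultrametric tree.

    Cluster updates are weighted by cluster sizes; the lowest-index pair
    merges first on ties.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 labels")
    d = dm.values.copy()
    nodes: list[Clade | None] = [Clade(name=l) for l in dm.labels]
    sizes = [1] * n
    heights = [0.0] * n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                key = d[i, j]
                if best is None or key < best[0] - 1e-15:
                    best = (key, i, j)
        _, i, j = best
        h = d[i, j] / 2
        left, right = nodes[i], nodes[j]
        left.length = h - heights[i]
        right.length = h - heights[j]
        parent = Clade(children=[left, right])
        # weighted average update (UPGMA proper)
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (
                sizes[i] * d[i, k] + sizes[j] * d[j, k]
            ) / (sizes[i] + sizes[j])
        sizes[i] += sizes[j]
        heights[i] = h
        nodes[i] = parent
        nodes[j] = None
        active.remove(j)
    root = nodes[active[0]]
    root.length = 0.0
    return root


def neighbor_joining(dm: DistanceMatrix) -> Clade:
    """Saitou–Nei neighbor joining; unrooted tree (root is a trifurcation).

    Negative branch lengths are clamped to zero with a warning.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("need at least 3 labels")
    d = dm.values.copy()
    nodes: list[Clade] = [Clade(name=l) for l in dm.labels]
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < -1e-9:
            warnings.warn("negative branch length clamped to 0", stacklevel=3)
        return max(x, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent = Clade(children=[nodes[i], nodes[j]])
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[i] = parent
        active.remove(j)
    i, j, k = active
    # closed-form lengths for the final three branches
    nodes[i].length = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].length = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].length = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    return Clade(children=[nodes[i], nodes[j], nodes[k]])


def bipartitions(tree: Clade, labels: Sequence[str] | None = None) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each as the smaller-side block
    (canonicalised against the full label set)."""
    all_labels = frozenset(labels if labels is not None else tree.leaf_names())
    out: set[frozenset[str]] = set()

    def walk(node: Clade) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if 1 < len(below) < len(all_labels) - 1:
            other = all_labels - below
            out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        return below

    walk(tree)
    return out


def bootstrap_support(
    labels: Sequence[str],
    seqs: Sequence[str],
    builder: str | Callable[[DistanceMatrix], Clade] = "nj",
    n_replicates: int = 1000,
    seed: int | None = None,
    ambiguity_policy: str = "fractional",
    locus_spans: Mapping[str, tuple[int, int]] | None = None,
) -> Clade:
    """Column-bootstrap support values on a distance tree.

    Resamples alignment columns with replacement (or whole loci when
    ``locus_spans`` is given), rebuilds with the same method, and labels
    each internal bipartition of the original tree with the percentage of
    replicates containing it.
    """
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("alignment is not rectangular")
    build = {"upgma": upgma, "nj": neighbor_joining}.get(builder, builder)
    if not callable(build):
        raise ValueError(f"unknown builder {builder!r}")
    arr = np.array([list(s) for s in seqs])
    tree = build(p_distance_matrix(labels, seqs, ambiguity_policy))
    target = bipartitions(tree, labels)
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    L = arr.shape[1]
    for _ in range(n_replicates):
        if locus_spans is not None:
            blocks = list(locus_spans.values())
            chosen = rng.integers(0, len(blocks), size=len(blocks))
            cols = np.concatenate(
                [np.arange(blocks[c][0] - 1, blocks[c][1]) for c in chosen])
        else:
            cols = rng.integers(0, L, size=L)
        boot = ["".join(row) for row in arr[:, cols]]
        rep = build(p_distance_matrix(labels, boot, ambiguity_policy))
        for b in bipartitions(rep, labels):
            if b in counts:
                counts[b] += 1

    def annotate(node: Clade, seen: frozenset[str]) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c, seen) for c in node.children))
        key = min(below, frozenset(labels) - below, key=lambda s: (len(s), sorted(s)))
        if key in counts:
            node.support = 100.0 * counts[key] / n_replicates
        return below

    annotate(tree, frozenset())
    return tree
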