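"""Recombination and selection statistics.

* Index of association I_A and its standardized form I^S_A = I_A/(l−1):
  multilocus linkage disequilibrium from the variance of pairwise
  locus-mismatch counts, with a within-locus permutation null. Zero is
  expected under free recombination (linkage equilibrium); clonal
  populations inflate the variance.
* PHI (pairwise homoplasy) test: mean refined incompatibility of nearby
  parsimony-informative site pairs against a permuted-site-order null;
  recombination makes nearby sites more compatible than distant ones.
* Nei–Gojobori dN/dS with pathway averaging and codon bootstrap; ratios
  below 1 indicate purifying selection (locus neutrality for typing).
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .iupac import bases
from .profiles import DstCatalog

__all__ = [
    "IaResult",
    "PhiResult",
    "DnDsResult",
    "locus_heterozygosity",
    "index_of_association",
    "parsimony_informative_columns",
    "pair_incompatibility",
    "phi_statistic",
    "phi_test",
    "codon_sites",
    "pairwise_codon_differences",
    "dn_ds",
]


# ---------------------------------------------------------------------------
# index of association


@dataclass(frozen=True)
class IaResult:
    n: int
    l: int
    h: tuple[float, ...]           # per-locus unbiased heterozygosity
    mean_k: float                  # mean pairwise locus-mismatch count
    v_d: float                     # observed variance of mismatch counts
    v_e: float                     # expected variance under equilibrium
    i_a: float
    i_sa: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None


def _genotype_matrix(catalog: DstCatalog) -> np.ndarray:
    return catalog.genotype_matrix().to_numpy()


def locus_heterozygosity(catalog: DstCatalog, locus: str) -> float:
    """Unbiased expected heterozygosity h = n/(n−1)·(1 − Σ p_i²)."""
    j = catalog.loci.index(locus)
    column = _genotype_matrix(catalog)[:, j]
    return _h_unbiased(column)


def _h_unbiased(column: np.ndarray) -> float:
    n = len(column)
    if n < 2:
        raise ValueError("need at least 2 strains")
    _, counts = np.unique(column, return_counts=True)
    p = counts / n
    return n / (n - 1) * (1.0 - float(np.sum(p**2)))


def _pair_mismatch_counts(G: np.ndarray) -> np.ndarray:
    n, l = G.shape
    K = np.zeros((n, n))
    for j in range(l):
        K += G[:, j][:, None] != G[:, j][None, :]
    iu = np.triu_indices(n, 1)
    return K[iu]


def index_of_association(
    catalog: DstCatalog,
    n_permutations: int = 0,
    seed: int | None = None,
    variance: str = "population",
) -> IaResult:
    """I_A = V_D/V_e − 1 and I^S_A = I_A/(l−1) over all strain pairs.

    K_ab counts loci at which strains a and b differ; V_D is the variance
    of {K_ab} over the n(n−1)/2 unordered pairs (population variance by
    default, ``variance="sample"`` divides by pairs−1); V_e = Σ h_j(1−h_j).
    The permutation null shuffles each locus column independently, keeping
    allele frequencies but destroying between-locus association; the
    p-value is (#{V_D,perm ≥ V_D} + 1)/(B + 1).
    """
    G = _genotype_matrix(catalog)
    n, l = G.shape
    if l < 2:
        raise ValueError("I^S_A undefined for a single locus")
    if n < 3:
        raise ValueError("need at least 3 strains")
    ddof = 0 if variance == "population" else 1
    h = np.array([_h_unbiased(G[:, j]) for j in range(l)])
    v_e = float(np.sum(h * (1 - h)))
    if v_e <= 0:
        raise ValueError(
            "expected variance V_e is zero (every locus is either "
            "monomorphic or fully polymorphic)")
    k = _pair_mismatch_counts(G)
    v_d = float(k.var(ddof=ddof))
    i_a = v_d / v_e - 1
    i_sa = i_a / (l - 1)
    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        P = G.copy()
        for _ in range(n_permutations):
            for j in range(l):
                rng.shuffle(P[:, j])
            if _pair_mismatch_counts(P).var(ddof=ddof) >= v_d:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)
    return IaResult(n=n, l=l, h=tuple(float(x) for x in h),
                    mean_k=float(k.mean()),
                    v_d=v_d, v_e=v_e, i_a=i_a, i_sa=i_sa,
                    p_value=p_value, n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# PHI test


@dataclass(frozen=True)
class PhiResult:
    phi: float
    w: int
    n_informative: int
    n_pairs: int
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    computable: bool = True


def parsimony_informative_columns(seqs: Sequence[str]) -> list[tuple[int, list[str]]]:
    """Columns with ≥2 states each carried by ≥2 sequences.

    Heterozygous IUPAC calls are treated as missing (None): a diploid
    ambiguity is not a third allele and must not masquerade as homoplasy.
    Returns (0-based position, per-sequence resolved state or None).
    """
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("alignment is not rectangular")
    out = []
    for col in range(length):
        states: list[str | None] = []
        for s in seqs:
            c = s[col].upper()
            states.append(c if len(bases(c)) == 1 else None)
        counts: dict[str, int] = {}
        for c in states:
            if c is not None:
                counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            out.append((col, states))
    return out


def pair_incompatibility(states_a: Sequence[str | None],
                         states_b: Sequence[str | None]) -> int:
    """Refined incompatibility of two sites: E − V + C of the state graph.

    Vertices are the states observed at each site, edges the distinct joint
    states, over sequences resolved at both sites. Zero iff the pair is
    compatible with a single tree (for binary sites this is exactly the
    four-gamete test); each extra cycle is one extra homoplasy.
    """
    edges = set()
    for a, b in zip(states_a, states_b):
        if a is not None and b is not None:
            edges.add((a, b))
    va = {a for a, _ in edges}
    vb = {b for _, b in edges}
    # connected components of the bipartite graph by union-find
    parent: dict[tuple[int, str], tuple[int, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for v in [(0, a) for a in va] + [(1, b) for b in vb]:
        parent[v] = v
    for a, b in edges:
        ra, rb = find((0, a)), find((1, b))
        if ra != rb:
            parent[ra] = rb
    comps = len({find(v) for v in parent})
    return len(edges) - (len(va) + len(vb)) + comps


def _phi_machinery(seqs: Sequence[str], w: int):
    info = parsimony_informative_columns(seqs)
    m = len(info)
    if m < 2:
        return None
    positions = np.array([p for p, _ in info])
    score = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            score[i, j] = score[j, i] = pair_incompatibility(info[i][1], info[j][1])
    near = np.abs(positions[:, None] - positions[None, :]) < w
    np.fill_diagonal(near, False)
    return positions, score, near, m


def phi_statistic(seqs: Sequence[str], w: int = 100) -> PhiResult:
    """Mean refined incompatibility over informative site pairs closer than
    ``w`` alignment positions."""
    mach = _phi_machinery(seqs, w)
    if mach is None:
        return PhiResult(phi=math.nan, w=w, n_informative=0, n_pairs=0,
                         computable=False)
    _, score, near, m = mach
    iu = np.triu_indices(m, 1)
    mask = near[iu]
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        return PhiResult(phi=math.nan, w=w, n_informative=m, n_pairs=0,
                         computable=False)
    phi = float(score[iu][mask].mean())
    return PhiResult(phi=phi, w=w, n_informative=m, n_pairs=n_pairs)


def phi_test(
    seqs: Sequence[str],
    w: int = 100,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> PhiResult:
    """PHI permutation test for recombination.

    The null permutes informative sites over their positions, destroying
    any spatial clustering of compatibility. One-sided: recombination makes
    *nearby* pairs less incompatible than random ones, so
    p = (#{phi_perm ≤ phi_obs} + 1)/(B + 1).
    """
    mach = _phi_machinery(seqs, w)
    if mach is None:
        return PhiResult(phi=math.nan, w=w, n_informative=0, n_pairs=0,
                         computable=False, seed=seed)
    _, score, near, m = mach
    iu = np.triu_indices(m, 1)
    mask = near[iu]
    if not mask.any():
        return PhiResult(phi=math.nan, w=w, n_informative=m, n_pairs=0,
                         computable=False, seed=seed)
    obs = float(score[iu][mask].mean())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(m)
        ps = score[np.ix_(perm, perm)]
        if float(ps[iu][mask].mean()) <= obs + 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PhiResult(phi=obs, w=w, n_informative=m, n_pairs=int(mask.sum()),
                     p_value=p, n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# Nei–Gojobori dN/dS


@dataclass(frozen=True)
class DnDsResult:
    dn: float
    ds: float
    ratio: float | None            # None when 0/0; inf when dS=0 < dN
    se: float | None = None        # codon-bootstrap SE of the ratio
    n_bootstrap: int = 0
    n_codons: int = 0
    n_pairs: int = 0


_STOPS = {"TAA", "TAG", "TGA"}


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon (NG86).

    At each position the fraction of one-step changes that are synonymous
    is counted; changes creating stop codons are disregarded.
    """
    if codon in _STOPS:
        return 0.0, 0.0
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in _STOPS:
                continue
            tot += 1
            if _translate(alt) == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pairwise_codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two codons.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are excluded (all pathways are kept if every
    one is blocked). Counts are averaged over the retained pathways.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                blocked = True
            if _translate(nxt) == _translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in pathways if not b]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in pathways]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


def _split_codons(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def dn_ds(
    seqs: Sequence[str],
    n_bootstrap: int = 1000,
    seed: int | None = None,
    ambiguity_policy: str = "skip",
    jukes_cantor: bool = False,
) -> DnDsResult:
    """Mean pairwise Nei–Gojobori dN and dS over an in-frame codon alignment.

    Proportion distances by default (``jukes_cantor`` applies the standard
    correction). Codons containing ambiguity codes are skipped under
    ``ambiguity_policy="skip"`` or expanded and averaged under ``"expand"``.
    The standard error of dN/dS comes from a codon bootstrap.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    codon_lists = [_split_codons(s.upper()) for s in seqs]
    n_codons = len(codon_lists[0])
    if any(len(c) != n_codons for c in codon_lists):
        raise ValueError("sequences differ in length")
    for cl in codon_lists:
        for c in cl:
            if c in _STOPS:
                raise ValueError(f"internal stop codon {c}")

    # per strain pair, per codon: (S, N, Sd, Nd) contributions, averaged over
    # ambiguity expansions; computed once so the bootstrap only re-sums
    pair_tables: list[np.ndarray] = []
    for a, b in itertools.combinations(range(len(seqs)), 2):
        table = np.zeros((n_codons, 4))
        for i in range(n_codons):
            pairs = _codon_pairs(codon_lists[a][i], codon_lists[b][i],
                                 ambiguity_policy)
            if not pairs:
                continue
            acc = np.zeros(4)
            for x, y in pairs:
                s1, n1 = codon_sites(x)
                s2, n2 = codon_sites(y)
                sd, nd = pairwise_codon_differences(x, y)
                acc += ((s1 + s2) / 2, (n1 + n2) / 2, sd, nd)
            table[i] = acc / len(pairs)
        pair_tables.append(table)

    def stats(codon_idx) -> tuple[float, float]:
        dns, dss = [], []
        for table in pair_tables:
            S, N, Sd, Nd = table[codon_idx].sum(axis=0)
            ps = Sd / S if S > 0 else 0.0
            pn = Nd / N if N > 0 else 0.0
            if jukes_cantor:
                ps = _jc(ps)
                pn = _jc(pn)
            dss.append(ps)
            dns.append(pn)
        return float(np.mean(dns)), float(np.mean(dss))

    dn, ds = stats(range(n_codons))
    ratio: float | None
    if ds == 0 and dn == 0:
        ratio = None
    elif ds == 0:
        ratio = math.inf
    else:
        ratio = dn / ds
    se = None
    if n_bootstrap > 0 and ratio is not None and math.isfinite(ratio):
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n_codons, size=n_codons)
            bdn, bds = stats(idx)
            if bds > 0:
                reps.append(bdn / bds)
        if len(reps) > 1:
            se = float(np.std(reps, ddof=1))
    return DnDsResult(dn=dn, ds=ds, ratio=ratio, se=se,
                      n_bootstrap=n_bootstrap, n_codons=n_codons,
                      n_pairs=len(seqs) * (len(seqs) - 1) // 2)


def _jc(p: float) -> float:
    if p >= 0.75:
        raise ValueError("proportion too large for Jukes–Cantor correction")
    return -0.75 * math.log(1 - 4 * p / 3)


def _codon_pairs(ca: str, cb: str, policy: str) -> list[tuple[str, str]]:
    amb_a = any(len(bases(c)) > 1 for c in ca)
    amb_b = any(len(bases(c)) > 1 for c in cb)
    if not amb_a and not amb_b:
        return [(ca, cb)]
    if policy == "skip":
        return []
    ex_a = [x for x in _expand(ca) if x not in _STOPS] or _expand(ca)
    ex_b = [x for x in _expand(cb) if x not in _STOPS] or _expand(cb)
    return [(x, y) for x in ex_a for y in ex_b]


def _expand(codon: str) -> list[str]:
    out = [""]
    for c in codon:
        out = [p + b for p in out for b in sorted(bases(c))]
    return out
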