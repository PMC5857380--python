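"""Synthetic diploid MLST populations and Sanger-style strand reads.

The generator emulates the study system: diploid yeast strains typed at
five housekeeping loci, with heterozygous positions emitted as IUPAC
double-peak codes on both strands. Two population structures bracket the
biology: ``clonal`` strains copy a few founder genotype vectors (strong
linkage, tree-like signal) while ``panmictic`` strains draw each locus
independently from the allele pool (linkage equilibrium, as under free
recombination); ``mixture`` recombines a fraction of strains. Defaults are
sized to the study population (83 strains, 5 loci, fragment lengths
763/791/862/871/906, 26–37 alleles per locus, ~4.6 % polymorphic sites).

Alignment-level helpers generate clonal (mutations on a random tree, with
recurrent mutation, hence homoplasy but no spatial signal) and two-block
recombinant alignments for calibrating the recombination tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .iupac import code_for, reverse_complement
from .profiles import DstCatalog, StrainProfile
from .scheme import MlstScheme, SequenceRecord, write_fasta
from .typing import AlleleCatalog

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "simulate_allele_pool",
    "simulate_population",
    "emit_reads",
    "simulate_clonal_alignment",
    "simulate_recombinant_alignment",
]

_BASES = np.array(list("ACGT"))

# study-scale defaults
DEFAULT_FRAGMENT_LENGTHS = (763, 791, 862, 871, 906)
DEFAULT_ALLELES_PER_LOCUS = (28, 37, 30, 34, 26)
DEFAULT_POLY_SITES = (25, 44, 34, 49, 44)


@dataclass
class SimulationConfig:
    seed: int
    n_strains: int = 83
    n_loci: int = 5
    fragment_lengths: tuple[int, ...] = DEFAULT_FRAGMENT_LENGTHS
    alleles_per_locus: tuple[int, ...] = DEFAULT_ALLELES_PER_LOCUS
    polymorphic_sites_per_locus: tuple[int, ...] = DEFAULT_POLY_SITES
    recombination_mode: str = "clonal"      # clonal | panmictic | mixture
    mixture_rate: float = 0.0               # P(strain recombines) in mixture mode
    n_founders: int = 8
    heterozygosity_rate: float = 0.3        # P(two distinct alleles at a locus)
    mutation_rate: float = 0.0              # per-site per-transmission
    locus_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("fragment_lengths", "alleles_per_locus",
                     "polymorphic_sites_per_locus"):
            val = getattr(self, name)
            if isinstance(val, int):
                val = (val,) * self.n_loci
            val = tuple(val)[: self.n_loci]
            if len(val) != self.n_loci or any(v < 1 for v in val):
                raise ValueError(f"{name} must give a positive value per locus")
            setattr(self, name, val)
        if self.n_strains < 1 or self.n_founders < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.mixture_rate <= 1:
            raise ValueError("mixture_rate must be in [0, 1]")
        if not 0 <= self.heterozygosity_rate <= 1:
            raise ValueError("heterozygosity_rate must be in [0, 1]")
        if self.recombination_mode not in ("clonal", "panmictic", "mixture"):
            raise ValueError(f"unknown mode {self.recombination_mode!r}")
        if not self.locus_names:
            self.locus_names = tuple(f"L{i + 1}" for i in range(self.n_loci))


@dataclass
class SimulatedPopulation:
    config: SimulationConfig
    strain_ids: list[str]
    pools: list[list[str]]                       # per locus: allele sequences
    truth_pairs: list[list[tuple[str, str]]]     # per strain per locus
    founder_of: list[int | None]                 # None = panmictic draw
    merged: dict[str, dict[str, str]]            # strain -> locus -> IUPAC seq
    catalogs: dict[str, AlleleCatalog]
    profiles: DstCatalog

    def truth_partition(self) -> dict[tuple, set[str]]:
        """Strains grouped by identical (unordered) true allele pairs."""
        groups: dict[tuple, set[str]] = {}
        for sid, pairs in zip(self.strain_ids, self.truth_pairs):
            key = tuple(tuple(sorted(p)) for p in pairs)
            groups.setdefault(key, set()).add(sid)
        return groups


def simulate_allele_pool(
    length: int,
    n_alleles: int,
    n_polymorphic_sites: int,
    rng: np.random.Generator,
) -> list[str]:
    """Distinct allele sequences differing only at designated sites.

    The first allele is the random reference; variants substitute at a
    random non-empty subset of the polymorphic sites. No indels.
    """
    if n_polymorphic_sites > length:
        raise ValueError("more polymorphic sites than sequence length")
    if n_alleles > 4 ** n_polymorphic_sites:
        raise ValueError(
            f"cannot make {n_alleles} distinct alleles from "
            f"{n_polymorphic_sites} sites"
        )
    ref = "".join(rng.choice(_BASES, size=length))
    sites = sorted(rng.choice(length, size=n_polymorphic_sites, replace=False))
    pool = [ref]
    seen = {ref}
    while len(pool) < n_alleles:
        n_mut = 1 + rng.binomial(max(n_polymorphic_sites - 1, 0), 0.3)
        chosen = rng.choice(sites, size=min(n_mut, len(sites)), replace=False)
        seq = list(ref)
        for s in chosen:
            alts = [b for b in "ACGT" if b != ref[s]]
            seq[s] = alts[rng.integers(0, 3)]
        cand = "".join(seq)
        if cand not in seen:
            seen.add(cand)
            pool.append(cand)
    return pool


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        alts = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alts[rng.integers(0, 3)]
    return "".join(out)


def _merge_pair(a: str, b: str) -> str:
    return "".join(x if x == y else code_for({x, y}) for x, y in zip(a, b))


def _draw_pair(pool: list[str], het_rate: float,
               rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(0, len(pool)))
    if len(pool) > 1 and rng.random() < het_rate:
        j = int(rng.integers(0, len(pool) - 1))
        if j >= i:
            j += 1
        return pool[i], pool[j]
    return pool[i], pool[i]


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Simulate diploid strains, their merged IUPAC fragments and profiles.

    Deterministic given the seed: the same config reproduces the same
    population bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    pools = [
        simulate_allele_pool(L, k, s, rng)
        for L, k, s in zip(config.fragment_lengths, config.alleles_per_locus,
                           config.polymorphic_sites_per_locus)
    ]
    founders = [
        [_draw_pair(pool, config.heterozygosity_rate, rng) for pool in pools]
        for _ in range(config.n_founders)
    ]
    width = len(str(config.n_strains))
    strain_ids = [f"S{i + 1:0{width}d}" for i in range(config.n_strains)]
    truth_pairs: list[list[tuple[str, str]]] = []
    founder_of: list[int | None] = []
    for _ in range(config.n_strains):
        if config.recombination_mode == "panmictic":
            recombinant = True
        elif config.recombination_mode == "mixture":
            recombinant = rng.random() < config.mixture_rate
        else:
            recombinant = False
        if recombinant:
            pairs = [_draw_pair(pool, config.heterozygosity_rate, rng)
                     for pool in pools]
            founder_of.append(None)
        else:
            f = int(rng.integers(0, config.n_founders))
            pairs = [tuple(founders[f][j]) for j in range(config.n_loci)]
            founder_of.append(f)
        pairs = [
            (_mutate(a, config.mutation_rate, rng),
             _mutate(b, config.mutation_rate, rng))
            for a, b in pairs
        ]
        truth_pairs.append(pairs)

    merged: dict[str, dict[str, str]] = {}
    for sid, pairs in zip(strain_ids, truth_pairs):
        merged[sid] = {
            locus: _merge_pair(a, b)
            for locus, (a, b) in zip(config.locus_names, pairs)
        }
    catalogs = {
        locus: AlleleCatalog.from_sequences(
            locus, [merged[sid][locus] for sid in strain_ids])
        for locus in config.locus_names
    }
    profiles = DstCatalog(config.locus_names)
    for sid in strain_ids:
        genotypes = tuple(
            catalogs[locus].add(merged[sid][locus])
            for locus in config.locus_names
        )
        profiles.add(StrainProfile(strain_id=sid, genotypes=genotypes))
    return SimulatedPopulation(
        config=config, strain_ids=strain_ids, pools=pools,
        truth_pairs=truth_pairs, founder_of=founder_of, merged=merged,
        catalogs=catalogs, profiles=profiles,
    )


def emit_reads(
    pop: SimulatedPopulation,
    out_dir: str | Path,
    scheme: MlstScheme | None = None,
) -> tuple[Path, Path]:
    """Write forward and reverse read FASTA files (ids ``strain|locus``).

    Both strands carry the IUPAC code at heterozygous sites, as double
    peaks appear on both chromatograms. With a scheme, primer flanks are
    added so the trimming step can be exercised end to end.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fwd_records, rev_records = [], []
    for sid in pop.strain_ids:
        for locus_name, seq in pop.merged[sid].items():
            if scheme is not None:
                locus = scheme.locus(locus_name)
                seq = (locus.fwd_primer + seq
                       + reverse_complement(locus.rev_primer))
            fwd_records.append(SequenceRecord(
                id=f"{sid}|{locus_name}", sequence=seq,
                locus=locus_name, strand="forward"))
            rev_records.append(SequenceRecord(
                id=f"{sid}|{locus_name}", sequence=reverse_complement(seq),
                locus=locus_name, strand="reverse"))
    fwd_path = out_dir / "reads_fwd.fasta"
    rev_path = out_dir / "reads_rev.fasta"
    write_fasta(fwd_records, fwd_path)
    write_fasta(rev_records, rev_path)
    return fwd_path, rev_path


# ---------------------------------------------------------------------------
# alignment-level generators for the recombination tests


def _random_tree(n: int, rng: np.random.Generator):
    """Random binary topology by uniform pair coalescence; exp(1) branches."""
    active = list(range(n))
    # node id -> (id, branch length, left child, right child)
    store: dict[int, tuple] = {i: (i, float(rng.exponential()), None, None)
                               for i in range(n)}
    nxt = n
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        store[nxt] = (nxt, float(rng.exponential()), a, b)
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root = active[0]
    return store, root


def simulate_clonal_alignment(
    n_sequences: int,
    length: int,
    expected_mutations: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Sequences evolved along a random tree without recombination.

    Mutations land on random sites (recurrent mutation allowed), so
    homoplasy occurs but carries no spatial pattern — the null model of
    the PHI test holds exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    store, root = _random_tree(n_sequences, rng)
    total_bl = sum(v[1] for k, v in store.items() if k != root)
    seqs: dict[int, str] = {}
    root_seq = "".join(rng.choice(_BASES, size=length))

    def walk(node: int, parent_seq: str) -> None:
        _, bl, left, right = store[node]
        if node == root:
            seq = parent_seq
        else:
            lam = expected_mutations * bl / total_bl if total_bl > 0 else 0.0
            seq = parent_seq
            for _ in range(rng.poisson(lam)):
                pos = int(rng.integers(0, length))
                alts = [b for b in "ACGT" if b != seq[pos]]
                seq = seq[:pos] + alts[rng.integers(0, 3)] + seq[pos + 1:]
        if left is None:
            seqs[node] = seq
        else:
            walk(left, seq)
            walk(right, seq)

    walk(root, root_seq)
    return [seqs[i] for i in range(n_sequences)]


def simulate_recombinant_alignment(
    n_sequences: int,
    length: int,
    n_divergent_sites: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise_mutations: int = 2,
) -> list[str]:
    """Two divergent haplotype blocks, recombined in half the sequences.

    Half the sequences are pure haplotype A or B; the other half swap
    blocks at the midpoint breakpoint (A-left/B-right and the reverse).
    Site pairs spanning the breakpoint show all four gametes while pairs
    within a block show two — the spatial compatibility pattern the PHI
    test detects.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_sequences < 4:
        raise ValueError("need at least 4 sequences")
    hap_a = "".join(rng.choice(_BASES, size=length))
    sites = sorted(rng.choice(length, size=n_divergent_sites, replace=False))
    b = list(hap_a)
    for s in sites:
        alts = [x for x in "ACGT" if x != b[s]]
        b[s] = alts[rng.integers(0, 3)]
    hap_b = "".join(b)
    bp = length // 2
    templates = [
        hap_a,
        hap_b,
        hap_a[:bp] + hap_b[bp:],
        hap_b[:bp] + hap_a[bp:],
    ]
    seqs = []
    for i in range(n_sequences):
        seq = templates[i % 4]
        for _ in range(rng.poisson(noise_mutations)):
            pos = int(rng.integers(0, length))
            alts = [x for x in "ACGT" if x != seq[pos]]
            seq = seq[:pos] + alts[rng.integers(0, 3)] + seq[pos + 1:]
        seqs.append(seq)
    return seqs
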