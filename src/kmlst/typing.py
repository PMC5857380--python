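"""Allele typing: strand-read merging, catalogs, genotype calls, site classes.

Every unique fragment sequence of a locus — compared as literal IUPAC
strings, so a heterozygous R is a different genotype from a homozygous A —
receives a genotype number. Genotype 1 is the reference: the majority
consensus over the typed population. A sequence differing at even a single
site is a distinct genotype; no alignment is attempted because the typed
fragments carry no indels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .iupac import bases, code_for, is_ambiguous, reverse_complement, validate_sequence
from .scheme import LocusDefinition, SequenceRecord

__all__ = [
    "AlleleCatalog",
    "GenotypeCall",
    "MergeResult",
    "MergeError",
    "CallError",
    "PolymorphicSite",
    "SiteClassification",
    "merge_strand_reads",
    "call_allele",
    "build_reference_allele",
    "find_polymorphic_sites",
    "classify_site",
    "AA_CATEGORIES",
]


class MergeError(ValueError):
    """Forward/reverse reads cannot be reconciled."""


class CallError(ValueError):
    """A fragment cannot be called against a catalog."""


@dataclass
class MergeResult:
    """Consensus of a forward/reverse read pair.

    ``conflicts`` lists 1-based positions where the two strands share no
    base (output as N); ``heterozygous_positions`` lists positions whose
    consensus is an ambiguity code — the double-peak heterozygote signal
    seen on both strands.
    """

    record: SequenceRecord
    conflicts: list[tuple[int, str, str]] = field(default_factory=list)
    heterozygous_positions: list[int] = field(default_factory=list)


def merge_strand_reads(
    fwd: SequenceRecord,
    rev: SequenceRecord,
    max_conflict_fraction: float = 0.05,
) -> MergeResult:
    """Merge a forward read and a reverse read into an IUPAC consensus.

    The reverse read is reverse-complemented, then each position's consensus
    is the IUPAC code of the intersection of the two base sets. An empty
    intersection becomes N and is reported as a conflict; more than
    ``max_conflict_fraction`` conflicting positions aborts the merge.
    """
    r = reverse_complement(rev.sequence) if rev.strand != "forward" else rev.sequence
    f = fwd.sequence
    if len(f) != len(r):
        raise MergeError(
            f"{fwd.id}: strand length mismatch ({len(f)} vs {len(r)}); "
            "reads must align without indels"
        )
    out = []
    conflicts: list[tuple[int, str, str]] = []
    hets: list[int] = []
    for i, (a, b) in enumerate(zip(f, r), start=1):
        inter = bases(a) & bases(b)
        if not inter:
            out.append("N")
            conflicts.append((i, a, b))
            continue
        code = code_for(inter)
        out.append(code)
        if len(inter) > 1:
            hets.append(i)
    if len(conflicts) > max_conflict_fraction * len(f):
        raise MergeError(
            f"{fwd.id}: {len(conflicts)} strand conflicts in {len(f)} positions "
            f"exceeds the {max_conflict_fraction:.0%} threshold"
        )
    rec = SequenceRecord(id=fwd.id, sequence="".join(out),
                         locus=fwd.locus or rev.locus, strand="merged")
    return MergeResult(record=rec, conflicts=conflicts, heterozygous_positions=hets)


@dataclass
class GenotypeCall:
    locus: str
    genotype: int | None
    is_novel: bool = False
    heterozygous_positions: list[int] = field(default_factory=list)

    @property
    def matched(self) -> bool:
        return self.genotype is not None


def build_reference_allele(
    alleles: Sequence[str],
    weights: Sequence[int] | None = None,
) -> str:
    """Majority-consensus sequence: the most common nucleotide at each site.

    ``weights`` gives per-allele strain multiplicities so the consensus
    reflects the population, not the allele list. Ties break alphabetically.
    """
    if not alleles:
        raise ValueError("no alleles given")
    alleles = [validate_sequence(a) for a in alleles]
    length = len(alleles[0])
    if any(len(a) != length for a in alleles):
        raise ValueError("alleles differ in length")
    if weights is None:
        weights = [1] * len(alleles)
    out = []
    for col in range(length):
        counts: Counter[str] = Counter()
        for a, w in zip(alleles, weights):
            counts[a[col]] += w
        # tie-break: among max counts pick alphabetically smallest symbol
        top = max(counts.values())
        out.append(min(c for c, n in counts.items() if n == top))
    return "".join(out)


class AlleleCatalog:
    """Numbered allele sequences of one locus; genotype 1 is the reference.

    Registration is append-only and input-order deterministic, so replaying
    the same discovery order always reproduces the same numbering.
    """

    def __init__(self, locus: str, fragment_length: int | None = None) -> None:
        self.locus = locus
        self.fragment_length = fragment_length
        self._by_number: dict[int, str] = {}
        self._by_sequence: dict[str, int] = {}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_sequences(
        cls,
        locus: str,
        sequences: Iterable[str],
        weights: Sequence[int] | None = None,
        seed_reference: bool = True,
    ) -> "AlleleCatalog":
        """Build a catalog from observed fragments in discovery order.

        With ``seed_reference`` the majority consensus over the inputs
        becomes genotype 1 and observed variants are numbered from there.
        """
        seqs = [validate_sequence(s) for s in sequences]
        if not seqs:
            raise ValueError("no sequences given")
        cat = cls(locus, fragment_length=len(seqs[0]))
        if seed_reference:
            cat.add(build_reference_allele(seqs, weights))
        for s in seqs:
            cat.add(s)
        return cat

    def add(self, sequence: str) -> int:
        """Register a sequence (idempotent); returns its genotype number."""
        sequence = validate_sequence(sequence)
        if self.fragment_length is None:
            self.fragment_length = len(sequence)
        if len(sequence) != self.fragment_length:
            raise CallError(
                f"{self.locus}: sequence length {len(sequence)} != catalog "
                f"fragment length {self.fragment_length}"
            )
        if sequence in self._by_sequence:
            return self._by_sequence[sequence]
        number = len(self._by_number) + 1
        self._by_number[number] = sequence
        self._by_sequence[sequence] = number
        return number

    # -- access ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._by_number)

    def __contains__(self, sequence: str) -> bool:
        return validate_sequence(sequence) in self._by_sequence

    @property
    def genotype_numbers(self) -> list[int]:
        return sorted(self._by_number)

    def sequence(self, genotype: int) -> str:
        return self._by_number[genotype]

    @property
    def reference(self) -> str:
        return self._by_number[1]

    def alleles(self) -> dict[int, str]:
        return dict(self._by_number)

    # -- persistence (FASTA, header ">LOCUS_g<N>") --------------------------
    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for num in self.genotype_numbers:
                fh.write(f">{self.locus}_g{num}\n{self._by_number[num]}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlleleCatalog":
        entries: list[tuple[int, str]] = []
        locus = None
        header, chunks = None, []
        def flush():
            if header is not None:
                entries.append((header, "".join(chunks)))
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    flush()
                    name = line[1:].split()[0]
                    locus_part, _, num = name.rpartition("_g")
                    if not locus_part or not num.isdigit():
                        raise CallError(f"bad catalog header {line!r}")
                    locus = locus or locus_part
                    header, chunks = int(num), []
                else:
                    chunks.append(line)
            flush()
        if not entries:
            raise CallError(f"empty catalog file {path}")
        cat = cls(locus)
        for num, seq in sorted(entries):
            got = cat.add(seq)
            if got != num:
                raise CallError(
                    f"catalog {path}: genotype numbers not consecutive from 1 "
                    f"(saw {num}, expected {got})"
                )
        return cat


def call_allele(
    fragment: SequenceRecord,
    catalog: AlleleCatalog,
    allow_novel: bool = False,
) -> GenotypeCall:
    """Call a merged fragment against a catalog by exact string identity.

    A novel sequence gets the next genotype number when ``allow_novel`` is
    set; otherwise the call reports a miss (``genotype is None``).
    """
    seq = fragment.sequence
    if catalog.fragment_length is not None and len(seq) != catalog.fragment_length:
        raise CallError(
            f"{fragment.id}: fragment length {len(seq)} != catalog length "
            f"{catalog.fragment_length}; indel-bearing input is rejected"
        )
    hets = [i for i, c in enumerate(seq, start=1) if is_ambiguous(c)]
    if seq in catalog:
        return GenotypeCall(catalog.locus, catalog.add(seq), False, hets)
    if not allow_novel:
        return GenotypeCall(catalog.locus, None, False, hets)
    return GenotypeCall(catalog.locus, catalog.add(seq), True, hets)


@dataclass(frozen=True)
class PolymorphicSite:
    """A fragment column with at least two distinct states among alleles."""

    site: int                       # 1-based fragment position
    states: tuple[str, ...]         # distinct literal IUPAC states observed
    informative: bool               # >=2 states each carried by >=2 alleles


def find_polymorphic_sites(
    catalog: AlleleCatalog,
    weights: dict[int, int] | None = None,
) -> list[PolymorphicSite]:
    """All polymorphic fragment columns, with parsimony-informative flags.

    States compare as literal IUPAC characters (A vs R is polymorphic).
    ``weights`` maps genotype number to strain count, so informativeness can
    be judged over strains rather than over the allele list.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    nums = catalog.genotype_numbers
    seqs = [catalog.sequence(n) for n in nums]
    w = [1 if weights is None else weights.get(n, 0) for n in nums]
    out = []
    for col in range(len(seqs[0])):
        counts: Counter[str] = Counter()
        for s, wt in zip(seqs, w):
            if wt:
                counts[s[col]] += wt
        if len(counts) < 2:
            continue
        informative = sum(1 for c in counts.values() if c >= 2) >= 2
        out.append(PolymorphicSite(site=col + 1,
                                   states=tuple(sorted(counts)),
                                   informative=informative))
    return out


# Side-chain categories used to grade amino-acid replacements.
AA_CATEGORIES: dict[str, str] = {
    **{aa: "nonpolar-aliphatic" for aa in "GAVLIPM"},
    **{aa: "polar-aliphatic" for aa in "STCNQ"},
    **{aa: "aromatic" for aa in "FYW"},
    **{aa: "basic" for aa in "KRH"},
    **{aa: "acidic" for aa in "DE"},
    "*": "stop",
}


@dataclass(frozen=True)
class SiteClassification:
    site: int                # 1-based fragment position
    gene_position: int       # 1-based CDS position
    codon_index: int         # 1-based codon number within the CDS
    codon_position: int      # 1, 2 or 3 within the codon
    states: tuple[str, ...]
    kind: str                # "synonymous" | "non-synonymous" | "indeterminate"
    substantive: bool        # any replacement crosses side-chain categories
    amino_acids: tuple[str, ...] = ()


def classify_site(
    catalog: AlleleCatalog,
    site: int,
    locus: LocusDefinition,
) -> SiteClassification:
    """Classify a polymorphic site as synonymous or non-synonymous.

    The codon containing the site is read off every allele; IUPAC ambiguity
    anywhere in the codon is expanded into all compatible concrete codons.
    The site is synonymous only if every expansion encodes one amino acid,
    and substantive if any two encoded amino acids fall in different
    side-chain categories (e.g. basic vs acidic). A codon truncated at the
    fragment edge yields kind="indeterminate".
    """
    nums = catalog.genotype_numbers
    seqs = [catalog.sequence(n) for n in nums]
    col = site - 1
    states = tuple(sorted({s[col] for s in seqs}))
    if len(states) < 2:
        raise ValueError(f"site {site} is monomorphic")
    gene_position = locus.fragment_start + site - 1
    codon_index = (gene_position - 1) // 3 + 1
    codon_position = (gene_position - 1) % 3 + 1
    codon_gene_start = (codon_index - 1) * 3 + 1
    frag_lo = codon_gene_start - locus.fragment_start      # 0-based in fragment
    frag_hi = frag_lo + 3
    if frag_lo < 0 or frag_hi > len(seqs[0]):
        return SiteClassification(site, gene_position, codon_index, codon_position,
                                  states, "indeterminate", False)
    amino_acids: set[str] = set()
    for s in seqs:
        codon = s[frag_lo:frag_hi]
        for concrete in _expand_codon(codon):
            amino_acids.add(str(Seq(concrete).translate()))
    kind = "synonymous" if len(amino_acids) == 1 else "non-synonymous"
    cats = {AA_CATEGORIES[a] for a in amino_acids}
    substantive = kind == "non-synonymous" and len(cats) > 1
    return SiteClassification(site, gene_position, codon_index, codon_position,
                              states, kind, substantive,
                              tuple(sorted(amino_acids)))


def _expand_codon(codon: str) -> list[str]:
    out = [""]
    for c in codon:
        out = [p + b for p in out for b in sorted(bases(c))]
    return out
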