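"""MLST scheme definitions: loci, primers, fragment coordinates.

A scheme lists the housekeeping loci that are PCR-amplified and Sanger
sequenced for typing. Each locus carries its primer pair, amplicon size and
the 1-based inclusive coordinates of the sequenced fragment inside the coding
sequence; the frame offset derived from the start coordinate lets downstream
code place fragment positions into codons.

The packaged ``kmarxianus`` scheme covers the five loci IPP1, TFC1, GPH1,
GSY2 and SGA1 used for Kluyveromyces marxianus, together with the published
per-locus bookkeeping (genotype counts, variable-site and synonymous/
non-synonymous site counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import CONCRETE_BASES, reverse_complement, validate_sequence

__all__ = [
    "LocusDefinition",
    "MlstScheme",
    "SequenceRecord",
    "SchemeValidationError",
    "SchemeParseError",
    "PrimerTrimError",
    "SchemeWarning",
    "load_scheme",
    "trim_primer_region",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
]

PACKAGED_SCHEMES = {"kmarxianus": "kmarxianus.tsv"}


class SchemeValidationError(ValueError):
    """A scheme violates a structural invariant."""


class SchemeParseError(ValueError):
    """A scheme file row could not be parsed."""


class PrimerTrimError(ValueError):
    """Primers could not be located unambiguously in an amplicon."""


class SchemeWarning(UserWarning):
    """Non-fatal inconsistency in a scheme's published numbers."""


@dataclass(frozen=True)
class LocusDefinition:
    """One typed locus: primers, amplicon and sequenced-fragment geometry.

    Coordinates are 1-based inclusive within the gene CDS. ``frame_offset``
    is ``(fragment_start - 1) % 3``: the number of bases of the fragment's
    first codon that lie upstream of the fragment.
    """

    name: str
    gene_length: int
    fwd_primer: str
    rev_primer: str
    amplicon_size: int
    fragment_start: int
    fragment_end: int
    fragment_size: int
    n_genotypes: int | None = None
    n_variable_sites: int | None = None
    n_nonsynonymous: int | None = None
    n_synonymous: int | None = None

    @property
    def frame_offset(self) -> int:
        return (self.fragment_start - 1) % 3

    def validate(self, on_conflict: str = "error") -> list[str]:
        """Check invariants; returns warning messages.

        Coordinate and alphabet violations always raise. The primer
        arithmetic check (fragment_size = amplicon − both primers) raises
        when ``on_conflict="error"`` and warns when ``on_conflict="warn"`` —
        published schemes occasionally count one primer inside the reported
        fragment size.
        """
        msgs: list[str] = []
        for primer, label in ((self.fwd_primer, "fwd"), (self.rev_primer, "rev")):
            if not primer or set(primer) - CONCRETE_BASES:
                raise SchemeValidationError(
                    f"{self.name}: {label} primer must be non-empty A/C/G/T"
                )
        if self.fragment_size != self.fragment_end - self.fragment_start + 1:
            raise SchemeValidationError(
                f"{self.name}: fragment_size {self.fragment_size} != "
                f"end - start + 1 = {self.fragment_end - self.fragment_start + 1}"
            )
        expected = self.amplicon_size - len(self.fwd_primer) - len(self.rev_primer)
        if self.fragment_size != expected:
            msg = (
                f"{self.name}: fragment_size {self.fragment_size} != amplicon "
                f"{self.amplicon_size} - primers "
                f"({len(self.fwd_primer)}+{len(self.rev_primer)}) = {expected}"
            )
            if on_conflict == "warn":
                warnings.warn(msg, SchemeWarning, stacklevel=2)
                msgs.append(msg)
            else:
                raise SchemeValidationError(msg)
        return msgs


@dataclass(frozen=True)
class MlstScheme:
    """An ordered collection of loci; the order fixes the profile tuple order."""

    name: str
    loci: tuple[LocusDefinition, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise SchemeValidationError(f"duplicate locus names in scheme {self.name}")

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    def __iter__(self) -> Iterator[LocusDefinition]:
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def locus(self, name: str) -> LocusDefinition:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"no locus {name!r} in scheme {self.name}")

    def validate(self, on_conflict: str = "error") -> list[str]:
        msgs: list[str] = []
        for l in self.loci:
            msgs.extend(l.validate(on_conflict=on_conflict))
        return msgs


@dataclass
class SequenceRecord:
    """A named IUPAC nucleotide sequence, optionally tagged with locus/strand."""

    id: str
    sequence: str
    locus: str | None = None
    strand: str = "merged"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        self.sequence = validate_sequence(self.sequence)
        if self.strand not in ("forward", "reverse", "merged"):
            raise ValueError(f"record {self.id}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def strain(self) -> str:
        """Strain part of a ``strain|locus`` style identifier."""
        return self.id.split("|")[0]


_INT_FIELDS = (
    "gene_length", "amplicon_size", "fragment_start", "fragment_end", "fragment_size",
)
_OPT_FIELDS = ("n_genotypes", "n_variable_sites", "n_nonsynonymous", "n_synonymous")


def load_scheme(source: str | Path, on_conflict: str | None = None) -> MlstScheme:
    """Load an MLST scheme from a packaged name or a TSV file.

    Packaged schemes validate with ``on_conflict="warn"`` (their printed
    numbers are kept even where the primer arithmetic disagrees); files
    default to ``on_conflict="error"``.
    """
    source = str(source)
    if source in PACKAGED_SCHEMES:
        if on_conflict is None:
            on_conflict = "warn"
        ref = resources.files("kmlst.data") / PACKAGED_SCHEMES[source]
        with resources.as_file(ref) as path:
            return _load_scheme_tsv(path, name=source, on_conflict=on_conflict)
    return _load_scheme_tsv(Path(source), name=Path(source).stem,
                            on_conflict=on_conflict or "error")


def _load_scheme_tsv(path: Path, name: str, on_conflict: str) -> MlstScheme:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap as parse error
        raise SchemeParseError(f"cannot read scheme file {path}: {exc}") from exc
    required = ["locus", "fwd_primer", "rev_primer", *_INT_FIELDS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemeParseError(f"scheme file {path}: missing columns {missing}")
    loci = []
    for i, row in df.iterrows():
        kwargs: dict = {"name": row["locus"], "fwd_primer": str(row["fwd_primer"]).upper(),
                        "rev_primer": str(row["rev_primer"]).upper()}
        for f in _INT_FIELDS:
            try:
                kwargs[f] = int(row[f])
            except (TypeError, ValueError):
                raise SchemeParseError(
                    f"scheme file {path}, row {i + 1} ({row['locus']}): "
                    f"field {f!r} is not an integer: {row[f]!r}"
                ) from None
        for f in _OPT_FIELDS:
            if f in df.columns and pd.notna(row[f]):
                kwargs[f] = int(row[f])
        loci.append(LocusDefinition(**kwargs))
    scheme = MlstScheme(name=name, loci=tuple(loci))
    scheme.validate(on_conflict=on_conflict)
    return scheme


def _find_once(haystack: str, needle: str, label: str, max_mismatches: int) -> int:
    if max_mismatches == 0:
        hits = []
        start = haystack.find(needle)
        while start != -1:
            hits.append(start)
            start = haystack.find(needle, start + 1)
    else:
        m = len(needle)
        hits = [
            i for i in range(len(haystack) - m + 1)
            if sum(a != b for a, b in zip(haystack[i:i + m], needle)) <= max_mismatches
        ]
    if not hits:
        raise PrimerTrimError(f"{label} primer not found in amplicon")
    if len(hits) > 1:
        raise PrimerTrimError(f"{label} primer found {len(hits)} times in amplicon")
    return hits[0]


def trim_primer_region(
    amplicon: SequenceRecord,
    locus: LocusDefinition,
    max_mismatches: int = 0,
) -> SequenceRecord:
    """Cut the sequenced fragment out of an amplicon.

    The forward primer and the reverse complement of the reverse primer must
    each occur exactly once, in that order; the interior strictly between the
    two copies is returned. Primers target non-variable regions, so matching
    is exact by default.
    """
    seq = amplicon.sequence
    f = _find_once(seq, locus.fwd_primer, "forward", max_mismatches)
    r = _find_once(seq, reverse_complement(locus.rev_primer), "reverse", max_mismatches)
    interior_start = f + len(locus.fwd_primer)
    if r < interior_start:
        raise PrimerTrimError(
            "reverse primer site precedes or overlaps the forward primer"
        )
    fragment = seq[interior_start:r]
    if not fragment:
        # empty interior is legal (primers abut); bypass the non-empty check
        rec = SequenceRecord.__new__(SequenceRecord)
        rec.id, rec.sequence, rec.locus, rec.strand = (
            amplicon.id, "", locus.name, amplicon.strand)
        return rec
    return SequenceRecord(id=amplicon.id, sequence=fragment,
                          locus=locus.name, strand=amplicon.strand)


def read_fasta(path: str | Path, parse_ids: bool = True) -> list[SequenceRecord]:
    """Read a multi-FASTA file.

    With ``parse_ids`` a ``strain|locus`` record id fills the locus field.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        locus = None
        if parse_ids and "|" in rec.id:
            locus = rec.id.split("|")[1] or None
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq), locus=locus))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")
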