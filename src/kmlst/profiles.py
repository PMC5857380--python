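"""Diploid sequence types (DSTs) from five-locus genotype profiles.

A strain's profile is the ordered tuple of genotype numbers at the scheme's
loci; each unique tuple is a DST, numbered in discovery order. The packaged
fixture carries the published 83-strain K. marxianus table (66 DSTs).
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .scheme import MlstScheme

__all__ = [
    "StrainProfile",
    "DstCatalog",
    "ProfileSummary",
    "assign_dst",
    "summarize",
    "filter_by_source",
    "read_profiles",
    "write_profiles",
    "load_packaged_profiles",
    "DEFAULT_LOCI",
]

DEFAULT_LOCI: tuple[str, ...] = ("IPP1", "TFC1", "GPH1", "GSY2", "SGA1")
PACKAGED_PROFILES = "kmarxianus_profiles.tsv"


@dataclass(frozen=True)
class StrainProfile:
    strain_id: str
    genotypes: tuple[int, ...]
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.genotypes or any(g < 1 for g in self.genotypes):
            raise ValueError(
                f"{self.strain_id}: genotype numbers must be positive integers"
            )


class DstCatalog:
    """Strain profiles plus the discovery-ordered tuple → DST map."""

    def __init__(self, loci: Sequence[str] = DEFAULT_LOCI) -> None:
        self.loci = tuple(loci)
        self.profiles: list[StrainProfile] = []
        self.dst_map: "OrderedDict[tuple[int, ...], int]" = OrderedDict()

    @classmethod
    def from_profiles(
        cls,
        profiles: Iterable[StrainProfile],
        loci: Sequence[str] = DEFAULT_LOCI,
    ) -> "DstCatalog":
        cat = cls(loci)
        for p in profiles:
            cat.add(p)
        return cat

    def add(self, profile: StrainProfile) -> int:
        if len(profile.genotypes) != len(self.loci):
            raise ValueError(
                f"{profile.strain_id}: expected {len(self.loci)} genotypes, "
                f"got {len(profile.genotypes)}"
            )
        self.profiles.append(profile)
        if profile.genotypes not in self.dst_map:
            self.dst_map[profile.genotypes] = self._next_dst()
        return self.dst_map[profile.genotypes]

    def _next_dst(self) -> int:
        return max(self.dst_map.values(), default=0) + 1

    def dst_of(self, profile: StrainProfile) -> int | None:
        return self.dst_map.get(profile.genotypes)

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def n_dsts(self) -> int:
        return len(set(self.dst_map[p.genotypes] for p in self.profiles))

    def genotype_matrix(self) -> pd.DataFrame:
        """Strains × loci genotype numbers (index = strain ids)."""
        return pd.DataFrame(
            [p.genotypes for p in self.profiles],
            index=[p.strain_id for p in self.profiles],
            columns=list(self.loci),
        )

    @property
    def sources(self) -> set[str]:
        return {p.source for p in self.profiles if p.source is not None}


def assign_dst(
    profile: StrainProfile,
    catalog: DstCatalog,
    allow_novel: bool = False,
    register: bool = False,
) -> int | None:
    """DST of a profile; a novel tuple gets max+1 when ``allow_novel``.

    With ``register`` the strain row is appended to the catalog (novel
    tuples are always recorded in the DST map when accepted).
    """
    existing = catalog.dst_of(profile)
    if existing is not None:
        if register:
            catalog.profiles.append(profile)
        return existing
    if not allow_novel:
        return None
    return catalog.add(profile)


@dataclass(frozen=True)
class ProfileSummary:
    n_strains: int
    n_dsts: int
    n_singleton_strains: int
    n_multi_dsts: int
    max_dst_size: int
    genotypes_per_locus: dict[str, int] = field(default_factory=dict)


def summarize(catalog: DstCatalog) -> ProfileSummary:
    """Catalog headline counts: strains, DSTs, singleton/multi structure."""
    if not catalog.profiles:
        return ProfileSummary(0, 0, 0, 0, 0, {l: 0 for l in catalog.loci})
    dsts = [catalog.dst_map[p.genotypes] for p in catalog.profiles]
    sizes = Counter(dsts)
    per_locus = {
        locus: len({p.genotypes[j] for p in catalog.profiles})
        for j, locus in enumerate(catalog.loci)
    }
    return ProfileSummary(
        n_strains=len(catalog.profiles),
        n_dsts=len(sizes),
        n_singleton_strains=sum(1 for s in sizes.values() if s == 1),
        n_multi_dsts=sum(1 for s in sizes.values() if s >= 2),
        max_dst_size=max(sizes.values()),
        genotypes_per_locus=per_locus,
    )


def filter_by_source(catalog: DstCatalog, labels: Iterable[str]) -> DstCatalog:
    """Sub-catalog of strains whose source is in ``labels``.

    Original DST numbering is preserved: the sub-catalog keeps the parent's
    tuple → DST entries for the retained profiles.
    """
    labels = set(labels)
    unknown = labels - catalog.sources
    if unknown:
        raise KeyError(
            f"unknown source label(s) {sorted(unknown)}; "
            f"known: {sorted(catalog.sources)}"
        )
    sub = DstCatalog(catalog.loci)
    for p in catalog.profiles:
        if p.source in labels:
            sub.profiles.append(p)
            if p.genotypes not in sub.dst_map:
                sub.dst_map[p.genotypes] = catalog.dst_map[p.genotypes]
    return sub


def read_profiles(path: str | Path, loci: Sequence[str] = DEFAULT_LOCI) -> DstCatalog:
    """Read a profile TSV (columns: strain, <loci...>, source, dst optional)."""
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    missing = [c for c in ("strain", *loci) if c not in df.columns]
    if missing:
        raise ValueError(f"profile file {path}: missing columns {missing}")
    cat = DstCatalog(loci)
    for _, row in df.iterrows():
        source = row.get("source")
        cat.add(StrainProfile(
            strain_id=row["strain"],
            genotypes=tuple(int(row[l]) for l in loci),
            source=None if pd.isna(source) else str(source),
        ))
    if "dst" in df.columns:
        declared = df["dst"].astype(int).tolist()
        computed = [cat.dst_map[p.genotypes] for p in cat.profiles]
        if declared != computed:
            raise ValueError(
                f"profile file {path}: declared DST column does not match "
                "discovery-order numbering"
            )
    return cat


def write_profiles(catalog: DstCatalog, path: str | Path) -> None:
    rows = []
    for p in catalog.profiles:
        row = {"strain": p.strain_id}
        row.update(dict(zip(catalog.loci, p.genotypes)))
        row["source"] = p.source
        row["dst"] = catalog.dst_map[p.genotypes]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_packaged_profiles() -> DstCatalog:
    """The published 83-strain K. marxianus profile table."""
    ref = resources.files("kmlst.data") / PACKAGED_PROFILES
    with resources.as_file(ref) as path:
        return read_profiles(path)
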