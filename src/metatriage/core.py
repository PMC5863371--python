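"""Shared in-memory containers for the pipeline.

All coordinates held in these containers are 0-based, half-open. Writers
convert to each target format's convention (GFF3 is 1-based inclusive).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

NUCLEOTIDES = frozenset("ACGTN")

#: Ordered taxonomic ranks accepted in lineage strings, coarsest first.
RANK_ORDER = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

CONTROL = "control"
TREATMENT = "treatment"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ContigSet:
    """Assembled contigs keyed by unique id; sequences uppercase ACGTN."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for contig {cid!r}")
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise FormatError(
                    f"contig {cid!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, cid: str) -> str:
        return self.sequences[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.sequences

    def ids(self) -> list[str]:
        return list(self.sequences)


@dataclass(frozen=True)
class HitRecord:
    """One homology alignment row (BLAST tabular dialect).

    ``db_tier`` identifies the database cascade level the hit came from:
    1 = primary protein tier, 2 = fallback protein tier, 3 = nucleotide
    tier, 4 = auxiliary tier.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    evalue: float
    bitscore: float
    subject_description: str = ""
    subject_taxon: str = "unclassified"
    db_tier: int = 1

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.query_id}")
        if self.bitscore <= 0:
            raise ValueError(f"non-positive bitscore for {self.query_id}")
        if self.db_tier not in (1, 2, 3, 4):
            raise ValueError(f"db_tier must be in 1..4, got {self.db_tier}")


@dataclass(frozen=True)
class Lineage:
    """Ordered (rank, name) pairs, coarsest rank first."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("empty lineage")
        idx = []
        for rank, _name in self.pairs:
            if rank not in RANK_ORDER:
                raise ValueError(f"unknown rank {rank!r}")
            idx.append(RANK_ORDER.index(rank))
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("lineage ranks must be strictly ordered")

    def name_at(self, rank: str) -> str | None:
        for r, n in self.pairs:
            if r == rank:
                return n
        return None

    def names(self) -> tuple[str, ...]:
        return tuple(n for _r, n in self.pairs)

    def __str__(self) -> str:
        return ";".join(f"{r}:{n}" for r, n in self.pairs)

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        pairs = []
        for chunk in text.strip().split(";"):
            if not chunk:
                continue
            rank, _, name = chunk.partition(":")
            pairs.append((rank.strip(), name.strip()))
        return cls(tuple(pairs))


#: taxon_key -> Lineage
TaxonomyTable = dict[str, Lineage]

#: contig_id -> self-alignment bitscore (bits)
SelfScoreTable = dict[str, float]


@dataclass
class OperonReference:
    """Reference operon table: operon_id -> ordered gene symbols (>= 2)."""

    operons: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for oid, genes in self.operons.items():
            if len(genes) < 2:
                raise ValueError(f"operon {oid!r} has fewer than 2 genes")

    def __len__(self) -> int:
        return len(self.operons)

    def items(self):
        return self.operons.items()


@dataclass
class CountMatrix:
    """Raw counts per contig x sample plus a condition label per sample."""

    counts: pd.DataFrame  # rows: contig ids, cols: sample ids, int
    conditions: dict[str, str]  # sample id -> control | treatment

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        bad = set(self.conditions.values()) - {CONTROL, TREATMENT}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def contig_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def subset(self, contig_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(contig_ids)].copy(), dict(self.conditions))
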