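"""Core domain types shared across the pipeline.

All genomic and residue coordinates are 1-based inclusive throughout the
package (the native GFF3 convention); nothing converts to half-open
intervals internally, so there is a single coordinate system to reason
about from parsing to reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class RlkfamError(Exception):
    """Base class for all package errors."""


class ParseError(RlkfamError):
    """A file violated its format or a record violated a type invariant."""


class ConfigError(RlkfamError):
    """Invalid configuration (bad threshold, missing file, unknown mode)."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with a unique identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("protein record with empty id")
        if len(self.sequence) < 1:
            raise ParseError(f"empty sequence for protein {self.id!r}")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_AA
        if bad:
            raise ParseError(
                f"invalid residue(s) {sorted(bad)} in protein {self.id!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene with its exon chain on a chromosome or scaffold.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted by start,
    non-overlapping and contained in [start, end].
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ParseError(
                f"gene {self.gene_id!r}: invalid span {self.start}-{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ParseError(f"gene {self.gene_id!r}: strand must be + or -")
        prev_end = None
        for (s, e) in self.exons:
            if s > e:
                raise ParseError(f"gene {self.gene_id!r}: exon {s}-{e} inverted")
            if s < self.start or e > self.end:
                raise ParseError(
                    f"gene {self.gene_id!r}: exon {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise ParseError(
                    f"gene {self.gene_id!r}: exons overlap or unsorted at {s}"
                )
            prev_end = e

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


DOMAIN_CATEGORIES = ("LRR", "kinase", "malectin", "other")


@dataclass(frozen=True)
class DomainHit:
    """One domain-evidence row for a protein (hmmscan-style)."""

    protein_id: str
    domain_name: str
    category: str
    env_start: int
    env_end: int
    score: float = 0.0
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in DOMAIN_CATEGORIES:
            raise ParseError(f"unknown domain category {self.category!r}")
        if not (1 <= self.env_start <= self.env_end):
            raise ParseError(
                f"{self.protein_id}/{self.domain_name}: bad envelope "
                f"{self.env_start}-{self.env_end}"
            )
        if self.evalue < 0:
            raise ParseError(f"{self.protein_id}: negative E-value")


@dataclass(frozen=True)
class TMCall:
    """A predicted transmembrane segment (1-based residue coordinates)."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ParseError(
                f"{self.protein_id}: bad TM segment {self.start}-{self.end}"
            )


@dataclass(frozen=True)
class SPCall:
    """A predicted signal peptide; always anchored at residue 1."""

    protein_id: str
    start: int
    end: int
    cleavage: int

    def __post_init__(self) -> None:
        if self.start != 1:
            raise ParseError(f"{self.protein_id}: signal peptide must start at 1")
        if self.end < self.start:
            raise ParseError(f"{self.protein_id}: bad SP segment")


@dataclass(frozen=True)
class SimilarityHit:
    """A local-alignment hit between a query and a subject protein."""

    query_id: str
    subject_id: str
    score: float  # bits
    evalue: float
    q_start: int = 1
    q_end: int = 1
    s_start: int = 1
    s_end: int = 1
    pident: float = 100.0
    length: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ParseError(
                f"{self.query_id}->{self.subject_id}: negative E-value"
            )
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ParseError(
                f"{self.query_id}->{self.subject_id}: inverted interval"
            )


@dataclass
class MembershipDecision:
    """Outcome of the three-evidence family membership rule.

    A protein is a family member iff it has at least one LRR-category
    domain hit, a kinase-category hit, and at least one transmembrane
    segment. ``reasons`` names each failed criterion.
    """

    protein_id: str
    n_lrr: int
    has_kinase: bool
    n_tm: int
    is_member: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = self.n_lrr >= 1 and self.has_kinase and self.n_tm >= 1
        if self.is_member != expected:
            raise RlkfamError(
                f"{self.protein_id}: inconsistent membership decision"
            )


@dataclass
class GenePlacement:
    """A gene's position in whole-annotation rank order on its sequence."""

    gene_id: str
    seq_id: str
    rank: int
    start: int
    end: int
    is_family: bool
    subgenome: Optional[str] = None


@dataclass
class TDEvent:
    """A maximal cluster of tandemly duplicated family genes."""

    event_id: str
    seq_id: str
    gene_ids: list[str]
    span_bp: int

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise RlkfamError(f"{self.event_id}: a TDE needs >= 2 genes")


@dataclass
class SubcladeAssignment:
    """Phylogenetic subclade label for one query leaf."""

    query_id: str
    label: str
    support: float
    nearest_reference: Optional[str] = None
    nearest_distance: float = float("nan")


def index_by_protein(rows: Sequence) -> dict[str, list]:
    """Group evidence rows by ``protein_id``."""
    out: dict[str, list] = {}
    for r in rows:
        out.setdefault(r.protein_id, []).append(r)
    return out
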