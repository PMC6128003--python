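"""Chromosomal distribution, tandem-duplication calling, gene structure.

The tandem-duplication rule works on whole-annotation gene rank order per
chromosome/scaffold: two family genes are tandemly linked if at most one
gene of any kind lies between them, or if exactly two genes lie between
them and the genomic gap (end of the upstream gene to start of the
downstream one) is at most 1 Mb. A tandem duplication event (TDE) is a
maximal connected cluster of linked family genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import GeneModel, GenePlacement, RlkfamError, TDEvent

#: seq_id -> subgenome classing rules (regex, class); first match wins.
DEFAULT_SUBGENOME_PATTERNS: list[tuple[str, str]] = [
    (r"^A\d+", "A"),
    (r"^D\d+", "D"),
    (r"(?i)^scaffold", "scaffold"),
]


def classify_subgenome(
    seq_id: str, patterns: Optional[Sequence[tuple[str, str]]] = None
) -> Optional[str]:
    for pattern, cls in patterns or DEFAULT_SUBGENOME_PATTERNS:
        if re.match(pattern, seq_id):
            return cls
    return None


def place_genes(
    gene_models: Sequence[GeneModel],
    member_ids: Iterable[str],
    subgenome_patterns: Optional[Sequence[tuple[str, str]]] = None,
) -> list[GenePlacement]:
    """Rank every gene along its sequence and flag family members.

    Ranks are 0-based start-order indices among ALL genes on a seq_id
    (ties broken by end, then id, so placement is deterministic).
    """
    members = set(member_ids)
    placements: list[GenePlacement] = []
    by_seq: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_seq.setdefault(g.seq_id, []).append(g)
    for seq_id in sorted(by_seq):
        genes = sorted(by_seq[seq_id], key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(genes):
            placements.append(
                GenePlacement(
                    gene_id=g.gene_id,
                    seq_id=seq_id,
                    rank=rank,
                    start=g.start,
                    end=g.end,
                    is_family=g.gene_id in members
                    or (g.protein_id is not None and g.protein_id in members),
                    subgenome=classify_subgenome(seq_id, subgenome_patterns),
                )
            )
    return placements


def distribution_table(placements: Sequence[GenePlacement]) -> pd.DataFrame:
    """Family-gene counts per seq_id with the subgenome class attached."""
    rows = {}
    for p in placements:
        key = p.seq_id
        if key not in rows:
            rows[key] = {"seq_id": key, "subgenome": p.subgenome, "n_family": 0}
        if p.is_family:
            rows[key]["n_family"] += 1
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["seq_id"]))


def subgenome_counts(placements: Sequence[GenePlacement]) -> dict[str, int]:
    """Family-gene totals grouped by subgenome class (A / D / scaffold)."""
    out: dict[str, int] = {}
    for p in placements:
        if p.is_family:
            key = p.subgenome or "unclassified"
            out[key] = out.get(key, 0) + 1
    return out


MAX_INTERRUPTION = 1          # genes of any kind between a tandem pair
EXTENDED_INTERRUPTION = 2     # allowed if within the distance window
DISTANCE_WINDOW_BP = 1_000_000


def _linked(a: GenePlacement, b: GenePlacement, window_bp: int) -> bool:
    """Tandem link between two family genes on one seq (a upstream of b)."""
    between = b.rank - a.rank - 1
    if between <= MAX_INTERRUPTION:
        return True
    if between == EXTENDED_INTERRUPTION and (b.start - a.end) <= window_bp:
        return True
    return False


def call_tandem_duplications(
    placements: Sequence[GenePlacement],
    window_bp: int = DISTANCE_WINDOW_BP,
) -> list[TDEvent]:
    """Maximal clusters of tandemly linked family genes.

    Placements must cover ALL annotated genes (family and not) so rank
    gaps count interruptions correctly; a seq_id whose ranks are not a
    permutation of 0..n-1 is rejected as a mix of rank systems. Chains are
    merged transitively: consecutive family genes in rank order are tested
    pairwise and linked runs become one event.
    """
    by_seq: dict[str, list[GenePlacement]] = {}
    for p in placements:
        by_seq.setdefault(p.seq_id, []).append(p)

    events: list[TDEvent] = []
    for seq_id in sorted(by_seq):
        group = sorted(by_seq[seq_id], key=lambda p: p.rank)
        ranks = [p.rank for p in group]
        if ranks != list(range(len(group))):
            raise RlkfamError(
                f"{seq_id}: ranks are not a permutation of 0..n-1 "
                "(placements from mixed rank systems?)"
            )
        fam = [p for p in group if p.is_family]
        cluster: list[GenePlacement] = []
        n_on_seq = 0

        def flush() -> None:
            nonlocal cluster, n_on_seq
            if len(cluster) >= 2:
                n_on_seq += 1
                events.append(
                    TDEvent(
                        event_id=f"{seq_id}:TDE{n_on_seq}",
                        seq_id=seq_id,
                        gene_ids=[p.gene_id for p in cluster],
                        span_bp=cluster[-1].end - cluster[0].start + 1,
                    )
                )
            cluster = []

        for p in fam:
            if cluster and _linked(cluster[-1], p, window_bp):
                cluster.append(p)
            else:
                flush()
                cluster = [p]
        flush()
    return events


def tde_summary(events: Sequence[TDEvent]) -> dict[str, int]:
    genes = [g for e in events for g in e.gene_ids]
    if len(genes) != len(set(genes)):
        raise RlkfamError("a gene appears in more than one TDE")
    return {"n_events": len(events), "n_genes": len(genes)}


@dataclass
class GeneStructure:
    gene_id: str
    n_exons: int
    exon_lengths: list[int]
    intron_lengths: list[int]
    cds_span_bp: int


def exon_structure(gene_models: Sequence[GeneModel]) -> list[GeneStructure]:
    """Exon/intron lengths per gene (1-based inclusive arithmetic)."""
    out: list[GeneStructure] = []
    for g in gene_models:
        exon_lengths = [e - s + 1 for s, e in g.exons]
        intron_lengths = [
            g.exons[k + 1][0] - g.exons[k][1] - 1 for k in range(len(g.exons) - 1)
        ]
        span = (g.exons[-1][1] - g.exons[0][0] + 1) if g.exons else 0
        out.append(
            GeneStructure(
                gene_id=g.gene_id,
                n_exons=len(g.exons),
                exon_lengths=exon_lengths,
                intron_lengths=intron_lengths,
                cds_span_bp=span,
            )
        )
    return out


def structure_by_subclade(
    structures: Sequence[GeneStructure], subclade_of: dict[str, str]
) -> pd.DataFrame:
    """Mean exon count and span aggregated per subclade."""
    rows = []
    for s in structures:
        sub = subclade_of.get(s.gene_id)
        if sub is not None:
            rows.append({"subclade": sub, "n_exons": s.n_exons, "span": s.cds_span_bp})
    if not rows:
        return pd.DataFrame(columns=["subclade", "mean_exons", "mean_span", "n_genes"])
    df = pd.DataFrame(rows)
    agg = df.groupby("subclade").agg(
        mean_exons=("n_exons", "mean"),
        mean_span=("span", "mean"),
        n_genes=("n_exons", "size"),
    )
    return agg.reset_index()
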