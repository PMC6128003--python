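"""Candidate discovery by protein similarity and the membership rule.

The screen mirrors a BLASTP-based workflow: reference family proteins are
compared against a target proteome, subjects hit below an E-value cutoff
(default 1e-10) become candidates, and candidates pass to a three-evidence
classification — at least one LRR repeat, a kinase domain and a
transmembrane helix are all required for family membership.

The built-in search is a k-mer-seeded Smith–Waterman: pairs sharing at
least one exact 3-mer are aligned locally with BLOSUM62 and affine gaps
(open 11, extend 1, i.e. a gap of length L costs 11 + L), and raw scores
are converted to E-values with the Karlin–Altschul formula
``E = K * m * n * exp(-lambda * S)`` using the standard gapped constants
lambda = 0.267, K = 0.041. Precomputed BLAST tabular hits can be supplied
instead via :func:`rlkfam.io_formats.read_similarity_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .types import (
    DomainHit,
    MembershipDecision,
    ProteinRecord,
    RlkfamError,
    SimilarityHit,
    TMCall,
    index_by_protein,
)


@dataclass
class SearchParams:
    """Tunables for the internal similarity search."""

    k: int = 3                   # seed word size
    gap_open: float = 11.0       # BLAST-style: gap of length L costs open + L*extend
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267  # gapped BLOSUM62 defaults
    karlin_k: float = 0.041
    matrix: str = "BLOSUM62"
    exclude_self: bool = True


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # PairwiseAligner charges open_gap_score on the first gap residue, so a
    # BLAST-style 11/1 scheme maps to open -(11+1), extend -1.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def karlin_altschul_evalue(score: float, m: int, n: int, params: SearchParams) -> float:
    """E-value of a raw local-alignment score over an m x n search space."""
    return params.karlin_k * m * n * math.exp(-params.karlin_lambda * score)


def bit_score(score: float, params: SearchParams) -> float:
    return (params.karlin_lambda * score - math.log(params.karlin_k)) / math.log(2)


def similarity_search(
    queries: Sequence[ProteinRecord],
    subjects: Sequence[ProteinRecord],
    params: Optional[SearchParams] = None,
) -> list[SimilarityHit]:
    """All-vs-all seeded Smith–Waterman search, best hit per pair.

    Pairs sharing no exact k-mer are never aligned (the seeding
    heuristic); for seeded pairs the reported score is the exhaustive
    local-alignment optimum. The search space for the E-value is
    m = query length, n = total subject length.
    """
    if not queries or not subjects:
        raise RlkfamError("similarity_search requires non-empty query and subject sets")
    params = params or SearchParams()
    aligner = _make_aligner(params)

    subject_kmers = {s.id: _kmers(s.sequence, params.k) for s in subjects}
    for rec in list(queries) + list(subjects):
        if len(rec.sequence) < params.k:
            raise RlkfamError(
                f"sequence {rec.id!r} shorter than the seed size k={params.k}"
            )
    total_n = sum(len(s) for s in subjects)

    hits: list[SimilarityHit] = []
    for q in queries:
        q_kmers = _kmers(q.sequence, params.k)
        for s in subjects:
            if params.exclude_self and q.id == s.id:
                continue
            if not (q_kmers & subject_kmers[s.id]):
                continue  # unseeded pair: heuristic reports nothing
            aln = aligner.align(q.sequence, s.sequence)
            score = float(aln.score)
            if score <= 0:
                continue
            best = aln[0]
            qblocks, sblocks = best.aligned
            q_start, q_end = int(qblocks[0][0]) + 1, int(qblocks[-1][1])
            s_start, s_end = int(sblocks[0][0]) + 1, int(sblocks[-1][1])
            ident = 0
            length = 0
            for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
                length += qb - qa
                ident += sum(
                    1 for a, b in zip(q.sequence[qa:qb], s.sequence[sa:sb]) if a == b
                )
            hits.append(
                SimilarityHit(
                    query_id=q.id,
                    subject_id=s.id,
                    score=bit_score(score, params),
                    evalue=karlin_altschul_evalue(score, len(q), total_n, params),
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    pident=100.0 * ident / length if length else 0.0,
                    length=length,
                )
            )
    return hits


def screen_candidates(
    hits: Iterable[SimilarityHit],
    e_max: float = 1e-10,
    direction: str = "subject",
) -> set[str]:
    """Unique ids with any hit at E-value <= *e_max*.

    ``direction='subject'`` collects subject ids (reference proteins were
    the queries); ``'query'`` flips it.
    """
    if direction not in {"subject", "query"}:
        raise RlkfamError(f"unknown screen direction {direction!r}")
    out: set[str] = set()
    for h in hits:
        if h.evalue <= e_max:
            out.add(h.subject_id if direction == "subject" else h.query_id)
    return out


def classify_membership(
    protein_id: str,
    domain_hits: Sequence[DomainHit],
    tm_calls: Sequence[TMCall],
) -> MembershipDecision:
    """Apply the three-evidence membership rule to one protein.

    Member iff: >= 1 LRR-category domain hit AND >= 1 kinase-category hit
    AND >= 1 transmembrane segment.
    """
    mine_dom = [h for h in domain_hits if h.protein_id == protein_id]
    mine_tm = [t for t in tm_calls if t.protein_id == protein_id]
    n_lrr = sum(1 for h in mine_dom if h.category == "LRR")
    has_kinase = any(h.category == "kinase" for h in mine_dom)
    n_tm = len(mine_tm)
    reasons = []
    if n_lrr < 1:
        reasons.append("LRR")
    if not has_kinase:
        reasons.append("kinase")
    if n_tm < 1:
        reasons.append("TM")
    return MembershipDecision(
        protein_id=protein_id,
        n_lrr=n_lrr,
        has_kinase=has_kinase,
        n_tm=n_tm,
        is_member=not reasons,
        reasons=reasons,
    )


def classify_all(
    candidate_ids: Iterable[str],
    domain_hits: Sequence[DomainHit],
    tm_calls: Sequence[TMCall],
) -> list[MembershipDecision]:
    """Membership decisions for a whole candidate set (evidence pre-indexed)."""
    dom_idx = index_by_protein(domain_hits)
    tm_idx = index_by_protein(tm_calls)
    return [
        classify_membership(pid, dom_idx.get(pid, []), tm_idx.get(pid, []))
        for pid in sorted(candidate_ids)
    ]
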