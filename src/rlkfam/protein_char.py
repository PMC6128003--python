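"""Physicochemical properties, motif scans and architecture summaries.

Molecular weights use average isotopic residue masses (the convention of
the ExPASy Compute pI/Mw tool); the isoelectric point solves net charge =
0 by bisection with the Bjellqvist pKa set. The extracellular LRR
consensus scan implements the 24-residue pattern
``L--L--L--L-L--N-L--G-IP-`` in which each ``L`` position admits Leu or
Ile, position 15 is Asn, 20 is Gly, 22 is Val or Ile, and 23 is Pro.
A Kyte–Doolittle hydropathy scan provides transmembrane-segment calls
when no external TM prediction table is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .types import (
    DomainHit,
    ProteinRecord,
    RlkfamError,
    SPCall,
    SubcladeAssignment,
    TMCall,
)

WATER_DA = 18.0153

#: average residue masses (free amino-acid mass minus one water)
_RESIDUE_MASS = {aa: w - WATER_DA for aa, w in protein_weights.items()}
_RESIDUE_MASS["X"] = sum(_RESIDUE_MASS[a] for a in "ACDEFGHIKLMNPQRSTVWY") / 20.0


def molecular_weight(sequence: str) -> float:
    """Average-isotopic molecular weight in Da (sum of residues + water)."""
    if not sequence:
        raise RlkfamError("cannot compute molecular weight of an empty sequence")
    try:
        return sum(_RESIDUE_MASS[a] for a in sequence.upper()) + WATER_DA
    except KeyError as exc:
        raise RlkfamError(f"invalid residue {exc} in sequence") from exc


# Bjellqvist pKa values as used by ExPASy; swappable because the exact set
# behind any given server run is configuration, not ground truth.
BJELLQVIST = {
    "n_term_default": 7.5,
    "n_term": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7},
    "c_term_default": 3.55,
    "c_term": {"D": 4.55, "E": 4.75},
    "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
}


def net_charge(sequence: str, ph: float, pka: dict = BJELLQVIST) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH."""
    seq = sequence.upper()
    pos = [pka["n_term"].get(seq[0], pka["n_term_default"])]
    pos += [pka["positive"][a] for a in seq if a in pka["positive"]]
    neg = [pka["c_term"].get(seq[-1], pka["c_term_default"])]
    neg += [pka["negative"][a] for a in seq if a in pka["negative"]]
    charge = sum(1.0 / (1.0 + 10 ** (ph - p)) for p in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (p - ph)) for p in neg)
    return charge


def isoelectric_point(sequence: str, pka: dict = BJELLQVIST, tol: float = 0.001) -> float:
    """pH of zero net charge, by bisection on [0, 14] to *tol* pH units."""
    if not sequence:
        raise RlkfamError("cannot compute pI of an empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# LRR consensus scan

LRR_CONSENSUS_LEN = 24
# 1-based position -> allowed residues within the 24-residue window
_LRR_RULES = {
    1: "LI", 4: "LI", 7: "LI", 10: "LI", 12: "LI", 17: "LI",
    15: "N", 20: "G", 22: "VI", 23: "P",
}


def scan_lrr_consensus(sequence: str) -> list[int]:
    """1-based start positions of every (possibly overlapping) window
    matching the LRR consensus."""
    seq = sequence.upper()
    matches = []
    for start in range(len(seq) - LRR_CONSENSUS_LEN + 1):
        window = seq[start:start + LRR_CONSENSUS_LEN]
        if all(window[pos - 1] in allowed for pos, allowed in _LRR_RULES.items()):
            matches.append(start + 1)
    return matches


# ---------------------------------------------------------------------------
# Hydropathy TM fallback

def hydropathy_tm_scan(
    sequence: str, window: int = 19, cutoff: float = 1.6, protein_id: str = ""
) -> list[TMCall]:
    """Kyte–Doolittle sliding-window transmembrane scan.

    The residue spans of windows whose mean hydropathy is >= *cutoff* are
    merged into maximal segments by interval union (1-based, inclusive).
    A fallback for when no external TM prediction table is supplied.
    """
    seq = sequence.upper()
    if len(seq) < window:
        return []
    scores = [KYTE_DOOLITTLE.get(a, 0.0) for a in seq]
    spans: list[list[int]] = []  # union of residue spans of qualifying windows
    for i in range(len(seq) - window + 1):
        if sum(scores[i:i + window]) / window >= cutoff:
            start, end = i + 1, i + window
            if spans and start <= spans[-1][1] + 1:
                spans[-1][1] = end
            else:
                spans.append([start, end])
    return [TMCall(protein_id, s, e) for s, e in spans]


# ---------------------------------------------------------------------------
# Architecture and summaries

ARCH_TOKENS = ("SP", "Malectin", "LRR", "TM", "KD")


def architecture_string(
    protein_id: str,
    domain_hits: Sequence[DomainHit],
    tm_calls: Sequence[TMCall],
    sp_calls: Sequence[SPCall] = (),
) -> list[str]:
    """Ordered domain-architecture tokens for one protein.

    Evidence segments are sorted by start coordinate and mapped to tokens
    (SP, Malectin, LRR, TM, KD); consecutive repeats of the same token
    (e.g. an LRR array) collapse to one.
    """
    segments: list[tuple[int, str]] = []
    for sp in sp_calls:
        if sp.protein_id == protein_id:
            segments.append((sp.start, "SP"))
    for h in domain_hits:
        if h.protein_id != protein_id:
            continue
        token = {"LRR": "LRR", "kinase": "KD", "malectin": "Malectin"}.get(h.category)
        if token:
            segments.append((h.env_start, token))
    for tm in tm_calls:
        if tm.protein_id == protein_id:
            segments.append((tm.start, "TM"))
    segments.sort()
    tokens: list[str] = []
    for _, tok in segments:
        if not tokens or tokens[-1] != tok:
            tokens.append(tok)
    return tokens


def malectin_is_n_terminal(
    protein_id: str, domain_hits: Sequence[DomainHit]
) -> Optional[bool]:
    """True if the malectin-like domain precedes the first LRR; None if
    the protein has no malectin hit."""
    mine = [h for h in domain_hits if h.protein_id == protein_id]
    mal = [h.env_start for h in mine if h.category == "malectin"]
    if not mal:
        return None
    lrr = [h.env_start for h in mine if h.category == "LRR"]
    return min(mal) < min(lrr) if lrr else True


@dataclass
class ProteinProperties:
    protein_id: str
    length: int
    mol_weight_da: float
    pi: float
    n_lrr_domains: int       # LRR-category evidence hits
    n_lrr_consensus: int     # consensus-scan matches (alternate counter)
    architecture: list[str]


def compute_properties(
    record: ProteinRecord,
    domain_hits: Sequence[DomainHit] = (),
    tm_calls: Sequence[TMCall] = (),
    sp_calls: Sequence[SPCall] = (),
) -> ProteinProperties:
    mine = [h for h in domain_hits if h.protein_id == record.id]
    return ProteinProperties(
        protein_id=record.id,
        length=len(record),
        mol_weight_da=molecular_weight(record.sequence),
        pi=isoelectric_point(record.sequence),
        n_lrr_domains=sum(1 for h in mine if h.category == "LRR"),
        n_lrr_consensus=len(scan_lrr_consensus(record.sequence)),
        architecture=architecture_string(record.id, domain_hits, tm_calls, sp_calls),
    )


def properties_table(props: Sequence[ProteinProperties]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": p.protein_id,
                "length_aa": p.length,
                "mol_weight_kda": p.mol_weight_da / 1000.0,
                "pI": p.pi,
                "n_lrr": p.n_lrr_domains,
                "n_lrr_consensus": p.n_lrr_consensus,
                "architecture": "-".join(p.architecture),
            }
            for p in props
        ]
    )


def summarize_subclades(
    assignments: Sequence[SubcladeAssignment],
    props: Sequence[ProteinProperties],
    gene_span_bp: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Per-subclade molecular-property ranges (gene kb, aa, pI, kDa, LRRs)."""
    by_id = {p.protein_id: p for p in props}
    rows = []
    for a in assignments:
        p = by_id.get(a.query_id)
        if p is None:
            continue
        rows.append(
            {
                "subclade": a.label,
                "gene_kb": (gene_span_bp or {}).get(a.query_id, float("nan")) / 1000.0,
                "aa": p.length,
                "pI": p.pi,
                "kda": p.mol_weight_da / 1000.0,
                "n_lrr": p.n_lrr_domains,
            }
        )
    if not rows:
        raise RlkfamError("no overlap between assignments and properties")
    df = pd.DataFrame(rows)
    agg = df.groupby("subclade").agg(
        n_genes=("aa", "size"),
        gene_kb_min=("gene_kb", "min"), gene_kb_max=("gene_kb", "max"),
        aa_min=("aa", "min"), aa_max=("aa", "max"),
        pI_min=("pI", "min"), pI_max=("pI", "max"),
        kda_min=("kda", "min"), kda_max=("kda", "max"),
        lrr_min=("n_lrr", "min"), lrr_max=("n_lrr", "max"),
    )
    return agg.reset_index()
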