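"""Readers and writers for every external format the pipeline touches.

Supported formats: FASTA, GFF3, HMMER3 domtblout, a generic header-bearing
TSV dialect for domain/TM/SP evidence, BLAST tabular (outfmt 6), Newick,
and TSV count matrices. Parsing is strict: a record that violates its type
invariant raises :class:`~rlkfam.types.ParseError` immediately rather than
propagating a silently wrong coordinate downstream.

Coordinates are 1-based inclusive everywhere (GFF3-native).
"""

from __future__ import annotations

import io
import os
import re
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SearchIO, SeqIO

from .types import (
    DomainHit,
    GeneModel,
    ParseError,
    ProteinRecord,
    SimilarityHit,
    SPCall,
    TMCall,
)

# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> list[ProteinRecord]:
    """Parse a protein FASTA file into :class:`ProteinRecord` objects.

    Wrapped sequence lines are concatenated; input order is preserved.
    Duplicate identifiers, empty sequences and non-amino-acid symbols are
    parse errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from a GFF3 file into gene models.

    Exons are attached to their gene through the mRNA Parent chain.
    Coordinates stay 1-based inclusive. An exon outside its gene's span or
    an mRNA/exon with an unknown Parent is a parse error.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # sqlite/attribute-level failures
        raise ParseError(f"cannot parse GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    gene_ids = {g.id for g in db.features_of_type("gene")}

    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        for p in parents:
            if p not in gene_ids:
                raise ParseError(f"mRNA {mrna.id!r} has orphan Parent {p!r}")
    for exon in db.features_of_type("exon"):
        for p in exon.attributes.get("Parent", []):
            if db[p] is None:  # pragma: no cover - gffutils raises first
                raise ParseError(f"exon has orphan Parent {p!r}")

    for g in db.features_of_type("gene", order_by="start"):
        exons: list[tuple[int, int]] = []
        protein_id: Optional[str] = None
        for mrna in db.children(g, featuretype="mRNA"):
            pid = mrna.attributes.get("protein_id", [None])[0]
            protein_id = protein_id or pid or mrna.id
            for exon in db.children(mrna, featuretype="exon", order_by="start"):
                exons.append((exon.start, exon.end))
        # single-exon genes may carry exons directly under the gene
        if not exons:
            for exon in db.children(g, featuretype="exon", order_by="start"):
                exons.append((exon.start, exon.end))
        exons.sort()
        genes.append(
            GeneModel(
                gene_id=g.id,
                seq_id=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=exons,
                protein_id=protein_id,
            )
        )
    if not genes:
        raise ParseError(f"no gene features in {path}")
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene models as a minimal gene/mRNA/exon GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.seq_id, x.start, x.end, x.gene_id)):
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.seq_id}\trlkfam\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            mattrs = f"ID={mrna_id};Parent={g.gene_id}"
            if g.protein_id:
                mattrs += f";protein_id={g.protein_id}"
            fh.write(
                f"{g.seq_id}\trlkfam\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{mattrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.seq_id}\trlkfam\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# Domain evidence (hmmscan domtblout / generic TSV)

#: Default rules mapping HMM profile names to the categories the membership
#: rule consumes. The source data never pins exact profile names, so the
#: mapping is configuration, not hard-coded truth.
DEFAULT_CATEGORY_RULES: list[tuple[str, str]] = [
    (r"^LRR", "LRR"),
    (r"^Pkinase", "kinase"),
    (r"^PK_Tyr_Ser-Thr", "kinase"),
    (r"^Malectin", "malectin"),
]


def categorize_domain(name: str, rules: Optional[Sequence[tuple[str, str]]] = None) -> str:
    for pattern, category in rules or DEFAULT_CATEGORY_RULES:
        if re.match(pattern, name):
            return category
    return "other"


def read_domain_table(
    path: str,
    dialect: str = "domtblout",
    category_rules: Optional[Sequence[tuple[str, str]]] = None,
) -> list[DomainHit]:
    """Read per-domain evidence in either HMMER3 domtblout or TSV dialect.

    domtblout rows map target name -> domain_name, query name ->
    protein_id, the full-sequence E-value -> evalue, and the *env*
    coordinates (the domain envelope) -> env_start/env_end. The TSV
    dialect expects a header with columns
    ``protein_id  domain_name  env_start  env_end  evalue`` (``score``
    optional).
    """
    hits: list[DomainHit] = []
    if dialect == "domtblout":
        try:
            results = list(SearchIO.parse(path, "hmmscan3-domtab"))
        except Exception as exc:
            raise ParseError(f"cannot parse domtblout {path}: {exc}") from exc
        for qresult in results:
            for hit in qresult:
                for hsp in hit.hsps:
                    hits.append(
                        DomainHit(
                            protein_id=qresult.id,
                            domain_name=hit.id,
                            category=categorize_domain(hit.id, category_rules),
                            env_start=hsp.env_start + 1,  # SearchIO is 0-based
                            env_end=hsp.env_end,
                            score=float(hsp.bitscore),
                            evalue=float(hit.evalue),
                        )
                    )
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"protein_id", "domain_name", "env_start", "env_end", "evalue"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing TSV columns {sorted(missing)}")
        for row in df.itertuples(index=False):
            hits.append(
                DomainHit(
                    protein_id=str(row.protein_id),
                    domain_name=str(row.domain_name),
                    category=categorize_domain(str(row.domain_name), category_rules),
                    env_start=int(row.env_start),
                    env_end=int(row.env_end),
                    score=float(getattr(row, "score", 0.0)),
                    evalue=float(row.evalue),
                )
            )
    else:
        raise ParseError(f"unknown domain-table dialect {dialect!r}")
    return hits


def write_domtblout(hits: Sequence[DomainHit], path: str) -> None:
    """Write domain hits in the HMMER3 domtblout column layout."""
    with open(path, "w") as fh:
        fh.write("# target name accession tlen query name accession qlen "
                 "E-value score bias # of c-Evalue i-Evalue score bias "
                 "hmm_from hmm_to ali_from ali_to env_from env_to acc "
                 "description\n".replace(" ", "\t"))
        by_protein: dict[str, list[DomainHit]] = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        for pid in sorted(by_protein):
            rows = sorted(by_protein[pid], key=lambda h: (h.env_start, h.domain_name))
            n = len(rows)
            for i, h in enumerate(rows, 1):
                span = h.env_end - h.env_start + 1
                fh.write(
                    f"{h.domain_name:<20} -            {span:5d} {pid:<20} -     "
                    f"    0 {h.evalue:9.2g} {h.score:6.1f}   0.0 {i:3d} {n:3d} "
                    f"{h.evalue:9.2g} {h.evalue:9.2g} {h.score:6.1f}   0.0 "
                    f"    1 {span:5d} {h.env_start:5d} {h.env_end:5d} "
                    f"{h.env_start:5d} {h.env_end:5d} 0.99 {h.category} domain\n"
                )


def read_tm_table(path: str) -> list[TMCall]:
    """TSV with header ``protein_id  start  end`` -> TM segments."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "start", "end"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing TM columns {sorted(missing)}")
    return [
        TMCall(str(r.protein_id), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def read_sp_table(path: str) -> list[SPCall]:
    """TSV with header ``protein_id  start  end  cleavage`` -> signal peptides."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "start", "end", "cleavage"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing SP columns {sorted(missing)}")
    return [
        SPCall(str(r.protein_id), int(r.start), int(r.end), int(r.cleavage))
        for r in df.itertuples(index=False)
    ]


def write_tm_table(calls: Sequence[TMCall], path: str) -> None:
    pd.DataFrame(
        [(c.protein_id, c.start, c.end) for c in calls],
        columns=["protein_id", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def write_sp_table(calls: Sequence[SPCall], path: str) -> None:
    pd.DataFrame(
        [(c.protein_id, c.start, c.end, c.cleavage) for c in calls],
        columns=["protein_id", "start", "end", "cleavage"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_similarity_table(path: str) -> list[SimilarityHit]:
    """Read BLAST tabular (outfmt 6, 12 standard columns) similarity hits."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hits.append(
                    SimilarityHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pident=float(fields[2]),
                        length=int(fields[3]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_similarity_table(hits: Sequence[SimilarityHit], path: str) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.2f}\t{h.length}\t0\t0\t"
                f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.evalue:.3g}\t{h.score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Newick (delegates to the tree container, which wraps dendropy)

def write_newick(tree, path: Optional[str] = None) -> str:
    """Serialize a :class:`~rlkfam.phylo.PhyloTree` to Newick text.

    Branch lengths are emitted; integer bootstrap supports appear as
    internal-node labels. If *path* is given the text is also written there.
    """
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_newick(source: str):
    """Parse Newick text (or a path to it) into a PhyloTree."""
    from .phylo import PhyloTree

    if os.path.exists(source):
        with open(source) as fh:
            source = fh.read()
    return PhyloTree.from_newick(source)


# ---------------------------------------------------------------------------
# Count matrices

def read_counts(path: str) -> pd.DataFrame:
    """Read a genes x samples TSV of raw counts.

    Gene ids must be unique; every value must be a non-negative integer.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene rows {dupes}")
    arr = df.to_numpy()
    if arr.size == 0:
        raise ParseError(f"{path}: empty count matrix")
    if not ((arr == arr.astype(int)).all() and (arr >= 0).all()):
        raise ParseError(f"{path}: counts must be non-negative integers")
    return df.astype(int)


def write_counts(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")
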