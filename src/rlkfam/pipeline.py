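"""Pipeline orchestration and report assembly.

``run_all`` drives every stage on a directory of input files and writes a
deterministic bundle of TSV reports: the membership table, the subclade
table with counts and percentages (half-up rounding to one decimal, the
convention of family-survey summary tables), the chromosomal distribution
table, the tandem-duplication table, the per-subclade molecular-property
summary, and the clustered expression heatmap.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import pandas as pd
import yaml

from . import (
    expression,
    family_screen,
    genome_map,
    io_formats,
    phylo,
    physiology,
    protein_char,
)
from .align import build_msa, read_aligned_fasta
from .types import ConfigError

log = logging.getLogger("rlkfam")


def percentage(count: int, total: int) -> float:
    """100*count/total rounded half-up to one decimal."""
    if total <= 0:
        raise ConfigError("percentage total must be positive")
    frac = Decimal(100 * count) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def subclade_table(labels: dict[str, str]) -> pd.DataFrame:
    """Counts and percentage share per subclade label."""
    counts: dict[str, int] = {}
    for lab in labels.values():
        counts[lab] = counts.get(lab, 0) + 1
    total = sum(counts.values())
    rows = [
        {"subclade": sub, "n_genes": n, "pct": percentage(n, total)}
        for sub, n in sorted(counts.items())
    ]
    rows.append({"subclade": "Total", "n_genes": total, "pct": percentage(total, total)})
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """File paths, thresholds and mode flags for a full run."""

    proteome: str
    gff3: str
    references: str
    ref_labels: str
    domains: str
    domains_dialect: str = "domtblout"
    tm: Optional[str] = None
    sp: Optional[str] = None
    counts: Optional[str] = None
    qpcr: Optional[str] = None
    physiology: Optional[str] = None
    alignment: Optional[str] = None  # precomputed aligned FASTA bypass
    hits_in: Optional[str] = None    # precomputed BLAST outfmt-6 bypass
    e_max: float = 1e-10
    tde_window_bp: int = 1_000_000
    n_boot: int = 1000
    seed: int = 42
    gap_mode: str = "complete_deletion"
    chlorophyll_mode: str = "as_printed"
    welch: bool = False
    out_dir: str = "rlkfam_out"

    def validate(self) -> None:
        if self.e_max <= 0 or self.tde_window_bp <= 0 or self.n_boot < 0:
            raise ConfigError("thresholds must be positive")
        if self.gap_mode not in {"complete_deletion", "pairwise_deletion"}:
            raise ConfigError(f"unknown gap_mode {self.gap_mode!r}")
        required = {"proteome": self.proteome, "gff3": self.gff3,
                    "references": self.references, "ref_labels": self.ref_labels,
                    "domains": self.domains}
        optional = {"tm": self.tm, "sp": self.sp, "counts": self.counts,
                    "qpcr": self.qpcr, "physiology": self.physiology,
                    "alignment": self.alignment, "hits_in": self.hits_in}
        for name, path in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not path or not os.path.exists(path):
                raise ConfigError(f"configured {name} file not found: {path!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class ReportBundle:
    membership: pd.DataFrame
    subclades: pd.DataFrame
    distribution: pd.DataFrame
    tde: pd.DataFrame
    properties: pd.DataFrame
    summary: pd.DataFrame
    assignments: dict[str, str] = field(default_factory=dict)
    newick: str = ""


def run_all(config: PipelineConfig) -> ReportBundle:
    """Execute screening, classification, phylogeny, mapping, protein and
    expression characterization; write reports under ``config.out_dir``."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)

    log.info("stage=screen reading proteome and references")
    proteome = io_formats.read_fasta(config.proteome)
    refs = io_formats.read_fasta(config.references)
    labels = dict(pd.read_csv(config.ref_labels, sep="\t").itertuples(index=False))

    if config.hits_in:
        hits = io_formats.read_similarity_table(config.hits_in)
    else:
        hits = family_screen.similarity_search(refs, proteome)
    candidates = family_screen.screen_candidates(hits, e_max=config.e_max)
    log.info("stage=screen candidates=%d", len(candidates))

    domain_hits = io_formats.read_domain_table(config.domains, config.domains_dialect)
    by_id = {p.id: p for p in proteome}
    if config.tm:
        tm_calls = io_formats.read_tm_table(config.tm)
    else:
        tm_calls = [
            c for pid in sorted(candidates) if pid in by_id
            for c in protein_char.hydropathy_tm_scan(by_id[pid].sequence,
                                                     protein_id=pid)
        ]
    sp_calls = io_formats.read_sp_table(config.sp) if config.sp else []

    decisions = family_screen.classify_all(candidates, domain_hits, tm_calls)
    members = sorted(d.protein_id for d in decisions if d.is_member)
    membership_df = pd.DataFrame(
        [
            {"protein_id": d.protein_id, "n_lrr": d.n_lrr,
             "has_kinase": d.has_kinase, "n_tm": d.n_tm,
             "is_member": d.is_member, "reasons": ";".join(d.reasons)}
            for d in decisions
        ]
    )
    log.info("stage=classify members=%d", len(members))

    log.info("stage=phylo aligning %d sequences", len(members) + len(refs))
    if config.alignment:
        aln = read_aligned_fasta(config.alignment)
    else:
        records = [by_id[m] for m in members if m in by_id] + refs
        aln = build_msa(records)
    if config.n_boot > 0:
        tree = phylo.bootstrap_support(
            aln, n_reps=config.n_boot, seed=config.seed, gap_mode=config.gap_mode
        )
    else:
        tree = phylo.neighbor_joining(phylo.p_distance(aln, config.gap_mode))
    newick = io_formats.write_newick(tree, out("tree.nwk"))
    assignments = phylo.assign_subclades(tree, labels)
    label_of = {a.query_id: a.label for a in assignments}
    subclades_df = subclade_table(label_of)

    log.info("stage=genome mapping and tandem duplication")
    genes = io_formats.read_gff3(config.gff3)
    placements = genome_map.place_genes(genes, members)
    distribution_df = genome_map.distribution_table(placements)
    events = genome_map.call_tandem_duplications(placements, config.tde_window_bp)
    tde_df = pd.DataFrame(
        [
            {"event_id": e.event_id, "seq_id": e.seq_id,
             "genes": ",".join(e.gene_ids), "span_bp": e.span_bp}
            for e in events
        ],
        columns=["event_id", "seq_id", "genes", "span_bp"],
    )

    log.info("stage=protein characterizing %d members", len(members))
    props = [
        protein_char.compute_properties(by_id[m], domain_hits, tm_calls, sp_calls)
        for m in members if m in by_id
    ]
    props_df = protein_char.properties_table(props)
    gene_spans = {g.gene_id: g.span_bp for g in genes}
    summary_df = protein_char.summarize_subclades(assignments, props, gene_spans)

    if config.counts:
        log.info("stage=expression heatmap")
        counts = io_formats.read_counts(config.counts)
        lengths = {
            g.gene_id: sum(e - s + 1 for s, e in g.exons) or g.span_bp
            for g in genes
        }
        mat = expression.normalize(expression.rpkm(counts, pd.Series(lengths)))
        expression.write_heatmap(mat, out("heatmap.tsv"))
    if config.qpcr:
        folds = expression.ddct(
            expression.read_qpcr(config.qpcr), "GhActin2", "control"
        )
        folds.to_csv(out("qpcr_folds.tsv"), sep="\t", index=False)
    if config.physiology:
        comps = physiology.compare_groups(
            physiology.read_physiology(config.physiology),
            chlorophyll_mode=config.chlorophyll_mode, welch=config.welch,
        )
        physiology.comparison_table(comps).to_csv(
            out("physiology.tsv"), sep="\t", index=False
        )

    # self-consistency: subclade counts and placements both total members
    assert int(subclades_df.iloc[-1]["n_genes"]) == len(label_of)
    n_placed = sum(1 for p in placements if p.is_family)
    if n_placed != len(members):
        log.warning("placement total %d != member total %d", n_placed, len(members))

    membership_df.to_csv(out("membership.tsv"), sep="\t", index=False)
    subclades_df.to_csv(out("subclades.tsv"), sep="\t", index=False)
    distribution_df.to_csv(out("distribution.tsv"), sep="\t", index=False)
    tde_df.to_csv(out("tde.tsv"), sep="\t", index=False)
    props_df.to_csv(out("properties.tsv"), sep="\t", index=False)
    summary_df.to_csv(out("subclade_summary.tsv"), sep="\t", index=False)

    return ReportBundle(
        membership=membership_df,
        subclades=subclades_df,
        distribution=distribution_df,
        tde=tde_df,
        properties=props_df,
        summary=summary_df,
        assignments=label_of,
        newick=newick,
    )
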