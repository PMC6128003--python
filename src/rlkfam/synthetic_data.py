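"""Seeded generator of complete toy datasets with planted ground truth.

The generator emulates the inputs of a genome-wide receptor-kinase family
survey: an annotated multi-chromosome genome, a proteome containing
planted family members, decoys that each violate exactly one membership
criterion, labeled reference proteins per subclade, evidence tables in
the dialects the parsers accept, a stage-structured RNA-seq count matrix,
qPCR Ct tables and salt-stress physiology measurements.

Family members are modular: a 22-aa signal peptide, an optional
malectin-like block (subclade I), k tandem copies of the 24-residue LRR
consensus instance, a 19-aa hydrophobic transmembrane stretch and a
260-aa kinase block. Each subclade descends from the common kinase/
malectin seed blocks by an ancestor-level substitution rate, and each
member mutates its subclade ancestor again at ``mutation_rate`` — so
phylogenetic signal, membership evidence and genomic placement are all
known exactly and every downstream stage can be scored against truth.

One global seed fans out to per-component streams (proteins, genome,
evidence, expression, qPCR, physiology), so adding a stage never perturbs
earlier draws.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .types import DomainHit, GeneModel, ProteinRecord, SPCall, TMCall

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# fixed building blocks: identical across user seeds so that datasets are
# comparable replicates of the same study conditions
_BLOCK_SEED = 20180914
SIGNAL_PEPTIDE = "MKTLLLLALLFSLLSLSATEAG"  # 22 aa, cleavage after position 22
TM_SEGMENT = "ILIVFLLVAVILLFIGLVL"  # 19 hydrophobic residues
LRR_UNIT = "LAALAALAALALAANALAAGAVPA"  # one consensus-matching repeat


def _fixed_block(length: int, offset: int) -> str:
    rng = np.random.default_rng(_BLOCK_SEED + offset)
    return "".join(rng.choice(list(AA20), size=length))


KINASE_BLOCK = _fixed_block(260, 1)
MALECTIN_BLOCK = _fixed_block(300, 2)


def mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. substitution at *rate*; replacements differ from the original."""
    seq = list(sequence)
    hits = np.where(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = AA20.replace(seq[i], "") if seq[i] in AA20 else AA20
        seq[i] = choices[rng.integers(len(choices))]
    return "".join(seq)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    subclades: dict[str, int] = field(
        default_factory=lambda: {"I": 5, "III": 5, "XI": 5, "XII": 5}
    )
    lrr_copies: dict[str, int] = field(
        default_factory=lambda: {"I": 2, "III": 3, "XI": 4, "XII": 5}
    )
    n_refs_per_subclade: int = 2
    n_decoys: int = 6  # cycled over the three violated criteria
    mutation_rate: float = 0.10      # member vs subclade ancestor
    ref_mutation_rate: float = 0.02  # reference vs subclade ancestor
    subclade_divergence: float = 0.35  # ancestor vs the seed blocks
    malectin_subclade: str = "I"
    malectin_fraction: float = 0.8   # fraction of that subclade with the block
    miss_tm_rate: float = 0.0        # evidence-table noise
    miss_domain_rate: float = 0.0
    n_filler_per_chrom: int = 10
    filler_protein_len: int = 250
    gene_bp: int = 3000
    gene_spacing_bp: int = 50_000
    fiber_high_subclades: tuple[str, ...] = ("XI", "XII")
    nb_mean_low: float = 20.0
    nb_mean_high: float = 400.0
    nb_size: float = 10.0
    qpcr_fold: float = 0.3           # planted silencing fold change
    qpcr_sigma: float = 0.15         # Ct noise, cycles
    physio_n: int = 5
    physio_sigma: float = 0.10       # relative noise
    physio_chl_effect: float = 1.30  # silenced / control chlorophyll
    physio_el_effect: float = 0.60   # silenced / control leakage

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


SAMPLES = ["-3dpa", "-1dpa", "0dpa", "1dpa", "3dpa", "5dpa", "10dpa", "20dpa",
           "25dpa", "leaf"]
FIBER_SAMPLES = set(SAMPLES) - {"leaf"}

DECOY_CRITERIA = ("LRR", "kinase", "TM")


@dataclass
class SyntheticTruth:
    """Planted ground truth; at zero noise it fully determines the
    expected output of every pipeline stage."""

    member_subclades: dict[str, str]
    decoy_criteria: dict[str, str]          # decoy id -> violated criterion
    tde_events: list[tuple[str, tuple[str, ...]]]
    expression_pattern: dict[str, str]      # gene -> fiber_high | baseline
    physiology_effects: dict[str, float]
    seed: int


@dataclass
class SyntheticDataset:
    out_dir: str
    paths: dict[str, str]
    truth: SyntheticTruth
    config: SimConfig


def _build_protein(
    subclade: str,
    cfg: SimConfig,
    ancestors: dict[str, dict[str, str]],
    rng: np.random.Generator,
    with_malectin: bool,
    omit: Optional[str] = None,
    mutation_rate: Optional[float] = None,
) -> tuple[str, list[DomainHit], Optional[TMCall], Optional[SPCall]]:
    """Assemble one protein and the evidence segments of its blocks."""
    rate = cfg.mutation_rate if mutation_rate is None else mutation_rate
    parts: list[str] = [SIGNAL_PEPTIDE]
    doms: list[tuple[str, str, int, int]] = []  # (name, category, start, end)
    pos = len(SIGNAL_PEPTIDE)
    if with_malectin:
        block = mutate(ancestors[subclade]["malectin"], rate, rng)
        doms.append(("Malectin_like", "malectin", pos + 1, pos + len(block)))
        parts.append(block)
        pos += len(block)
    if omit != "LRR":
        for _ in range(cfg.lrr_copies[subclade]):
            doms.append(("LRR_8", "LRR", pos + 1, pos + len(LRR_UNIT)))
            parts.append(LRR_UNIT)
            pos += len(LRR_UNIT)
    tm_call: Optional[TMCall] = None
    if omit != "TM":
        tm_start = pos + 1
        parts.append(TM_SEGMENT)
        pos += len(TM_SEGMENT)
        tm_call = TMCall("", tm_start, pos)
    if omit != "kinase":
        block = mutate(ancestors[subclade]["kinase"], rate, rng)
        doms.append(("Pkinase", "kinase", pos + 1, pos + len(block)))
        parts.append(block)
        pos += len(block)
    seq = "".join(parts)
    hits = [
        DomainHit("", name, cat, s, e, score=80.0, evalue=1e-30)
        for name, cat, s, e in doms
    ]
    sp = SPCall("", 1, len(SIGNAL_PEPTIDE), len(SIGNAL_PEPTIDE))
    return seq, hits, tm_call, sp


def generate_dataset(
    config: Optional[SimConfig] = None, seed: int = 0, out_dir: str = "."
) -> SyntheticDataset:
    """Write a complete synthetic input bundle under *out_dir*.

    Identical (config, seed) pairs produce byte-identical files.
    """
    cfg = config or SimConfig()
    os.makedirs(out_dir, exist_ok=True)
    streams = np.random.SeedSequence(seed).spawn(6)
    rng_prot, rng_genome, rng_evid, rng_expr, rng_qpcr, rng_phys = (
        np.random.default_rng(s) for s in streams
    )

    # ---- subclade ancestors ------------------------------------------
    ancestors: dict[str, dict[str, str]] = {}
    for sub in cfg.subclades:
        ancestors[sub] = {
            "kinase": mutate(KINASE_BLOCK, cfg.subclade_divergence, rng_prot),
            "malectin": mutate(MALECTIN_BLOCK, cfg.subclade_divergence, rng_prot),
        }

    proteins: list[ProteinRecord] = []
    domain_hits: list[DomainHit] = []
    tm_calls: list[TMCall] = []
    sp_calls: list[SPCall] = []
    member_subclades: dict[str, str] = {}
    decoy_criteria: dict[str, str] = {}

    def register(pid: str, seq: str, hits, tm, sp, desc: str) -> None:
        proteins.append(ProteinRecord(pid, seq, desc))
        for h in hits:
            domain_hits.append(
                DomainHit(pid, h.domain_name, h.category, h.env_start, h.env_end,
                          h.score, h.evalue)
            )
        if tm is not None:
            tm_calls.append(TMCall(pid, tm.start, tm.end))
        if sp is not None:
            sp_calls.append(SPCall(pid, sp.start, sp.end, sp.cleavage))

    # ---- members ------------------------------------------------------
    for sub, n in cfg.subclades.items():
        n_mal = round(cfg.malectin_fraction * n) if sub == cfg.malectin_subclade else 0
        for i in range(n):
            pid = f"Gh_{sub}_{i + 1:02d}"
            seq, hits, tm, sp = _build_protein(
                sub, cfg, ancestors, rng_prot, with_malectin=i < n_mal
            )
            register(pid, seq, hits, tm, sp, f"synthetic member subclade {sub}")
            member_subclades[pid] = sub

    # ---- decoys (each violates exactly one criterion) -----------------
    sub_names = list(cfg.subclades)
    for i in range(cfg.n_decoys):
        crit = DECOY_CRITERIA[i % len(DECOY_CRITERIA)]
        sub = sub_names[i % len(sub_names)]
        pid = f"Decoy_{i + 1:02d}"
        seq, hits, tm, sp = _build_protein(
            sub, cfg, ancestors, rng_prot, with_malectin=False, omit=crit
        )
        register(pid, seq, hits, tm, sp, f"synthetic decoy missing {crit}")
        decoy_criteria[pid] = crit

    # ---- references ---------------------------------------------------
    references: list[ProteinRecord] = []
    ref_labels: dict[str, str] = {}
    for sub, n in cfg.subclades.items():
        n_mal = 1 if sub == cfg.malectin_subclade else 0
        for r in range(cfg.n_refs_per_subclade):
            rid = f"AtRef_{sub}_{r + 1}"
            seq, _, _, _ = _build_protein(
                sub, cfg, ancestors, rng_prot,
                with_malectin=r < n_mal, mutation_rate=cfg.ref_mutation_rate,
            )
            references.append(ProteinRecord(rid, seq, f"reference subclade {sub}"))
            ref_labels[rid] = sub

    # ---- genome layout ------------------------------------------------
    chromosomes = ["A01", "A02", "D01", "D02", "scaffold101.1", "scaffold102.1"]
    member_ids = list(member_subclades)
    decoy_ids = list(decoy_criteria)
    # tandem plans: (chromosome index, [member slots], filler gaps, bp gap)
    # layout tokens: "F" = next member gene, "x" = filler gene
    tde_plans = [
        ("A01", ["F", "F"], None),               # adjacent pair -> event
        ("A02", ["F", "x", "F"], None),          # one interruption -> event
        ("D01", ["F", "x", "x", "F"], 400_000),  # two within window -> event
        ("D02", ["F", "x", "x", "F"], 2_000_000),  # two beyond window -> none
    ]
    planted: list[tuple[str, tuple[str, ...]]] = []
    mem_iter = iter(member_ids)

    genes: list[GeneModel] = []
    used_fillers: dict[str, int] = {c: 0 for c in chromosomes}

    def next_filler(seq_id: str) -> str:
        """Mint a filler gene id and register its (random) protein."""
        used_fillers[seq_id] += 1
        pid = f"Flr_{chromosomes.index(seq_id)}_{used_fillers[seq_id]:02d}"
        seq = "".join(rng_prot.choice(list(AA20), size=cfg.filler_protein_len))
        register(pid, seq, [], None, None, "synthetic filler")
        return pid

    def add_gene(seq_id: str, pid: str, start: int, rng: np.random.Generator) -> GeneModel:
        n_exons = int(rng.integers(1, 4))
        end = start + cfg.gene_bp - 1
        bounds = sorted(rng.choice(
            np.arange(start + 1, end - 1), size=2 * (n_exons - 1), replace=False
        )) if n_exons > 1 else []
        edges = [start] + [int(b) for b in bounds] + [end]
        exons = [(edges[2 * k], edges[2 * k + 1]) for k in range(n_exons)]
        g = GeneModel(
            gene_id=pid, seq_id=seq_id, start=start, end=end,
            strand="+" if rng.random() < 0.5 else "-",
            exons=exons, protein_id=pid,
        )
        genes.append(g)
        return g

    cursors = {c: 100_000 for c in chromosomes}

    for seq_id, layout, bp_gap in tde_plans:
        slot_members: list[str] = []
        complete = True
        for tok_i, tok in enumerate(layout):
            pid = next(mem_iter, None) if tok == "F" else next_filler(seq_id)
            if pid is None:  # config too small for this plan: fill instead
                complete = False
                pid = next_filler(seq_id)
            elif tok == "F":
                slot_members.append(pid)
            g = add_gene(seq_id, pid, cursors[seq_id], rng_genome)
            # the distance window applies between the flanking family
            # genes: stretch the last gap so end(F1) -> start(F2) == bp_gap
            if bp_gap is not None and tok_i == len(layout) - 2 and slot_members:
                fam_end = next(
                    gg.end for gg in reversed(genes) if gg.gene_id == slot_members[0]
                )
                cursors[seq_id] = fam_end + bp_gap
            else:
                cursors[seq_id] = g.end + cfg.gene_spacing_bp + 1
        # truth by the stated rule: <=1 interruption, or ==2 within 1 Mb
        n_between = len(layout) - 2
        if complete and (
            n_between <= 1 or (n_between == 2 and (bp_gap or 0) <= 1_000_000)
        ):
            planted.append((seq_id, tuple(slot_members)))

    # isolated members, decoys and remaining fillers: round-robin over
    # chromosomes with >= 3 filler genes between any two family genes
    remaining = list(mem_iter) + decoy_ids
    cidx = 0
    for pid in remaining:
        seq_id = chromosomes[cidx % len(chromosomes)]
        for _ in range(3):
            fid = next_filler(seq_id)
            g = add_gene(seq_id, fid, cursors[seq_id], rng_genome)
            cursors[seq_id] = g.end + cfg.gene_spacing_bp + 1
        g = add_gene(seq_id, pid, cursors[seq_id], rng_genome)
        cursors[seq_id] = g.end + cfg.gene_spacing_bp + 1
        cidx += 1
    for chrom in chromosomes:
        while used_fillers[chrom] < cfg.n_filler_per_chrom:
            fid = next_filler(chrom)
            g = add_gene(chrom, fid, cursors[chrom], rng_genome)
            cursors[chrom] = g.end + cfg.gene_spacing_bp + 1

    # ---- evidence noise ----------------------------------------------
    if cfg.miss_domain_rate > 0:
        domain_hits = [
            h for h in domain_hits if rng_evid.random() >= cfg.miss_domain_rate
        ]
    if cfg.miss_tm_rate > 0:
        tm_calls = [t for t in tm_calls if rng_evid.random() >= cfg.miss_tm_rate]

    # ---- expression ---------------------------------------------------
    pattern = {
        pid: ("fiber_high" if sub in cfg.fiber_high_subclades else "baseline")
        for pid, sub in member_subclades.items()
    }
    counts = {}
    for pid in member_ids:
        row = []
        for sample in SAMPLES:
            high = pattern[pid] == "fiber_high" and sample in FIBER_SAMPLES
            mean = cfg.nb_mean_high if high else cfg.nb_mean_low
            p = cfg.nb_size / (cfg.nb_size + mean)
            row.append(int(rng_expr.negative_binomial(cfg.nb_size, p)))
        counts[pid] = row
    counts_df = pd.DataFrame.from_dict(
        counts, orient="index", columns=SAMPLES
    ).rename_axis("gene_id")

    # ---- qPCR ---------------------------------------------------------
    target = member_ids[0]
    qpcr_rows = []
    delta_ct = -np.log2(cfg.qpcr_fold)  # Ct shift planted in the silenced group
    for group, shift in (("control", 0.0), ("treatment", delta_ct)):
        for bio in (1, 2):
            for tech in (1, 2, 3):
                rep = f"b{bio}t{tech}"
                sample = f"{group}_b{bio}"
                ref_ct = 15.0 + rng_qpcr.normal(0, cfg.qpcr_sigma)
                qpcr_rows.append((sample, "GhActin2", round(ref_ct, 3), rep, group))
                tgt_ct = ref_ct + 5.0 + shift + rng_qpcr.normal(0, cfg.qpcr_sigma)
                qpcr_rows.append((sample, target, round(tgt_ct, 3), rep, group))
    qpcr_df = pd.DataFrame(
        qpcr_rows, columns=["sample", "gene", "ct", "replicate", "group"]
    )

    # ---- physiology ---------------------------------------------------
    phys_rows = []
    for group, chl_f, el_f in (
        ("control", 1.0, 1.0),
        ("silenced", cfg.physio_chl_effect, cfg.physio_el_effect),
    ):
        for i in range(cfg.physio_n):
            noise = lambda: 1.0 + rng_phys.normal(0, cfg.physio_sigma)
            phys_rows.append(
                {
                    "sample_id": f"{group}_{i + 1}",
                    "group": group,
                    "a663": round(0.80 * chl_f * noise(), 4),
                    "a645": round(0.40 * chl_f * noise(), 4),
                    "v_ml": 15.0,
                    "w_mg": 300.0,
                    "el1": round(min(60.0 * el_f * noise(), 99.0), 3),
                    "el2": 100.0,
                }
            )
    phys_df = pd.DataFrame(phys_rows)

    # ---- write everything --------------------------------------------
    paths = {k: os.path.join(out_dir, v) for k, v in {
        "proteome": "proteome.faa",
        "genome": "genome.gff3",
        "references": "references.faa",
        "ref_labels": "ref_labels.tsv",
        "domains_domtblout": "domains.domtblout",
        "domains_tsv": "domains.tsv",
        "tm": "tm.tsv",
        "sp": "sp.tsv",
        "counts": "counts.tsv",
        "qpcr": "qpcr.csv",
        "physiology": "physiology.csv",
        "truth": "truth.json",
    }.items()}

    io_formats.write_fasta(proteins, paths["proteome"])
    io_formats.write_gff3(genes, paths["genome"])
    io_formats.write_fasta(references, paths["references"])
    pd.DataFrame(
        sorted(ref_labels.items()), columns=["protein_id", "subclade"]
    ).to_csv(paths["ref_labels"], sep="\t", index=False)
    io_formats.write_domtblout(domain_hits, paths["domains_domtblout"])
    pd.DataFrame(
        [(h.protein_id, h.domain_name, h.env_start, h.env_end, h.score, h.evalue)
         for h in domain_hits],
        columns=["protein_id", "domain_name", "env_start", "env_end", "score",
                 "evalue"],
    ).to_csv(paths["domains_tsv"], sep="\t", index=False)
    io_formats.write_tm_table(tm_calls, paths["tm"])
    io_formats.write_sp_table(sp_calls, paths["sp"])
    io_formats.write_counts(counts_df, paths["counts"])
    qpcr_df.to_csv(paths["qpcr"], index=False)
    phys_df.to_csv(paths["physiology"], index=False)

    truth = SyntheticTruth(
        member_subclades=member_subclades,
        decoy_criteria=decoy_criteria,
        tde_events=planted,
        expression_pattern=pattern,
        physiology_effects={
            "chlorophyll_ratio": cfg.physio_chl_effect,
            "leakage_ratio": cfg.physio_el_effect,
        },
        seed=seed,
    )
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(truth), fh, indent=1, default=list)
    return SyntheticDataset(out_dir=out_dir, paths=paths, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# End-to-end recovery

@dataclass
class RecoveryReport:
    membership_precision: float
    membership_recall: float
    subclade_accuracy: float
    tde_exact_match: bool
    n_members_true: int
    n_members_found: int
    n_tde_true: int
    n_tde_found: int
    assignments: dict[str, str] = field(default_factory=dict)


def end_to_end_recovery(
    dataset: SyntheticDataset,
    e_max: float = 1e-10,
    gap_mode: str = "complete_deletion",
    n_boot: int = 0,
    boot_seed: int = 0,
) -> RecoveryReport:
    """Run the full pipeline on generated files and score against truth."""
    from . import family_screen, genome_map, phylo
    from .align import build_msa

    proteome = io_formats.read_fasta(dataset.paths["proteome"])
    refs = io_formats.read_fasta(dataset.paths["references"])
    labels = dict(
        pd.read_csv(dataset.paths["ref_labels"], sep="\t").itertuples(index=False)
    )

    hits = family_screen.similarity_search(refs, proteome)
    candidates = family_screen.screen_candidates(hits, e_max=e_max)
    domain_hits = io_formats.read_domain_table(
        dataset.paths["domains_domtblout"], dialect="domtblout"
    )
    tm_calls = io_formats.read_tm_table(dataset.paths["tm"])
    decisions = family_screen.classify_all(candidates, domain_hits, tm_calls)
    found = {d.protein_id for d in decisions if d.is_member}

    truth_members = set(dataset.truth.member_subclades)
    tp = len(found & truth_members)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(truth_members) if truth_members else 1.0

    # phylogeny over recovered members + references
    by_id = {p.id: p for p in proteome}
    records = [by_id[m] for m in sorted(found)] + refs
    aln = build_msa(records)
    if n_boot > 0:
        tree = phylo.bootstrap_support(aln, n_reps=n_boot, seed=boot_seed,
                                       gap_mode=gap_mode)
    else:
        tree = phylo.neighbor_joining(phylo.p_distance(aln, gap_mode))
    assignments = {a.query_id: a.label for a in phylo.assign_subclades(tree, labels)}
    scored = [
        m for m in found & truth_members if m in assignments
    ]
    correct = sum(
        1 for m in scored
        if assignments[m] == dataset.truth.member_subclades[m]
    )
    accuracy = correct / len(scored) if scored else 0.0

    # tandem duplications
    genes = io_formats.read_gff3(dataset.paths["genome"])
    placements = genome_map.place_genes(genes, found)
    events = genome_map.call_tandem_duplications(placements)
    found_sets = {frozenset(e.gene_ids) for e in events}
    true_sets = {frozenset(gs) for _, gs in dataset.truth.tde_events}

    return RecoveryReport(
        membership_precision=precision,
        membership_recall=recall,
        subclade_accuracy=accuracy,
        tde_exact_match=found_sets == true_sets,
        n_members_true=len(truth_members),
        n_members_found=len(found),
        n_tde_true=len(true_sets),
        n_tde_found=len(found_sets),
        assignments=assignments,
    )
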