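# Methods

This note records the models, numerical choices and open design decisions
behind each stage of the pipeline, and what the synthetic-data tests do
and do not demonstrate about real data.

## Similarity screening

The internal search is a seeding heuristic over exhaustive local
alignment: a query/subject pair is aligned only if the two sequences
share at least one exact 3-mer; seeded pairs get the full Smith–Waterman
optimum (BLOSUM62, affine gaps). Gap costs follow the BLAST convention —
"open 11, extend 1" means a gap of length L costs 11 + L — so the
heuristic score can never exceed the exhaustive optimum and equals it
whenever the optimal alignment contains a 3-residue exact match, which
holds for any biologically meaningful hit. E-values use the
Karlin–Altschul formula `E = K·m·n·exp(−λS)` with the standard gapped
BLOSUM62 constants λ = 0.267 and K = 0.041; `m` is the query length and
`n` the summed subject length. Edge-effect corrections are omitted at
these sequence lengths. The default candidate threshold is `E ≤ 1e-10`,
and candidates are collected on the subject side (references are the
queries), with a flag to flip the direction. Self-hits are excluded when
the query appears among the subjects.

## Membership rule

`member ⇔ (n_LRR ≥ 1) ∧ has_kinase ∧ (n_TM ≥ 1)`, evaluated on evidence
tables, never on raw sequence. Domain names map to categories through a
configurable rule list (defaults: `LRR*` → LRR, `Pkinase*`/
`PK_Tyr_Ser-Thr*` → kinase, `Malectin*` → malectin) because profile
databases do not agree on exact names; the mapping is configuration, not
ground truth. domtblout *env* (envelope) coordinates are used as the
domain extent — they bound the full domain, where *ali* coordinates only
bound the confidently aligned core. All coordinates are 1-based inclusive
end to end (GFF3-native); no half-open conversion exists anywhere in the
package, which removes a whole class of off-by-one drift.

## Alignment

Progressive alignment in the ClustalW mold: pairwise k-mer distances
(1 − shared 3-mer fraction over the shorter sequence) feed a UPGMA guide
tree (scipy average linkage), and profiles merge bottom-up with a global
profile–profile Needleman–Wunsch. Column pairs score the
frequency-weighted mean BLOSUM62 value with gap symbols scoring zero;
gaps cost 10 + 0.5·L. The dynamic program is vectorized row-wise, with
the horizontal affine state resolved by a max-accumulate scan. Traceback
ties prefer match, then the vertical gap state, making alignments
deterministic. A precomputed aligned FASTA can bypass the aligner
entirely. Single-sequence profiles reduce the same code to exact pairwise
Needleman–Wunsch, which is how the aligner is oracle-checked.

## Distances, trees, supports

p-distance is the proportion of differing residues among compared
positions. Two gap treatments are provided because the source protocol
is ambiguous between them (its figure legend says all gap-containing
positions were eliminated; its methods text says partial deletion):
`complete_deletion` (default) drops every column containing a gap before
any comparison, `pairwise_deletion` drops columns per pair. Only `-` is
treated as missing; `X` is compared as a residue.

Neighbor joining is the classic Saitou–Nei algorithm. Ties in the
Q-matrix resolve to the lexicographically smallest index pair —
reproducibility is preferred over fidelity to any particular legacy
implementation. Negative branch lengths are clamped to zero with the
deficit moved to the sister edge, preserving the joined pair's distance.
The final three-way join leaves a trifurcating central node, so trees are
genuinely unrooted; Newick output roots arbitrarily at that node and
carries integer bootstrap supports as internal-node labels.

Bootstrap replicates resample alignment columns uniformly with
replacement from a seeded 64-bit generator; an internal edge's support is
the percentage (rounded half-up) of replicates whose NJ tree contains the
same leaf bipartition. Replicates left with zero usable columns after gap
deletion are discarded and the denominator shrinks accordingly. Because
replicate distances are quantized (multiples of 1/columns), Q-matrix ties
occur in replicates and are resolved by index order; supports are
therefore invariant under leaf permutation only up to this tie noise
(a few percent on short alignments), while the full-data topology is
exactly invariant.

Subclade assignment formalizes "grouped with a labeled reference": for
each query, bipartition sides containing it are scanned from smallest to
largest, and the first side holding at least one labeled reference votes
by majority; support is the winning fraction among labeled references in
that side, vote ties go to the patristically nearest reference, and
references may carry an empty label to act as outgroup anchors that never
vote. A query that reaches the whole tree without meeting a labeled
reference is "unassigned" — this reproduces the behaviour of genuine
outliers that cluster only with non-family receptor proteins.

## Genome mapping

Gene ranks are 0-based start-order indices among **all** annotated genes
on a chromosome or scaffold (ties by end, then id). "Adjacent with at
most one interruption" counts intervening genes of any type in this rank
order; the 1 Mb window for two-interruption pairs is measured from the
end of the upstream gene to the start of the downstream one. Linked pairs
merge transitively into maximal events, which is why events can be fewer
than genes involved. The caller scans consecutive family genes only; this
is provably equivalent to the all-pairs link graph (a skipped family gene
would itself lie between the pair and shrink both sub-gaps) and is
oracle-checked against an all-pairs union-find on random genomes.
Subgenome classes come from configurable seq-id regexes (`^A\d+` → A,
`^D\d+` → D, `scaffold*` → scaffold) since assemblies differ in naming.

## Protein characterization

Molecular weight sums average-isotopic residue masses plus one water
(18.0153 Da); `X` contributes the mean residue mass. pI solves net
charge = 0 by bisection on [0, 14] to 0.001 pH with the Bjellqvist pKa
set (the set behind the ExPASy tool); the table is swappable because the
original server version is unrecoverable. The LRR consensus scan slides
a 24-residue window with positional constraints (positions 1, 4, 7, 10,
12, 17 ∈ {L, I}; 15 = N; 20 = G; 22 ∈ {V, I}; 23 = P; others free) and
reports overlapping matches. Two LRR counters are exposed — evidence-hit
count and consensus-match count — because published per-subclade "No. of
LRRs" ranges do not state their provenance; the evidence count is used in
summaries. The hydropathy TM fallback takes the union of residue spans of
19-residue windows with mean Kyte–Doolittle score ≥ 1.6. Architecture
strings order evidence segments by start and collapse consecutive equal
tokens; a malectin-like domain is N-terminal iff it starts before the
first LRR segment.

## Expression and validation statistics

RPKM uses `1e9·c/(N·L)` with L the summed exon length and N the column
sums of the count matrix (true mapped-read totals are unavailable without
raw reads). "Self-normalized log" is log2(RPKM + 1) followed by a
per-gene z-score (population SD); constant rows map to zeros by
convention. Heatmap ordering is average-linkage agglomeration on
1 − Pearson; zero-variance rows get distance 1 to everything rather than
being dropped. ΔΔCt matches target and reference Ct per
(sample, replicate), contrasts against the calibrator-group mean ΔCt per
target, and keeps replicate-level folds for statistics. The t-test is the
two-sided equal-variance Student flavour (Welch by flag), with the
conventional stars; two groups that are each exactly constant are handled
directly (identical means → t = 0, p = 1).

Chlorophyll equations are implemented verbatim from the source protocol,
including its internally inconsistent total — the printed
`(8.02·A663 − 20.20·A645)` disagrees in sign with the sum of the printed
a and b equations (`7.84·A663 + 20.21·A645`) and goes negative at
leaf-like absorbance ratios. The verbatim form stays the default
(`as_printed`); `arnon_corrected` flips the minus to the classic plus and
agrees with a + b to ~0.2% per coefficient. Statistical analyses of
chlorophyll use the corrected total, since the printed form cancels most
of the biological signal. Electrolyte leakage is 100·EL1/EL2; the
protocol defines EL1 and EL2 but stops short of the ratio, so the
standard percent form is adopted.

## Synthetic data: what it emulates and what it does not

Members are modular block proteins: a fixed 22-aa signal peptide, an
optional malectin-like block (subclade I, 80% of members by default), k
identical copies of the LRR consensus instance (k fixed per subclade,
2–5), a fixed 19-aa hydrophobic TM stretch, and a 260-aa kinase block.
Kinase and malectin blocks descend from fixed seed blocks through a
per-subclade ancestor (35% per-site divergence) and then per-member
mutation (default 10% — the regime the subclade-accuracy condition is
stated at). References are ancestors re-mutated at 2%; decoys omit
exactly one block. Defaults: 4 subclades × 5 members, 2 references per
subclade, 6 decoys, 60 filler proteins across 6 sequences (A01–A02,
D01–D02, two scaffolds). Tandem layouts plant an adjacent pair, a
one-interruption pair, a two-interruption pair 0.4 Mb apart (all true
events) and a two-interruption pair 2 Mb apart (a true negative). Counts
are negative-binomial (size 10) with fiber-stage means of 400 vs 20 for
the planted fiber-high subclades (XI, XII); qPCR plants a 0.3-fold
silencing with 0.15-cycle noise; physiology plants +30% chlorophyll and
−40% leakage in the silenced group at n = 5, σ = 10%. One global seed
fans out to six per-component streams, so adding a stage never perturbs
earlier draws and identical (config, seed) pairs are byte-identical.

Deliberately absent from the emulation: realistic domain-model noise
(evidence errors are simple Bernoulli drops), sequence-level evolution of
the LRR/TM/SP blocks, codon structure, alternative splicing, mapping
ambiguity in counts, and any correlation structure between stages.
Passing tests therefore demonstrate the *algorithms* are correct against
planted truth and stated rules — not that the evidence thresholds would
be optimal on a real proteome, where domain callers and TM predictors
have their own error modes.

Problem sizes in the test and acceptance runs (28-taxon alignments,
100-replicate bootstraps, 20-seed recovery sweeps, 200 random genomes,
100 additive matrices, 100 peptides) were chosen to exercise every code
path at desk scale while keeping each sweep in the low minutes.

## Known limitations

- The aligner is a desk-scale progressive aligner; it has no iterative
  refinement and will not match dedicated MSA tools on hard real
  alignments.
- Karlin–Altschul parameters are fixed constants, not fitted to the
  scoring system per search; E-values are comparable within a run, not
  calibrated across databases.
- The subclade rule assigns by majority in the smallest labeled cluster;
  on trees where references interleave poorly it has no rescue heuristic
  beyond nearest-reference tie-breaking.
- The bootstrap support tie-noise described above.
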