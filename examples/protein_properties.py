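"""Protein physicochemical properties and domain architectures.

Computes molecular weight (average masses), isoelectric point (Bjellqvist
bisection), LRR consensus matches, and the ordered domain-architecture
token string for a receptor-like kinase built from its canonical blocks.
"""

from rlkfam import protein_char
from rlkfam.types import DomainHit, SPCall, TMCall

# a consensus LRR repeat followed by hydrophobic and charged context
LRR = "LAALAALAALALAANALAAGAVPA"
seq = "MKTLLLLALLFSLLSLSATEAG" + LRR * 3 + "ILIVFLLVAVILLFIGLVL" + "KRDE" * 40

mw = protein_char.molecular_weight(seq)
pi = protein_char.isoelectric_point(seq)
matches = protein_char.scan_lrr_consensus(seq)
print(f"length {len(seq)} aa, MW {mw / 1000:.1f} kDa, pI {pi:.2f}")
print(f"LRR consensus matches at positions {matches}")

tm_calls = protein_char.hydropathy_tm_scan(seq, protein_id="demo")
print("Kyte-Doolittle TM segments:", [(c.start, c.end) for c in tm_calls])

evidence = [
    DomainHit("demo", "LRR_8", "LRR", 23, 94),
    DomainHit("demo", "Pkinase", "kinase", 120, 270),
]
tokens = protein_char.architecture_string(
    "demo", evidence, tm_calls, [SPCall("demo", 1, 22, 22)]
)
print("architecture:", "-".join(tokens))

# The three tandem repeats give overlapping consensus matches; the
# hydropathy fallback finds the planted 19-residue hydrophobic stretch
# (the signal peptide also scores hydrophobic, as real N-terminal signals do).
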