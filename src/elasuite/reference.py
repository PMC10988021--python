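"""Bundled epilancin reference cluster and codon table.

The epilancin biosynthetic gene cluster (BGC) comprises nine genes: the
precursor peptide (*elaA*), a leader protease (*elaP*), a transporter
(*elaT*), the dehydratase (*elaB*), the cyclase (*elaC*), the bifunctional
protease/oxidoreductase that installs the N-terminal lactate (*elaO*), and
three putative immunity proteins (*elaI1*, *elaI2*, *elaI3*).

The protein and coding sequences bundled here are SYNTHETIC stand-ins: the
real producer-strain sequences are only available from NCBI accessions and
supplementary material, so this module generates deterministic pseudo-random
proteins with realistic per-gene lengths plus a hand-designed precursor
whose 30-residue core reproduces the canonical epilancin ring topology
(11-residue linear N-terminus, 5-membered ring A, 3-residue hinge, a
5-residue intertwined double-ring system, 6-residue C-terminal tail).
All downstream modules treat these sequences exactly as they would real ones.
"""

from __future__ import annotations

import numpy as np

# Reference gene order on the forward strand of the cluster.
GENE_ORDER: tuple[str, ...] = (
    "elaA", "elaP", "elaT", "elaB", "elaC", "elaO", "elaI1", "elaI2", "elaI3",
)

# Realistic protein lengths (aa, excluding stop): the dehydratase is the
# largest ORF, the precursor the smallest; totals give a ~9.2 kbp cluster
# span with 50-nt intergenic spacers.
GENE_LENGTHS: dict[str, int] = {
    "elaA": 55,
    "elaP": 160,
    "elaT": 600,
    "elaB": 980,
    "elaC": 400,
    "elaO": 290,
    "elaI1": 150,
    "elaI2": 220,
    "elaI3": 120,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Most-frequent codon per amino acid in a low-GC staphylococcal genome;
# any fixed table works because mining operates at the protein level.
PREFERRED_CODON: dict[str, str] = {
    "A": "GCA", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "CGT",
    "S": "TCA", "T": "ACA", "V": "GTT", "W": "TGG", "Y": "TAT",
}
STOP_CODON = "TAA"

# Precursor: 25-aa leader + 30-aa core.  Core positions (1-based):
#   1      Ser -> Dha -> N-terminal lactate
#   4      Thr -> Dhb (free dehydro residue in the linear part)
#   12->16 ring A   (Dhb 12 + Cys 16, MeLan, 5-membered)
#   17-19  hinge
#   20->23 ring B   (Dhb 20 + Cys 23, MeLan, 4-membered)
#   21->24 ring C   (Dha 21 + Cys 24, Lan, 4-membered; intertwined with B)
#   25-30  C-terminal tail
LEADER_SEQ = "MNNSLFDLNLNKENMSNQDLEAITQ"
CORE_SEQ = "SAITVKAKFLKTAKGCNFKTSACCHFTGKK"
PRECURSOR_SEQ = LEADER_SEQ + CORE_SEQ
CLEAVAGE_POSITION = len(LEADER_SEQ)  # 25

# Default predicted modification set for the reference core (see maturation).
DEFAULT_DEHYDRATIONS: tuple[int, ...] = (1, 4, 12, 20, 21)  # 1-based core positions
DEFAULT_RINGS: tuple[tuple[int, int, str], ...] = (
    (12, 16, "MeLan"),
    (20, 23, "MeLan"),
    (21, 24, "Lan"),
)

_REFERENCE_SEED = 20240312


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    return "M" + body


def reference_proteins() -> dict[str, str]:
    """Return the nine reference proteins, keyed by gene name.

    Deterministic: the same sequences are produced on every call.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    proteins: dict[str, str] = {}
    for gene in GENE_ORDER:
        if gene == "elaA":
            proteins[gene] = PRECURSOR_SEQ
            # keep rng stream aligned regardless of elaA's special-casing
            rng.choice(list(AMINO_ACIDS), size=GENE_LENGTHS[gene] - 1)
        else:
            proteins[gene] = _random_protein(GENE_LENGTHS[gene], rng)
    return proteins


def back_translate(protein: str, include_stop: bool = True) -> str:
    """Back-translate with the fixed preferred-codon table."""
    try:
        nt = "".join(PREFERRED_CODON[aa] for aa in protein)
    except KeyError as exc:  # pragma: no cover - guarded by callers
        raise ValueError(f"cannot back-translate residue {exc}") from exc
    return nt + STOP_CODON if include_stop else nt


def reference_cds() -> dict[str, str]:
    """Coding sequences (incl. stop codon) for the nine reference genes."""
    return {g: back_translate(p) for g, p in reference_proteins().items()}
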