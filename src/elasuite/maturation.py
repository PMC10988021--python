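"""Lanthipeptide maturation model and mass prediction.

Models the class-I lanthipeptide maturation cascade for epilancin-like
precursors: leader cleavage, dehydration of Ser/Thr to dehydroalanine (Dha)
and dehydrobutyrine (Dhb), lanthionine ring formation between dehydrated
donors and cysteine acceptors, reduction of dehydro residues to
alpha-aminobutyric acid (Abu), capping of an N-terminal Dha as a lactyl
group, and optional methylations.  Masses are computed from explicit
per-residue atomic compositions.

Chemistry bookkeeping, relative to the unmodified residue:

* dehydration (Ser -> Dha, Thr -> Dhb): -H2O
* ring formation (thioether Michael addition): no atomic change beyond the
  prior dehydration
* Abu (reduced Dhb): +H2 on the dehydrated residue
* N-terminal lactate: the N-terminal Dha residue (C3H3NO) plus its free
  amine proton is replaced by a lactyl cap, net residue composition C3H4O2
* methylation: +CH2 each
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

# Residue (= amino acid minus water) atomic compositions.
RESIDUE_COMPOSITION: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER = {"H": 2, "O": 1}
LACTYL_RESIDUE = {"C": 3, "H": 4, "O": 2}

AVERAGE_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}
MONOISOTOPIC_MASS = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
                     "O": 15.9949146221, "S": 31.97207069}


def _comp_add(a: dict[str, int], b: dict[str, int], sign: int = 1) -> dict[str, int]:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + sign * n
    return {el: n for el, n in out.items() if n}


def composition_mass(comp: dict[str, int], mode: str = "average") -> float:
    weights = AVERAGE_MASS if mode == "average" else MONOISOTOPIC_MASS
    try:
        return sum(weights[el] * n for el, n in comp.items())
    except KeyError as exc:
        raise ValueError(f"unknown element {exc}") from exc


@dataclass(frozen=True)
class PrecursorPeptide:
    sequence: str
    cleavage_position: int  # leader length

    @property
    def leader(self) -> str:
        return self.sequence[: self.cleavage_position]

    @property
    def core(self) -> str:
        return self.sequence[self.cleavage_position:]


def cleave_leader(precursor: str, cleavage_rule: int | str) -> PrecursorPeptide:
    """Split a precursor into leader and core.

    ``cleavage_rule`` is either an explicit leader length or a motif whose
    last residue ends the leader.  A missing motif raises, listing near-miss
    candidates (substrings within one mismatch of the motif).
    """
    if isinstance(cleavage_rule, int):
        if not 0 < cleavage_rule < len(precursor):
            raise ValueError(f"cleavage position {cleavage_rule} outside sequence")
        return PrecursorPeptide(precursor, cleavage_rule)
    motif = cleavage_rule
    idx = precursor.find(motif)
    if idx < 0:
        candidates = [
            (i, precursor[i:i + len(motif)])
            for i in range(len(precursor) - len(motif) + 1)
            if sum(x != y for x, y in zip(precursor[i:i + len(motif)], motif)) == 1
        ]
        raise ValueError(
            f"cleavage motif {motif!r} not found; near-miss candidates: {candidates}")
    return PrecursorPeptide(precursor, idx + len(motif))


@dataclass(frozen=True)
class ModificationSet:
    """Positioned posttranslational modifications on a core peptide.

    Positions are 1-based within the core.  ``rings`` entries are
    ``(donor, acceptor_cys, type)`` with type "Lan" or "MeLan".
    """

    dehydrations: tuple[int, ...] = ()
    rings: tuple[tuple[int, int, str], ...] = ()
    lactate: bool = False
    abu_positions: tuple[int, ...] = ()
    methylations: int = 0

    def validate(self, core: str) -> None:
        n = len(core)
        for p in self.dehydrations:
            if not 1 <= p <= n:
                raise ValueError(f"dehydration position {p} outside core")
            if core[p - 1] not in "ST":
                raise ValueError(f"dehydration at position {p} requires Ser/Thr, "
                                 f"found {core[p - 1]}")
        seen_cys: set[int] = set()
        for donor, acceptor, ring_type in self.rings:
            if ring_type not in ("Lan", "MeLan"):
                raise ValueError(f"unknown ring type {ring_type!r}")
            if not donor < acceptor:
                raise ValueError(f"ring donor {donor} must precede acceptor {acceptor}")
            if core[acceptor - 1] != "C":
                raise ValueError(f"ring acceptor at {acceptor} is not Cys")
            if acceptor in seen_cys:
                raise ValueError(f"Cys {acceptor} used in more than one ring")
            seen_cys.add(acceptor)
            if donor not in self.dehydrations:
                raise ValueError(f"ring donor {donor} is not dehydrated")
            expected = "T" if ring_type == "MeLan" else "S"
            if core[donor - 1] != expected:
                raise ValueError(f"{ring_type} ring donor at {donor} must be {expected}")
        if self.lactate:
            if core[0] != "S" or 1 not in self.dehydrations:
                raise ValueError("N-terminal lactate requires a dehydrated Ser at position 1")
        for p in self.abu_positions:
            if p not in self.dehydrations or core[p - 1] != "T":
                raise ValueError(f"Abu position {p} must be a dehydrated Thr")
        if self.methylations < 0:
            raise ValueError("methylation count must be >= 0")


@dataclass
class MaturePeptide:
    core: str
    residues: list[tuple[str, dict[str, int]]]  # (residue label, composition)
    segments: list[tuple[str, int]]  # alternating ("linear"/"ring", length)
    mods: ModificationSet = field(default_factory=ModificationSet)

    @property
    def composition(self) -> dict[str, int]:
        total: dict[str, int] = {}
        for _, comp in self.residues:
            total = _comp_add(total, comp)
        extra = {"C": self.mods.methylations, "H": 2 * self.mods.methylations}
        total = _comp_add(total, extra)
        return _comp_add(total, WATER)


def _ring_segments(n: int, rings: tuple[tuple[int, int, str], ...]) -> list[tuple[str, int]]:
    """Partition core positions into linear stretches and (merged) ring
    systems; intertwined rings whose spans overlap form one system."""
    if not rings:
        return [("linear", n)] if n else []
    spans = sorted((d, a) for d, a, _ in rings)
    systems: list[list[int]] = []
    for d, a in spans:
        if systems and d <= systems[-1][1]:
            systems[-1][1] = max(systems[-1][1], a)
        else:
            systems.append([d, a])
    segments: list[tuple[str, int]] = []
    cursor = 1
    for d, a in systems:
        if d > cursor:
            segments.append(("linear", d - cursor))
        segments.append(("ring", a - d + 1))
        cursor = a + 1
    if cursor <= n:
        segments.append(("linear", n - cursor + 1))
    return segments


def apply_maturation(core: str, mods: ModificationSet) -> MaturePeptide:
    """Apply a validated modification set to a core peptide."""
    if not core:
        raise ValueError("empty core peptide")
    mods.validate(core)
    residues: list[tuple[str, dict[str, int]]] = []
    for i, aa in enumerate(core, start=1):
        if aa not in RESIDUE_COMPOSITION:
            raise ValueError(f"unknown residue {aa!r} at core position {i}")
        comp = dict(RESIDUE_COMPOSITION[aa])
        label = aa
        if i in mods.dehydrations:
            comp = _comp_add(comp, WATER, sign=-1)
            label = "Dha" if aa == "S" else "Dhb"
        if i in mods.abu_positions:
            comp = _comp_add(comp, {"H": 2})
            label = "Abu"
        residues.append((label, comp))
    for donor, acceptor, ring_type in mods.rings:
        dl, dc = residues[donor - 1]
        al, ac = residues[acceptor - 1]
        residues[donor - 1] = (f"{ring_type}-donor", dc)
        residues[acceptor - 1] = (f"{ring_type}-Cys", ac)
    if mods.lactate:
        residues[0] = ("Lac", dict(LACTYL_RESIDUE))
    segments = _ring_segments(len(core), mods.rings)
    return MaturePeptide(core=core, residues=residues, segments=segments, mods=mods)


def peptide_mass(mature: MaturePeptide | str, mode: str = "average") -> float:
    """Mass in Da of a mature peptide (or plain sequence).

    ``mode`` is "average" (IUPAC atomic weights) or "monoisotopic"
    (principal isotopes).
    """
    if mode not in ("average", "monoisotopic"):
        raise ValueError(f"unknown mass mode {mode!r}")
    if isinstance(mature, str):
        mature = apply_maturation(mature, ModificationSet())
    return composition_mass(mature.composition, mode)


_GLOBAL_ALIGNER = Align.PairwiseAligner()
_GLOBAL_ALIGNER.mode = "global"
_GLOBAL_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_GLOBAL_ALIGNER.open_gap_score = -10.0
_GLOBAL_ALIGNER.extend_gap_score = -0.5


def percent_similarity(a: str, b: str) -> tuple[float, float]:
    """Global alignment identity and similarity, both as percentages.

    Needleman-Wunsch with BLOSUM62, gap open 10 / extend 0.5.  Identity is
    identical pairs over alignment length; similarity counts pairs with a
    positive substitution score.
    """
    for seq, what in ((a, "first"), (b, "second")):
        if not seq:
            raise ValueError(f"empty {what} sequence")
        bad = set(seq) - set(RESIDUE_COMPOSITION) - {"X"}
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in {what} sequence")
    aln = _GLOBAL_ALIGNER.align(a, b)[0]
    matrix = _GLOBAL_ALIGNER.substitution_matrix
    cols = identical = similar = 0
    blocks_a, blocks_b = aln.aligned
    # count aligned (residue-residue) columns
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        for x, y in zip(a[as_:ae], b[bs:be]):
            identical += x == y
            try:
                similar += matrix[x, y] > 0
            except IndexError:
                pass
    cols = aln.length  # alignment length including gap columns
    return 100.0 * identical / cols, 100.0 * similar / cols
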