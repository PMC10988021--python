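"""Synthetic genome assemblies with planted epilancin-like gene clusters.

Generates FASTA-writable contigs containing the nine-gene reference cluster
(optionally diverged and/or perturbed by controlled anomalies) embedded in
random flanking sequence, together with an exact truth table of everything
that was planted.  The generator is the ground-truth oracle for the mining
and phylogeny stages.

Anomalies mirror variants observed among naturally occurring epilancin
clusters: whole-gene deletions, truncations, single-gene or whole-cluster
strand reversals, and frameshifts that turn a gene into a pseudogene with a
premature stop codon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import reference
from .reference import AMINO_ACIDS, GENE_ORDER, STOP_CODON, back_translate

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

INTERGENIC_SPACER = 50  # nt between adjacent genes; compact ~9 kb cluster


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Anomaly:
    """A planted deviation from the reference cluster.

    kind is one of ``frameshift`` (arg = 1-based codon), ``truncate``
    (arg = retained fraction), ``reverse``, ``delete`` (gene-level), or
    ``reverse_cluster`` (gene is None).
    """

    kind: str
    gene: str | None = None
    arg: float | None = None

    _KINDS = frozenset({"frameshift", "truncate", "reverse", "delete", "reverse_cluster"})

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        if self.kind != "reverse_cluster" and self.gene is None:
            raise ValueError(f"anomaly {self.kind!r} requires a gene")


@dataclass
class ClusterSpec:
    """Recipe for one planted cluster."""

    genes: tuple[str, ...] = GENE_ORDER
    divergence: dict[str, float] = field(default_factory=dict)
    anomalies: tuple[Anomaly, ...] = ()
    flank_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names in spec")
        unknown = set(self.genes) - set(GENE_ORDER)
        if unknown:
            raise ValueError(f"unknown genes {sorted(unknown)}")
        for g, d in self.divergence.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"divergence for {g} outside [0, 1]: {d}")
        if self.flank_length < 0:
            raise ValueError("flank_length must be >= 0")
        deleted = {a.gene for a in self.anomalies if a.kind == "delete"}
        for a in self.anomalies:
            if a.kind == "reverse_cluster":
                continue
            if a.gene not in self.genes:
                raise ValueError(f"anomaly references absent gene {a.gene!r}")
            if a.kind != "delete" and a.gene in deleted:
                raise ValueError(f"anomaly {a.kind!r} on deleted gene {a.gene!r}")


@dataclass
class GeneTruth:
    gene: str
    contig: str
    start: int  # 0-based, half-open, forward strand
    end: int
    strand: str
    identity: float  # realized aa identity to reference, in [0, 1]
    label: str  # "intact" | "pseudogene" | "truncated" | "absent"


@dataclass
class TruthTable:
    placed: bool
    genes: list[GeneTruth]
    anomaly_labels: list[str]

    def completeness(self) -> float:
        present = sum(1 for g in self.genes if g.label != "absent")
        return present / len(GENE_ORDER)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["gene", "contig", "start", "end", "strand", "identity", "label"])
            for g in self.genes:
                w.writerow([g.gene, g.contig, g.start, g.end, g.strand,
                            f"{g.identity:.4f}", g.label])


@dataclass
class GenomeAssembly:
    contigs: dict[str, str]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def mutate_protein(seq: str, divergence: float, seed: int | np.random.Generator) -> str:
    """Substitute a ``divergence`` fraction of residues.

    Substitution positions are drawn without replacement; each substitute is
    drawn uniformly from the 19 alternative amino acids, so realized identity
    equals 1 - divergence up to rounding of the substitution count.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = int(round(divergence * len(seq)))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(x == y for x, y in zip(a[:n], b[:n])) / max(len(a), len(b))


def _apply_frameshift(cds: str, codon: int) -> str:
    """Delete one nucleotide at the given 1-based codon.

    Guarantees a premature stop in the original frame: in the rare case
    the shifted downstream sequence contains none, the last full codon is
    replaced with TAA.
    """
    pos = (codon - 1) * 3
    if pos >= len(cds) - 3:
        raise ValueError(f"frameshift codon {codon} beyond gene end")
    shifted = cds[:pos] + cds[pos + 1:]
    codons = [shifted[i:i + 3] for i in range(0, len(shifted) - 2, 3)]
    if not any(c in ("TAA", "TAG", "TGA") for c in codons[codon - 1:]):
        last = (len(shifted) // 3 - 1) * 3  # pragma: no cover - rare seeds
        shifted = shifted[:last] + STOP_CODON + shifted[last + 3:]
    return shifted


def generate_assembly(spec: ClusterSpec) -> tuple[GenomeAssembly, TruthTable]:
    """Build one contig containing the planted cluster plus random flanks.

    Deterministic: identical spec (including seed) yields byte-identical
    FASTA output.
    """
    rng = np.random.default_rng(spec.seed)
    ref_proteins = reference.reference_proteins()

    deleted = {a.gene for a in spec.anomalies if a.kind == "delete"}
    frameshifts = {a.gene: int(a.arg) for a in spec.anomalies if a.kind == "frameshift"}
    truncations = {a.gene: float(a.arg) for a in spec.anomalies if a.kind == "truncate"}
    reversed_genes = {a.gene for a in spec.anomalies if a.kind == "reverse"}
    reverse_cluster = any(a.kind == "reverse_cluster" for a in spec.anomalies)

    contig_name = "ctg1"
    parts: list[str] = []
    gene_truths: list[GeneTruth] = []
    anomaly_labels: list[str] = []

    # Assemble the cluster region gene by gene (reference order, restricted
    # to the spec's gene list), tracking coordinates relative to region start.
    region: list[str] = []
    offset = 0
    entries: list[tuple[str, int, int, str, float, str]] = []
    for gene in [g for g in GENE_ORDER if g in spec.genes]:
        if gene in deleted:
            anomaly_labels.append(f"delete({gene})")
            continue
        div = spec.divergence.get(gene, 0.0)
        if div > 0:
            # initiator Met is kept so the planted ORF start survives mutation
            protein = "M" + mutate_protein(ref_proteins[gene][1:], div, rng)
        else:
            protein = ref_proteins[gene]
        identity = _identity(protein, ref_proteins[gene])
        label = "intact"
        cds = back_translate(protein)
        if gene in truncations:
            frac = truncations[gene]
            if not 0.0 < frac < 1.0:
                raise ValueError("truncate fraction must be in (0, 1)")
            keep = max(1, int(round(frac * len(protein))))
            cds = back_translate(protein[:keep])
            label = "truncated"
            anomaly_labels.append(f"truncate({gene})")
        if gene in frameshifts:
            cds = _apply_frameshift(cds, frameshifts[gene])
            label = "pseudogene"
            anomaly_labels.append(f"frameshift({gene})")
        strand = "-" if gene in reversed_genes else "+"
        if gene in reversed_genes:
            anomaly_labels.append(f"reverse({gene})")
            cds = revcomp(cds)
        if region:
            spacer = "".join(rng.choice(list("ACGT"), size=INTERGENIC_SPACER))
            region.append(spacer)
            offset += INTERGENIC_SPACER
        start, end = offset, offset + len(cds)
        region.append(cds)
        offset = end
        entries.append((gene, start, end, strand, identity, label))

    region_seq = "".join(region)
    if reverse_cluster:
        anomaly_labels.append("reverse_cluster")
        n = len(region_seq)
        region_seq = revcomp(region_seq)
        entries = [
            (g, n - e, n - s, "-" if st == "+" else "+", ident, lab)
            for g, s, e, st, ident, lab in entries
        ]

    left = "".join(rng.choice(list("ACGT"), size=spec.flank_length))
    right = "".join(rng.choice(list("ACGT"), size=spec.flank_length))
    contig = left + region_seq + right

    for g, s, e, st, ident, lab in entries:
        gene_truths.append(GeneTruth(g, contig_name, s + len(left), e + len(left), st, ident, lab))
    for gene in GENE_ORDER:
        if gene not in spec.genes or gene in deleted:
            gene_truths.append(GeneTruth(gene, contig_name, 0, 0, ".", 0.0, "absent"))

    assembly = GenomeAssembly(contigs={contig_name: contig})
    truth = TruthTable(placed=bool(entries), genes=gene_truths,
                       anomaly_labels=anomaly_labels)
    return assembly, truth


def random_cluster_spec(seed: int, max_divergence: float = 0.3,
                        allow_deletions: bool = True,
                        allow_reversals: bool = True) -> ClusterSpec:
    """Draw a random planting recipe within the benchmark's study
    conditions: per-gene divergence uniform in [0, max_divergence], an
    occasional deletion of up to two non-precursor genes, and occasional
    single-gene or whole-cluster reversals."""
    rng = np.random.default_rng(seed)
    divergence = {g: float(rng.uniform(0.0, max_divergence)) for g in GENE_ORDER}
    anomalies: list[Anomaly] = []
    if allow_deletions and rng.uniform() < 0.3:
        candidates = [g for g in GENE_ORDER if g != "elaA"]
        for gene in rng.choice(candidates, size=rng.integers(1, 3), replace=False):
            anomalies.append(Anomaly("delete", str(gene)))
    if allow_reversals:
        u = rng.uniform()
        deleted = {a.gene for a in anomalies}
        if u < 0.1:
            anomalies.append(Anomaly("reverse_cluster"))
        elif u < 0.3:
            remaining = [g for g in GENE_ORDER if g not in deleted]
            anomalies.append(Anomaly("reverse", str(rng.choice(remaining))))
    return ClusterSpec(seed=seed, divergence=divergence,
                       anomalies=tuple(anomalies))


def variant_catalogue(divergences: dict[str, float] | None = None) -> dict[str, dict[str, str]]:
    """Catalogue of typed cluster variants for similarity classification.

    Each entry maps gene name -> protein sequence; entry order is the
    documented tie-break order.  Default divergences emulate the observed
    spread between natural epilancin cluster variants.
    """
    if divergences is None:
        divergences = {"A37": 0.0, "15X": 0.20, "K7": 0.30,
                       "EC1": 0.05, "EC5": 0.15}
    ref = reference.reference_proteins()
    catalogue: dict[str, dict[str, str]] = {}
    for i, (label, div) in enumerate(divergences.items()):
        rng = np.random.default_rng(900_000 + i)
        entry = {}
        for gene, protein in ref.items():
            if div == 0:
                entry[gene] = protein
            else:
                entry[gene] = "M" + mutate_protein(protein[1:], div, rng)
        catalogue[label] = entry
    return catalogue
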