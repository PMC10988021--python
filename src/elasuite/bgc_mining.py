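"""Detection, filtering and classification of epilancin-like gene clusters.

Re-implements the published homology screen as a self-contained pipeline:
six-frame ORF calling, Smith-Waterman protein alignment against the nine
reference cluster proteins (BLOSUM62, gap open 11 / extend 1), the coverage
(> 70%) and completeness (> 50%) filters, the precursor-exclusion rule
(no *elaA*, no cluster), anomaly annotation (missing / truncated / reversed
genes, pseudogenes, reversed clusters) and similarity-based typing against a
catalogue of known cluster variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .reference import GENE_ORDER, reference_proteins
from .synth_genomes import GenomeAssembly

VALID_NT = set("ACGTN")
VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")
START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}

DEFAULT_MIN_ORF_LEN = 50       # aa; shortest reference protein is 55 aa
DEFAULT_MIN_COVERAGE = 0.70    # published filter: > 70% reference coverage
DEFAULT_MIN_COMPLETENESS = 0.50  # published filter: > 50% of the 9 genes
DEFAULT_MIN_IDENTITY = 0.35    # repo convention: rejects random local hits
DEFAULT_WINDOW = 5000          # nt between adjacent gene hits in one cluster
TRUNCATION_COVERAGE = 0.85     # hit coverage <= this => "truncated" flag
FRAGMENT_MIN_COVERAGE = 0.15   # smallest fragment considered for pseudogene rescue
FRAGMENT_MIN_IDENTITY = 0.60   # fragments must align tightly; true frameshift
                               # remnants match near the planting identity
PSEUDOGENE_REF_START = 5       # hits missing >= this many N-terminal reference
                               # residues indicate a broken (frameshifted) gene


@dataclass(frozen=True)
class ORF:
    """An open reading frame; coordinates 0-based half-open on the forward
    strand, stop codon included in the span when present."""

    contig: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str


@dataclass(frozen=True)
class HomologyHit:
    orf: ORF
    gene: str
    identity: float
    coverage: float
    score: float
    # genomic span of the aligned region (0-based half-open, forward strand);
    # tighter than the ORF span when the ORF extends into flanking sequence
    gene_start: int = 0
    gene_end: int = 0
    ref_start: int = 0  # first aligned reference residue (0-based)


@dataclass
class ClusterCall:
    contig: str
    span: tuple[int, int]
    hits: dict[str, HomologyHit | None]
    completeness: float
    anomalies: set[str] = field(default_factory=set)
    classification: str | None = None

    def present_genes(self) -> list[str]:
        return [g for g in GENE_ORDER if self.hits.get(g) is not None]


def _validate_contig(name: str, seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in VALID_NT:
            raise ValueError(f"invalid character {ch!r} in contig {name!r} at offset {i}")


def _translate(nt: str) -> str:
    """Standard-code translation of full codons; stop codons excluded."""
    aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    return aa.rstrip("*")


def _scan_frame(seq: str, frame: int) -> list[tuple[int, int]]:
    """Maximal ORFs in one forward frame: first start codon after each stop
    through the next stop (inclusive) or the contig edge."""
    orfs: list[tuple[int, int]] = []
    start: int | None = None
    i = frame
    n = len(seq)
    while i + 3 <= n:
        codon = seq[i:i + 3]
        if start is None:
            if codon in START_CODONS:
                start = i
        elif codon in STOP_CODONS:
            orfs.append((start, i + 3))
            start = None
        i += 3
    if start is not None:
        orfs.append((start, i))  # runs off the contig edge
    return orfs


def find_orfs(assembly: GenomeAssembly, min_orf_len: int = DEFAULT_MIN_ORF_LEN) -> list[ORF]:
    """Six-frame ORF scan with start codons ATG/GTG/TTG.

    Coordinates are reported on the forward strand, 0-based half-open;
    ``min_orf_len`` is the minimum translated length in amino acids.
    """
    if min_orf_len < 1:
        raise ValueError("min_orf_len must be >= 1")
    out: list[ORF] = []
    for name, seq in assembly.contigs.items():
        if not seq:
            continue
        _validate_contig(name, seq)
        n = len(seq)
        rc = str(Seq(seq).reverse_complement())
        for frame in range(3):
            for s, e in _scan_frame(seq, frame):
                aa = _translate(seq[s:e])
                if len(aa) >= min_orf_len:
                    out.append(ORF(name, s, e, "+", frame, aa))
            for s, e in _scan_frame(rc, frame):
                aa = _translate(rc[s:e])
                if len(aa) >= min_orf_len:
                    out.append(ORF(name, n - e, n - s, "-", frame, aa))
    out.sort(key=lambda o: (o.contig, o.start, o.end, o.strand))
    return out


def _make_aligner(mode: str, open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner

_LOCAL_ALIGNER = _make_aligner("local", 11.0, 1.0)


def _check_protein(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"empty {what} sequence")
    bad = set(seq) - VALID_AA
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in {what}")


def _align_local(query: str, ref: str
                 ) -> tuple[float, float, float, tuple[int, int], int]:
    """As :func:`align_proteins`, additionally returning the aligned query
    residue span ``(qstart, qend)`` and the first aligned reference residue."""
    _check_protein(query, "query")
    _check_protein(ref, "reference")
    alignments = _LOCAL_ALIGNER.align(ref, query)
    if len(alignments) == 0:  # no positive-scoring local alignment
        return 0.0, 0.0, 0.0, (0, 0), 0
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / columns if columns else 0.0
    ref_blocks, query_blocks = aln.aligned
    if len(ref_blocks) == 0:
        return 0.0, 0.0, 0.0, (0, 0), 0
    spanned = int(ref_blocks[-1][1] - ref_blocks[0][0])
    coverage = spanned / len(ref)
    # extrapolate the query span to the full reference extent (terminal
    # mismatches trimmed by the local alignment are re-included), clipped
    # to the query itself
    qs = int(query_blocks[0][0]) - int(ref_blocks[0][0])
    qe = int(query_blocks[-1][1]) + (len(ref) - int(ref_blocks[-1][1]))
    qspan = (max(qs, 0), min(qe, len(query)))
    return identity, coverage, float(aln.score), qspan, int(ref_blocks[0][0])


def align_proteins(query: str, ref: str) -> tuple[float, float, float]:
    """Smith-Waterman local alignment (BLOSUM62, gap open 11 / extend 1).

    Returns ``(identity, coverage, score)`` where identity is identical
    aligned pairs over alignment columns and coverage is the spanned
    reference residues over the reference length.  The highest-scoring
    alignment reported first by the aligner is used (deterministic).
    """
    identity, coverage, score, _, _ = _align_local(query, ref)
    return identity, coverage, score


def _genomic_span(orf: ORF, qspan: tuple[int, int]) -> tuple[int, int]:
    qs, qe = qspan
    # when the hit reaches the end of the translated ORF, include the stop
    # codon so spans line up with annotated gene coordinates
    tail = orf.end - orf.start - 3 * len(orf.protein) if qe == len(orf.protein) else 0
    if orf.strand == "+":
        return orf.start + 3 * qs, orf.start + 3 * qe + tail
    return orf.end - 3 * qe - tail, orf.end - 3 * qs


def score_orfs(
    orfs: list[ORF],
    references: dict[str, str] | None = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[list[HomologyHit], list[HomologyHit]]:
    """Best reference gene per ORF.

    Returns ``(passing, fragments)``: hits above the coverage filter, and
    sub-threshold fragments retained for pseudogene rescue.
    """
    if references is None:
        references = reference_proteins()
    passing: list[HomologyHit] = []
    fragments: list[HomologyHit] = []
    for orf in orfs:
        best: HomologyHit | None = None
        for gene, ref in references.items():
            identity, coverage, score, qspan, rstart = _align_local(orf.protein, ref)
            if best is None or score > best.score:
                gs, ge = _genomic_span(orf, qspan)
                best = HomologyHit(orf, gene, identity, coverage, score, gs, ge, rstart)
        if best is None or best.identity < min_identity:
            continue
        if best.coverage > min_coverage:
            passing.append(best)
        elif best.coverage >= FRAGMENT_MIN_COVERAGE and best.identity >= FRAGMENT_MIN_IDENTITY:
            fragments.append(best)
    return passing, fragments


def _has_internal_stop(hit: HomologyHit, assembly: GenomeAssembly,
                       references: dict[str, str]) -> bool:
    """Translate the hit's genomic span extended to the full reference
    length in the hit's frame; an internal stop marks a pseudogene."""
    ref_len = len(references[hit.gene])
    contig = assembly.contigs[hit.orf.contig]
    need = 3 * (ref_len + 1)
    if hit.orf.strand == "+":
        nt = contig[hit.orf.start: hit.orf.start + need]
    else:
        from .synth_genomes import revcomp
        nt = revcomp(contig[max(0, hit.orf.end - need): hit.orf.end])
    aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    return "*" in aa[:-1] or (aa.endswith("*") and len(aa) - 1 < ref_len)


def call_clusters(
    hits: list[HomologyHit],
    window: int = DEFAULT_WINDOW,
    fragments: list[HomologyHit] | None = None,
    assembly: GenomeAssembly | None = None,
    references: dict[str, str] | None = None,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
) -> list[ClusterCall]:
    """Group coverage-filtered hits into clusters and apply the published
    completeness and precursor rules.

    A group is emitted iff strictly more than ``min_completeness`` of the
    nine genes are present AND the precursor *elaA* is among them.  When the
    generating assembly and the fragment hits are supplied, sub-threshold
    fragments whose frame-extended translation carries an internal stop are
    rescued as pseudogenes (present, flagged).
    """
    if references is None:
        references = reference_proteins()
    fragments = fragments or []
    calls: list[ClusterCall] = []
    by_contig: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_contig.setdefault(h.orf.contig, []).append(h)
    for contig, contig_hits in sorted(by_contig.items()):
        contig_hits.sort(key=lambda h: h.orf.start)
        groups: list[list[HomologyHit]] = []
        for h in contig_hits:
            if groups and h.orf.start - groups[-1][-1].orf.end <= window:
                groups[-1].append(h)
            else:
                groups.append([h])
        for group in groups:
            best: dict[str, HomologyHit] = {}
            for h in group:
                if h.gene not in best or h.score > best[h.gene].score:
                    best[h.gene] = h
            anomalies: set[str] = set()
            lo = min(h.gene_start for h in best.values())
            hi = max(h.gene_end for h in best.values())
            # pseudogene rescue from sub-threshold fragments in the span
            if assembly is not None:
                for frag in fragments:
                    if frag.orf.contig != contig or frag.gene in best:
                        continue
                    if frag.orf.start > hi + window or frag.orf.end < lo - window:
                        continue
                    if _has_internal_stop(frag, assembly, references):
                        best[frag.gene] = frag
                        anomalies.add(f"pseudogene({frag.gene})")
            present = [g for g in GENE_ORDER if g in best]
            if len(present) / len(GENE_ORDER) <= min_completeness:
                continue
            if "elaA" not in best:
                continue
            lo = min(h.gene_start for h in best.values())
            hi = max(h.gene_end for h in best.values())
            strands = [best[g].orf.strand for g in present]
            majority = "+" if strands.count("+") >= strands.count("-") else "-"
            for g in present:
                h = best[g]
                if h.orf.strand != majority:
                    anomalies.add(f"reversed({g})")
                if f"pseudogene({g})" in anomalies:
                    continue
                if h.ref_start >= PSEUDOGENE_REF_START:
                    # reference N-terminus absent from the hit's frame:
                    # the gene is broken upstream (frameshift/internal stop)
                    anomalies.add(f"pseudogene({g})")
                elif DEFAULT_MIN_COVERAGE < h.coverage <= TRUNCATION_COVERAGE:
                    anomalies.add(f"truncated({g})")
            if majority == "-":
                anomalies.add("reversed_cluster")
            for g in GENE_ORDER:
                if g not in best:
                    anomalies.add(f"missing({g})")
            calls.append(ClusterCall(
                contig=contig,
                span=(lo, hi),
                hits={g: best.get(g) for g in GENE_ORDER},
                completeness=len(present) / len(GENE_ORDER),
                anomalies=anomalies,
            ))
    return calls


def mine_assembly(
    assembly: GenomeAssembly,
    references: dict[str, str] | None = None,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
    window: int = DEFAULT_WINDOW,
) -> list[ClusterCall]:
    """End-to-end screen of one assembly: ORFs -> hits -> cluster calls."""
    if references is None:
        references = reference_proteins()
    orfs = find_orfs(assembly, min_orf_len=min_orf_len)
    passing, fragments = score_orfs(orfs, references, min_coverage=min_coverage)
    return call_clusters(passing, window=window, fragments=fragments,
                         assembly=assembly, references=references,
                         min_completeness=min_completeness)


def classify_cluster(call: ClusterCall, catalogue: dict[str, dict[str, str]],
                     min_mean_identity: float = 0.95) -> tuple[str, str, float]:
    """Similarity typing: label of the catalogue entry with the highest mean
    per-gene identity over shared genes; "novel" below the identity floor.

    Returns ``(label, nearest_label, mean_identity)``; ties break by
    catalogue insertion order.
    """
    if not catalogue:
        raise ValueError("catalogue is empty")
    scored = [(g, h) for g, h in call.hits.items() if h is not None]
    if not scored:
        raise ValueError("cluster call has no scored genes")
    nearest, nearest_mean = None, -1.0
    for label, entry in catalogue.items():
        shared = [(g, h) for g, h in scored if g in entry]
        if not shared:
            continue
        mean_id = sum(align_proteins(h.orf.protein, entry[g])[0] for g, h in shared) / len(shared)
        if mean_id > nearest_mean:
            nearest, nearest_mean = label, mean_id
    if nearest is None:
        raise ValueError("no catalogue entry shares genes with the call")
    label = nearest if nearest_mean >= min_mean_identity else "novel"
    return label, nearest, nearest_mean


def calls_to_frame(calls: list[ClusterCall]) -> pd.DataFrame:
    """Tabular summary of cluster calls (one row per call)."""
    rows = []
    for i, c in enumerate(calls):
        rows.append({
            "cluster_id": i,
            "contig": c.contig,
            "start": c.span[0],
            "end": c.span[1],
            "completeness": c.completeness,
            "genes_present": ";".join(c.present_genes()),
            "anomalies": ";".join(sorted(c.anomalies)) or ".",
            "classification": c.classification or ".",
        })
    return pd.DataFrame(rows)


def calls_to_gff(calls: list[ClusterCall]) -> str:
    """GFF3-style feature lines (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for i, c in enumerate(calls):
        lines.append("\t".join([
            c.contig, "elasuite", "gene_cluster", str(c.span[0] + 1), str(c.span[1]),
            ".", ".", ".", f"ID=cluster{i};completeness={c.completeness:.2f}"]))
        for g in c.present_genes():
            h = c.hits[g]
            lines.append("\t".join([
                c.contig, "elasuite", "gene", str(h.gene_start + 1), str(h.gene_end),
                f"{h.score:.0f}", h.orf.strand, ".",
                f"ID=cluster{i}.{g};gene={g};identity={h.identity:.3f};coverage={h.coverage:.3f}"]))
    return "\n".join(lines) + "\n"
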