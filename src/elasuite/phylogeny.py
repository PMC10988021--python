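"""Concatenated-gene cluster phylogenies: concatenation rules, progressive
multiple alignment, p-distances and neighbor-joining.

The cluster tree is built from the concatenated coding sequences of the
cluster genes, with *elaO* omitted (it is absent from several natural
clusters) and markedly divergent clusters excluded before concatenation.
Maximum-likelihood inference is deliberately replaced by neighbor-joining
on p-distances: the claim of this package is the concatenation/omission
logic and topology recovery on planted data, not substitution-model
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference
from .synth_genomes import mutate_protein

DEFAULT_OMIT = frozenset({"elaO"})


@dataclass(frozen=True)
class ConcatenatedRecord:
    label: str
    sequence: str
    gene_order: tuple[str, ...]


def concatenate(
    sequences: dict[str, dict[str, str]],
    omit: set[str] | frozenset[str] = DEFAULT_OMIT,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> list[ConcatenatedRecord]:
    """Concatenate per-gene coding sequences in reference gene order.

    ``sequences`` maps cluster label -> {gene -> nucleotide sequence}.
    Genes in ``omit`` are dropped from every record; labels in ``exclude``
    are dropped entirely.  A gene missing from a retained cluster is
    concatenated as an all-gap slot of the reference CDS length, keeping
    columns positionally comparable.
    """
    labels = [lab for lab in sequences if lab not in exclude]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate cluster labels")
    order = tuple(g for g in reference.GENE_ORDER if g not in omit)
    ref_cds = reference.reference_cds()
    records = []
    for lab in labels:
        parts = []
        for gene in order:
            seq = sequences[lab].get(gene)
            parts.append(seq if seq else "-" * len(ref_cds[gene]))
        records.append(ConcatenatedRecord(lab, "".join(parts), order))
    return records


# ---------------------------------------------------------------------------
# progressive multiple alignment (k-mer guide tree + profile merging)

MATCH, MISMATCH, GAP = 1.0, -1.0, -2.0


def _pair_score(x: str, y: str) -> float:
    if x == "-" and y == "-":
        return 0.0
    if x == "-" or y == "-":
        return GAP
    return MATCH if x == y else MISMATCH


def _col_score(col_a: tuple[str, ...], col_b: tuple[str, ...]) -> float:
    return sum(_pair_score(x, y) for x in col_a for y in col_b) / (len(col_a) * len(col_b))


def _gap_cost(col: tuple[str, ...]) -> float:
    return sum(0.0 if x == "-" else GAP for x in col) / len(col)


def _align_profiles(pa: list[tuple[str, ...]], pb: list[tuple[str, ...]]
                    ) -> list[tuple[str, ...]]:
    """Needleman-Wunsch on two profiles (lists of columns)."""
    na, nb = len(pa), len(pb)
    width_a = len(pa[0]) if pa else 0
    width_b = len(pb[0]) if pb else 0
    score = np.zeros((na + 1, nb + 1))
    ptr = np.zeros((na + 1, nb + 1), dtype=np.int8)  # 0 diag, 1 up (gap in b), 2 left
    for i in range(1, na + 1):
        score[i, 0] = score[i - 1, 0] + _gap_cost(pa[i - 1])
        ptr[i, 0] = 1
    for j in range(1, nb + 1):
        score[0, j] = score[0, j - 1] + _gap_cost(pb[j - 1])
        ptr[0, j] = 2
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            diag = score[i - 1, j - 1] + _col_score(pa[i - 1], pb[j - 1])
            up = score[i - 1, j] + _gap_cost(pa[i - 1])
            left = score[i, j - 1] + _gap_cost(pb[j - 1])
            best = max(diag, up, left)
            score[i, j] = best
            ptr[i, j] = 0 if best == diag else (1 if best == up else 2)
    merged: list[tuple[str, ...]] = []
    i, j = na, nb
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == 0:
            merged.append(pa[i - 1] + pb[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and p == 1:
            merged.append(pa[i - 1] + ("-",) * width_b)
            i -= 1
        else:
            merged.append(("-",) * width_a + pb[j - 1])
            j -= 1
    merged.reverse()
    return merged


def _kmer_distance(a: str, b: str, k: int = 4) -> float:
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    union = ka | kb
    return 1.0 - len(ka & kb) / len(union) if union else 0.0


def align_msa(records: list[ConcatenatedRecord] | list[str]) -> list[str]:
    """Progressive multiple alignment.

    Guide order from k-mer distances (closest pairs merged first, UPGMA
    agglomeration); profiles merged by pairwise Needleman-Wunsch with
    match +1 / mismatch -1 / gap -2.  Removing gaps from any output row
    recovers the corresponding input sequence exactly.
    """
    seqs = [r.sequence if isinstance(r, ConcatenatedRecord) else r for r in records]
    if len(seqs) < 2:
        raise ValueError("multiple alignment needs >= 2 records")
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(seqs[i], seqs[j])
    # UPGMA agglomeration over active clusters; each cluster carries its
    # profile and the member row indices (to restore input order at the end)
    clusters: list[tuple[list[int], list[tuple[str, ...]]]] = [
        ([i], [(c,) for c in s]) for i, s in enumerate(seqs)]
    cdist = dist.copy()
    active = list(range(n))
    while len(active) > 1:
        best_pair, best_d = None, np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                if cdist[i, j] < best_d:
                    best_d, best_pair = cdist[i, j], (i, j)
        i, j = best_pair
        members = clusters[i][0] + clusters[j][0]
        profile = _align_profiles(clusters[i][1], clusters[j][1])
        # reorder profile rows to match member order bookkeeping
        clusters[i] = (members, profile)
        ni, nj = len(clusters[i][0]), 0  # sizes folded into UPGMA update below
        for k_ in active:
            if k_ not in (i, j):
                cdist[i, k_] = cdist[k_, i] = (cdist[i, k_] + cdist[j, k_]) / 2.0
        active.remove(j)
    members, profile = clusters[active[0]]
    rows = ["".join(col[r] for col in profile) for r in range(len(members))]
    out = [""] * n
    for pos, orig in enumerate(members):
        out[orig] = rows[pos]
    return out


# ---------------------------------------------------------------------------
# distances and neighbor-joining

def p_distance_matrix(rows: list[str]) -> np.ndarray:
    """Pairwise p-distances over an alignment, skipping columns where either
    row has a gap."""
    n = len(rows)
    arr = np.array([list(r) for r in rows])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            total = int(ok.sum())
            if total == 0:
                d = 0.0
            else:
                d = float((arr[i][ok] != arr[j][ok]).sum()) / total
            dist[i, j] = dist[j, i] = d
    return dist


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None,
                 children: list[tuple["_Node", float]] | None = None):
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{ln:.6f}" for c, ln in self.children)
        return f"({inner})"

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset({self.label})
        out: set[str] = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root node) with non-negative branch
    lengths; negative neighbor-joining estimates are clamped to zero and
    flagged."""

    root: _Node
    labels: tuple[str, ...]
    clamped: bool = False

    @property
    def newick(self) -> str:
        return self.root.newick() + ";"

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-side leaf set
        (both sides included for simple membership checks)."""
        all_leaves = self.root.leaves()
        out: set[frozenset[str]] = set()

        def visit(node: _Node) -> None:
            for child, _ in node.children:
                side = child.leaves()
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(side)
                    out.add(all_leaves - side)
                visit(child)

        visit(self.root)
        return out


def nj_tree(dist: np.ndarray, labels: list[str] | None = None) -> PhyloTree:
    """Neighbor-joining with deterministic lowest-index tie-breaking.

    On additive distance matrices the generating topology and branch
    lengths are recovered exactly.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(dist)) > 1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    if n < 3:
        raise ValueError("neighbor-joining needs >= 3 taxa")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    clamped = False

    nodes: list[_Node] = [_Node(lab) for lab in labels]
    idx = list(range(n))  # active indices into d
    d = dist.copy()

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(idx) > 3:
        m = len(idx)
        r = {i: sum(d[i, k] for k in idx if k != i) for i in idx}
        best, best_q = None, np.inf
        for ai, i in enumerate(idx):
            for j in idx[ai + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        new = _Node(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        # reuse slot i for the new node
        for k in idx:
            if k not in (i, j):
                d[i, k] = d[k, i] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        d[i, i] = 0.0
        nodes[i] = new
        idx.remove(j)

    a, b, c = idx
    la = clamp((d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = clamp((d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = clamp((d[a, c] + d[b, c] - d[a, b]) / 2.0)
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root=root, labels=tuple(labels), clamped=clamped)


def cluster_tree(records: list[ConcatenatedRecord]) -> PhyloTree:
    """Full pipeline: align (if needed), p-distance, neighbor-joining."""
    if len(records) < 3:
        raise ValueError("need >= 3 records for a tree")
    labels = [r.label for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate record labels")
    lengths = {len(r.sequence) for r in records}
    rows = ([r.sequence for r in records] if len(lengths) == 1
            else align_msa(records))
    dist = p_distance_matrix(rows)
    return nj_tree(dist, [r.label for r in records])


# ---------------------------------------------------------------------------
# planted horizontal-transfer scenario

def simulate_transfer_records(
    seed: int,
    n_lineages: int = 3,
    per_lineage: int = 3,
    lineage_divergence: float = 0.25,
    tip_divergence: float = 0.02,
) -> tuple[list[ConcatenatedRecord], dict[str, str], dict[str, str]]:
    """Cluster sequences copied across species backgrounds.

    Each cluster lineage descends from its own diverged ancestor; tips of a
    lineage are assigned to different "species" backgrounds round-robin, so
    grouping by cluster lineage and grouping by species are different
    partitions of the same leaves.  Returns ``(records, lineage_of,
    species_of)``.
    """
    rng = np.random.default_rng(seed)
    ref = reference.reference_proteins()
    order = [g for g in reference.GENE_ORDER if g != "elaO"]
    sequences: dict[str, dict[str, str]] = {}
    lineage_of: dict[str, str] = {}
    species_of: dict[str, str] = {}
    species_names = [f"sp{j}" for j in range(per_lineage)]
    for li in range(n_lineages):
        ancestors = {g: "M" + mutate_protein(ref[g][1:], lineage_divergence, rng)
                     for g in order}
        for ti in range(per_lineage):
            label = f"L{li}_{species_names[ti]}_{ti}"
            tip = {g: reference.back_translate(
                "M" + mutate_protein(ancestors[g][1:], tip_divergence, rng))
                for g in order}
            sequences[label] = tip
            lineage_of[label] = f"L{li}"
            species_of[label] = species_names[ti]
    records = concatenate(sequences, omit=DEFAULT_OMIT)
    return records, lineage_of, species_of
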