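# Methods

This note documents the models, conventions and numerical choices behind
`elasuite`, and what its synthetic benchmarks do and do not demonstrate
about real data.

## Reference cluster and synthetic genomes

The epilancin biosynthetic gene cluster comprises nine genes: the precursor
peptide (*elaA*), a protease (*elaP*), a transporter (*elaT*), the
dehydratase (*elaB*), the cyclase (*elaC*), the protease/oxidoreductase
installing the N-terminal lactate (*elaO*) and three putative immunity
proteins (*elaI1–3*). The bundled reference (`elasuite.reference`) is
**synthetic**: producer-strain sequences are only available from external
archives, so the package generates deterministic pseudo-random proteins
with realistic per-gene lengths (55–980 aa, ~9.3 kbp total span with 50-nt
spacers) and a hand-designed 25+30-residue precursor whose core carries the
canonical epilancin topology. All pipeline logic treats these sequences
exactly as it would real ones; swapping in real sequences only requires
passing a different `references` mapping.

Synthetic assemblies (`synth_genomes`) embed the cluster in i.i.d. uniform
ACGT flanks (2 kb per side by default; no decoy genes, keeping truth tables
exact). Back-translation uses a fixed most-frequent-codon table for a
low-GC staphylococcal genome; nucleotide realism is irrelevant to the
protein-level screen. Divergence is planted by substituting a
`round(d·L)` subset of positions (uniform among the 19 alternatives), so
realized identity is 1−d up to rounding; the initiator Met is preserved so
the planted ORF start survives. Anomalies mirror naturally observed cluster
variants: gene deletion, truncation, single-gene reversal, whole-cluster
reversal, and frameshifts. A frameshift deletes one nucleotide at the
stated codon; the generator verifies a premature stop arises in the
original frame before the gene end (forcing one in the rare seed where the
shifted sequence contains none), so the planted "pseudogene" is always
observable.

## Mining screen

`find_orfs` scans all six frames for maximal ORFs (starts ATG/GTG/TTG,
standard code, stop codon included in the reported span, coordinates
0-based half-open on the forward strand). `align_proteins` performs
Smith–Waterman local alignment with BLOSUM62 and gap open 11 / extend 1
(the classic protein-screen parameterization), delegating the dynamic
programming to Biopython's `PairwiseAligner`; identity is identical pairs
over alignment columns, coverage is the spanned reference residues over
the reference length. Tests verify the scores against an independent
exhaustive Gotoh recursion. Hit genomic spans are extrapolated to the full
reference extent (clipped to the ORF) so terminal mismatches trimmed by
the local alignment do not shift reported gene coordinates; planted genes
are recovered to within ±3 nt at divergence ≤ 0.3.

Filters follow the published screen verbatim: hits require coverage
> 0.70; a group of hits within 5 000 nt of each other on one contig is
emitted as a cluster call iff strictly more than 50% of the nine genes are
present **and** *elaA* is among them. Additional conventions of this
implementation:

* best hits additionally require 35% identity, rejecting random local
  matches from flanking sequence;
* a hit with coverage in (0.70, 0.85] is flagged `truncated`;
* a hit whose alignment misses ≥ 5 N-terminal reference residues, or a
  sub-threshold fragment (coverage ≥ 0.15, identity ≥ 0.60) whose
  frame-extended translation contains an internal stop, marks the gene as a
  `pseudogene` — counted as *present with anomaly* (the screen's
  completeness definition does not otherwise say how broken genes count;
  this is the package's documented interpretation);
* strand anomalies: a hit on the minority strand is `reversed(gene)`; a
  minority-"+" cluster is `reversed_cluster`.

Very late frameshifts (coverage > 0.85 in the unbroken frame) are
indistinguishable from intact genes under these rules and are not flagged;
this is a known limitation.

`classify_cluster` types a call by the catalogue entry maximizing mean
per-gene identity over shared genes, with "novel" below 0.95 and ties
broken by catalogue insertion order.

## Maturation and mass model

The modification set (dehydrated positions, rings, lactate, Abu,
methylations) is an *input*, mirroring how predicted structures are
asserted rather than inferred from sequence. Validation enforces: Ser/Thr
at dehydrated positions, Cys acceptors used at most once, donor before
acceptor, MeLan from Thr and Lan from Ser, lactate only on a dehydrated
position-1 Ser. Chemistry bookkeeping per residue: dehydration −H₂O; ring
formation (thioether Michael addition) atomically neutral; Abu +H₂ on a
dehydrated Thr; methylation +CH₂; lactyl capping replaces the N-terminal
Dha residue plus its amine proton with CH₃–CH(OH)–CO– (net residue
composition C₃H₄O₂, validated in tests against a hand-counted
lactyl-glycine formula). Masses sum residue compositions plus one water,
with IUPAC 2021 average weights or principal-isotope masses; tests
cross-check against pyteomics. Ring-topology segments merge rings with
overlapping spans into one system, so the reference core reports
11 + 5 + 3 + 5 + 6 = 30 — the intertwined 4-membered rings share interior
residues.

`percent_similarity` uses global Needleman–Wunsch (BLOSUM62, gap 10/0.5);
similarity counts positively scoring pairs over alignment length. The
field reports "percent similarity" without naming a tool; this convention
is the package's documented choice.

## Phylogeny

Concatenation uses the reference gene order with *elaO* omitted by default
(it is absent from several natural clusters); markedly divergent cluster
labels can be excluded up front. Missing genes in retained clusters become
all-gap slots of the reference CDS length, keeping columns positionally
comparable. The progressive MSA builds a k-mer-distance (k = 4 Jaccard)
UPGMA guide order and merges profiles by Needleman–Wunsch with match +1 /
mismatch −1 / gap −2; it is intended for short-to-moderate inputs, and the
pipeline skips it entirely when all concatenations already share one
length (the generator's default case). Trees come from classic
neighbor-joining on p-distances (gap-containing columns skipped pairwise):
Q-matrix selection with lowest-index tie-breaking, negative branch
estimates clamped to zero and flagged, final three nodes joined by the
three-point formulas. Maximum-likelihood inference is deliberately out of
scope — the claim here is the concatenation/omission logic and topology
recovery on planted data, not substitution-model selection. NJ is exact on
additive matrices and is cross-checked against scikit-bio in tests.

The horizontal-transfer scenario plants `n_lineages` cluster ancestors at
25% divergence from the reference, with tips at 2% divergence assigned
round-robin to "species" backgrounds; grouping by lineage and by species
are then different partitions of the same leaves, and the benchmark asserts
lineage monophyly (and absence of species monophyly) in the inferred tree.

## Synthetic microscopy

Scenes use Airyscan-like sampling (0.05 µm/px) and coryneform rod
dimensions (length 1.5–3 µm, width 0.6–0.9 µm). Cells are spherocylinders;
optional membrane shells are 0.1 µm thick; spots are 2-D Gaussians
(σ = 0.08 µm) placed in the cell frame. The ideal image is blurred with an
isotropic Gaussian PSF (default σ = 0.07 µm) and then corrupted with
Poisson and/or Gaussian noise; truth masks, per-cell means and spot
positions are recorded from the pre-noise image, making the generator the
oracle for the quantification modules. Septa are not modelled separately;
"near septum" localization is represented by midcell-proximal planted
spots. Two-channel scenes build channel B as
`coloc·A_structure + (1−coloc)·independent` with a PSF-smoothed random
field of matched variance as the independent part; the recorded expected
Pearson correlation is computed from the two pre-noise images over the
cell masks. GUVs are annuli centered on the nominal radius (the membrane
midline) with independent interior/exterior levels.

What passing these closures does *not* show: robustness to real-world
segmentation hazards (dense colonies, debris, uneven illumination,
out-of-focus light), PSF anisotropy, or chromatic misregistration. The
generator's cells never overlap and its noise is spatially white.

## Quantification conventions

Segmentation: Otsu threshold → hole filling → per-component
distance-transform watershed seeded from "cores" (pixels deeper than 50%
of the component's maximum depth) → area filter (≥ 50 px). A lone rod has
one connected core and stays whole; cells touching through a neck split.
Labels are ordered row-major by centroid. Cell length/width come from the
second-moment ellipse axes, so measured length slightly exceeds planted
tip-to-tip length conventions; folded coordinates therefore allow values
up to ~1.2. Per-cell intensity subtracts the median of out-of-mask pixels
and clamps at zero. Spot detection smooths with a σ = 1 px Gaussian, takes
in-mask local maxima, and keeps those whose prominence (smoothed peak
minus the owning cell's median) is ≥ `min_prominence` × that median
(default 1.0, chosen so 5× planted amplitudes survive PSF attenuation
while uniform cells yield none); maxima within 2 px merge, keeping the
brighter. Spot coordinates are exported both signed (µm along/across the
axis from the centroid) and folded (|Δlong|/(L/2), |Δtrans|/(W/2)) because
the plotted convention in published figures is ambiguous.

GUV analysis fits the membrane circle algebraically (Kasa least squares on
a thresholded Sobel edge map) and refines center and radius by hill
climbing the mean on-circle intensity on grids down to 0.25 px. Profiles
average 720 bilinear-interpolated rays at integer offsets −50..+50 px from
the fitted radius (ray averaging is this package's choice; per-GUV single
lines are equally consistent with published descriptions), clip below the
center, and normalize to their own maximum.

## Assay statistics

MIC is the lowest concentration of a two-fold series without growth
(OD > 0.05 counts as growth when ODs are given); growth everywhere reports
">max"; replicate disagreement reports the range "a–b" (the consolidation
convention is this package's choice); non-monotone patterns are flagged
and the MIC placed above the last growth. DiSC summaries use a tolerance
of 2% of the trace's dynamic range: baseline is the mean of the last 5
pre-addition minutes (flagged if unstable), the plateau is the first
post-addition time whose forward 2-minute window stays within tolerance,
release is plateau minus baseline. The t-test is Student's pooled-variance
unpaired two-tailed test (matching the stated convention; Welch behind a
flag) with a 95% CI of the mean difference. Star bins: ns ≥ 0.05;
* (0.01, 0.05); ** (0.001, 0.01]; *** (0.0001, 0.001]; **** ≤ 0.0001 —
boundaries go to the more significant bin except exactly 0.05, which is
"ns" (documented convention for the ambiguous legend boundary).

## Problem sizes and determinism

The benchmark sizes are chosen as the package's own test conditions: 50
random planted clusters for the mining precision/recall suite, 100 seeded
runs for transfer grouping, 2 000 simulated null pairs (n = 20 each) for
the p-value uniformity check, 16–24-cell scenes at 512² px for imaging
closure, and 12 vesicles per group for the scaled-down GUV shrinkage power
check. Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`), and identical seeds reproduce byte-identical
generator output.
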