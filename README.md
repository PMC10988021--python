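# elasuite

Epilancins are staphylococcal lantibiotics — ribosomally synthesized,
posttranslationally modified peptides carrying lanthionine rings and an
N-terminal lactate cap. Studying one of them end-to-end involves a chain of
computational steps: mining bacterial genome assemblies for the nine-gene
epilancin biosynthetic gene cluster (*elaA/P/T/B/C/O/I1/I2/I3*), modelling
precursor maturation and predicting the mature peptide mass, building
phylogenies of the clusters to detect horizontal transfer, and quantifying
single-cell fluorescence microscopy (uptake, spot formation, colocalization,
vesicle profiles) along with the accompanying plate-assay statistics.

`elasuite` re-implements that chain as a tested, reusable Python library.
Because the original imaging data and strain genomes are not bundled here,
every stage ships with a synthetic-data generator that plants known ground
truth (gene coordinates, modification sets, cell masks, spot positions,
colocalization fractions, vesicle geometry), so the whole pipeline is
exercisable and verifiable offline.

## What's inside

| Module | Role |
| --- | --- |
| `synth_genomes` | Assemblies with planted (possibly diverged/broken) clusters + truth tables |
| `bgc_mining` | Six-frame ORF calling, Smith–Waterman homology screen (BLOSUM62, gap 11/1), coverage > 70% and completeness > 50% filters, precursor-exclusion rule, anomaly annotation, similarity typing |
| `maturation` | Leader cleavage, Dha/Dhb dehydrations, Lan/MeLan rings, N-terminal lactate, Abu, methylations; average & monoisotopic masses from atomic compositions |
| `phylogeny` | Gene concatenation (with *elaO* omitted), progressive MSA, p-distances, neighbor-joining with exact recovery on additive matrices |
| `synth_images` | Rod-shaped cells with membrane/cytoplasm signal and planted spots, two-channel colocalization scenes, GUV rings — all with truth objects |
| `cell_quant` | Segmentation (Otsu + distance-transform watershed), per-cell intensities, prominence-filtered spot detection, normalized cell-frame coordinates |
| `coloc_guv` | Per-cell Pearson correlation, GUV circle fitting, −50..+50 px membrane-centered radial profiles, diameter comparisons |
| `assays_stats` | MIC calling with ">max"/range semantics, DiSC trace summaries, inhibition-zone and competition arithmetic, pooled-variance t-test with 95% CI and star bins |

The key statistics and models:

* **Homology screen.** ORFs from all six frames (starts ATG/GTG/TTG) are
  aligned to the nine reference proteins by local alignment; hits need
  reference coverage > 0.70, and a cluster call needs > 50% of genes present
  *and* the precursor *elaA* — assemblies without it are rejected.
* **Mass model.** mass = Σ residue compositions + H₂O, with each dehydration
  −H₂O, ring formation mass-neutral, lactate capping replacing the
  N-terminal Dha + amine proton with a lactyl group (net residue C₃H₄O₂) and
  each methylation +CH₂. Both IUPAC average and monoisotopic modes.
* **Neighbor joining.** Classic Q-matrix agglomeration on p-distances,
  lowest-index tie-breaking, negative branch estimates clamped to zero;
  exact on additive matrices.
* **Statistics.** Unpaired two-tailed Student's t (pooled variance; Welch
  optional) with 95% CI and the star binning ns / * / ** / *** / ****.

## Worked example

```python
from elasuite.synth_genomes import ClusterSpec, Anomaly, generate_assembly
from elasuite.bgc_mining import mine_assembly
from elasuite.maturation import ModificationSet, apply_maturation, peptide_mass
from elasuite import reference as R

# Plant a cluster whose immunity gene elaI2 carries a frameshift, then mine it
spec = ClusterSpec(seed=5, anomalies=(Anomaly("frameshift", "elaI2", 40),))
assembly, truth = generate_assembly(spec)
call = mine_assembly(assembly)[0]
print(call.completeness, sorted(call.anomalies))
# 1.0 ['pseudogene(elaI2)']

# Mature the bundled reference core and predict its mass
mods = ModificationSet(dehydrations=R.DEFAULT_DEHYDRATIONS,
                       rings=R.DEFAULT_RINGS, lactate=True)
mature = apply_maturation(R.CORE_SEQ, mods)
print(mature.segments)
# [('linear', 11), ('ring', 5), ('linear', 3), ('ring', 5), ('linear', 6)]
print(round(peptide_mass(mature, "average"), 2))
# 3132.81
```

The cluster call reports the frameshifted immunity gene as a pseudogene but
still counts it as present (completeness 1.0). The matured core shows the
epilancin topology — an 11-residue linear N-terminus, ring A, a 3-residue
hinge, the intertwined double-ring system and the C-terminal tail — and its
predicted average mass in daltons.

A thin CLI mirrors the main flows, e.g.:

```bash
elasuite synth-genome --seed 3 -o out/
elasuite mine --assembly out/assembly.fna -o out/
elasuite mature
elasuite ttest --a 1,2,3,4 --b 5,6,7,8
```

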