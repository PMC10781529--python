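# lagenaria

Dominant-marker diversity analysis for a panel of ten Egyptian bottle
gourd (*Lagenaria siceraria*) cultivars (S1–S10), built as a reusable
package plus a set of analysis drivers. It covers the full desk
analysis of three marker systems — SDS-PAGE protein bands, POD/PPO
isozymes, and SCoT PCR fingerprints — from scored band matrices to
dendrograms:

* **Band matrices** — loci × genotypes presence/absence grids with
  per-locus metadata (assay, primer/enzyme, band size), read and
  written as plain CSV/TSV; intensity grades (+/++/+++) collapse to
  presence; multi-assay pooling aligns genotypes by label.
* **Marker statistics** — band frequency p, locus classes
  (monomorphic / polymorphic / unique-positive M+ / unique-negative
  M−), polymorphism percentages, genotype-specific marker tables, and
  per-primer informativeness: PIC = mean 2p(1−p), EMR = PBN·(PBN/TBN),
  MI = PIC·EMR, Rp = Σ(1 − 2|0.5 − p|).
* **Similarity** — Jaccard a/(a+b+c) (plus Dice and simple matching),
  with extremes reports.
* **Clustering** — UPGMA on d = 1 − s with deterministic tie-breaking,
  Newick export, cophenetic distances, k-cluster cuts.
* **Synthetic data** — a seedable generator of band matrices with
  planted clusters and planted unique markers for truth-known
  validation.

The published band matrices and reference tables of the study are
packaged under `src/lagenaria/data/` and everything downstream is
recomputed from them.

## Worked example

```python
from lagenaria import datasets, jaccard, pool, collapse_intensity
from lagenaria.markerstats import polymorphism_percent, genotype_specific_markers
from lagenaria.similarity import similarity_report
from lagenaria.clustering import upgma, to_newick

protein = datasets.protein_sds_page()          # 17 bands x 10 cultivars
print(round(polymorphism_percent(protein), 2)) # 29.41
print(genotype_specific_markers(protein))
#   genotype  polarity     group  size_label
# 0       S8  negative  SDS-PAGE       126.0
# 1       S8  negative  SDS-PAGE       100.0
# 2       S6  negative  SDS-PAGE        23.0
# 3       S2  negative  SDS-PAGE        11.0

pooled = pool([protein,
               collapse_intensity(datasets.isozyme_pod()),
               collapse_intensity(datasets.isozyme_ppo())])
rep = similarity_report(jaccard(pooled))       # 27 pooled loci
print(round(rep.min_value, 3), rep.min_pairs)  # 0.778 [('S2', 'S8')]

print(to_newick(upgma(datasets.scot_similarity()))[:40])
# (((S1:0.1047,((S10:0.066,(S5:0.0555,S7:0
```

The 29.41% is the protein polymorphism percentage (5 of 17 bands);
the four negative markers are bands absent from exactly one cultivar
each, usable as fingerprints; 0.778 is the lowest pooled
protein+isozyme similarity (S2 vs S8); the Newick tree's first merge
is (S5, S7), the most similar pair (0.889) in the SCoT fingerprints.

A command-line interface mirrors the stages:

```bash
lagenaria reproduce                 # recompute all published numbers (38 checks)
lagenaria summarize --input src/lagenaria/data/protein_sds_page.csv
lagenaria tree --similarity-file src/lagenaria/data/scot_similarity.csv --cut 2
lagenaria simulate --seed 7 --out sim.csv
```

The numbered scripts under `analysis/` run the full study narrative
(protein profile, isozymes and pooling, SCoT diversity, synthetic
validation, reproduction report) and write their tables under
`results/`.

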