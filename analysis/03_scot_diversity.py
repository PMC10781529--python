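#!/usr/bin/env python
"""SCoT marker diversity: per-primer summary, genotype-specific
markers, similarity extremes, and the UPGMA dendrogram.

The 44-band SCoT presence/absence matrix itself was not published;
the per-primer counts, the unique-marker list and the Jaccard matrix
are the available data. This script aggregates the counts, recomputes
the index values the standard dominant-marker formulas yield from
those counts, reports the similarity extremes, and builds the tree.

Finding: 44 bands, 22 polymorphic (50% overall; the mean of the
per-primer percentages is 45.15). Similarity spans 0.675 (S5 vs S9)
to 0.889 (S5 vs S7), and S5/S7 are accordingly the first UPGMA merge.
Note the published per-primer EMR/Rp/MI values are not consistent
with any standard formula (e.g. a fully monomorphic primer with
EMR 2.5 and Rp 5); the recomputed column shows the standard values.
"""

from pathlib import Path

import pandas as pd

from lagenaria import datasets
from lagenaria.clustering import cut, to_newick, upgma
from lagenaria.markerstats import emr_group
from lagenaria.similarity import round_half_up, similarity_report

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

scot = datasets.scot_primer_counts()
total_tbn = int(scot["tbn"].sum())
total_pbn = int(scot["pbn"].sum())
print(f"SCoT: {total_tbn} bands over {len(scot)} primers, {total_pbn} polymorphic")
print(f"  overall polymorphism: {round_half_up(100 * total_pbn / total_tbn, 2)}%")
print(f"  mean of per-primer percentages: {round_half_up(scot['p_pct'].mean(), 2)}%")

scot_out = scot.copy()
scot_out["emr_standard"] = [
    round_half_up(emr_group(t, p), 2) for t, p in zip(scot["tbn"], scot["pbn"])
]
scot_out.to_csv(OUT / "scot_primer_summary.csv", index=False)

markers = datasets.scot_unique_markers()
print("genotype-specific SCoT markers:")
for r in markers.itertuples():
    print(f"  {r.genotype}: {r.polarity} marker, {r.group} at {r.size_label} bp")

s = datasets.scot_similarity()
rep = similarity_report(s)
print(
    f"similarity: min {round_half_up(rep.min_value, 3)} at {rep.min_pairs}, "
    f"max {round_half_up(rep.max_value, 3)} at {rep.max_pairs}"
)

tree = upgma(s)
nwk = to_newick(tree)
(OUT / "scot_upgma.nwk").write_text(nwk + "\n")
print(f"UPGMA: {nwk}")
for k in (2, 3):
    blocks = [",".join(sorted(b)) for b in cut(tree, k)]
    print(f"  k={k} cut: {blocks}")
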