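#!/usr/bin/env python
"""UPGMA cluster analysis: dual dendrograms, seriation and the k=2 patient cut.

Clusters the 768 antigens and the 10 plasma samples with UPGMA on Euclidean
distances over log reactivities, cuts the sample tree at k=2, and compares
the two sample clusters with the planted low/high antibody-level patient
groups.  Writes Newick trees and cluster assignments under results/ and the
heatmap PNG under scratch/figures/.
"""

import sys
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

sys.path.insert(0, str(Path(__file__).parent))
from common import FIGURES, RESULTS, load_cohort  # noqa: E402

from seroarray import clustering, normalize  # noqa: E402


def main() -> None:
    design, arrays, meta, (_, patient_truth) = load_cohort()
    _, cohort = normalize.normalize_cohort(arrays, design, meta)
    pl = cohort.fluid_columns("PL")

    ant_tree = clustering.upgma(clustering.euclidean_distances(pl, "antigens"))
    smp_tree = clustering.upgma(clustering.euclidean_distances(pl, "samples"))
    print("sample dendrogram leaf order:", " ".join(smp_tree.leaf_order))

    cut = clustering.cut_tree(smp_tree, 2)
    members = {}
    for sid, c in cut.items():
        members.setdefault(c, []).append(sid[:-2])
    for c, pats in sorted(members.items()):
        levels = {patient_truth[p] for p in pats}
        print(f"  cluster {c}: {sorted(pats)} (planted level: {sorted(levels)})")
    ari = adjusted_rand_score(
        [patient_truth[s[:-2]] for s in cut], [cut[s] for s in cut]
    )
    print(f"adjusted Rand index vs planted groups: {ari:.2f}")

    RESULTS.mkdir(exist_ok=True)
    FIGURES.mkdir(parents=True, exist_ok=True)
    paths = clustering.heatmap_export(pl, ant_tree, smp_tree, FIGURES / "heatmap", png=True)
    (RESULTS / "antigen_tree.nwk").write_text(clustering.to_newick(ant_tree) + "\n")
    (RESULTS / "sample_tree.nwk").write_text(clustering.to_newick(smp_tree) + "\n")
    pd.Series(cut, name="cluster").rename_axis("sample_id").to_csv(
        RESULTS / "sample_clusters.tsv", sep="\t"
    )
    print(f"wrote trees and clusters to {RESULTS}; heatmap to {paths['png']}")


if __name__ == "__main__":
    main()
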