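#!/usr/bin/env python
"""Classify antigens by plasma-vs-synovial-fluid fold change.

Applies the 1.45-fold / 10% rules to the per-fluid mean log reactivities,
compares the calls against the planted ground truth, and flags per-patient
outlier antibodies.  Writes results/differential_calls.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, load_cohort  # noqa: E402

from seroarray import differential, normalize  # noqa: E402


def main() -> None:
    design, arrays, meta, (ant_truth, _) = load_cohort()
    _, cohort = normalize.normalize_cohort(arrays, design, meta)
    table = differential.differential_table(cohort)

    counts = table["category"].value_counts().to_dict()
    print("differential calls over", len(table), "antigens:", counts)
    rec = differential.category_recovery(table, ant_truth)
    print("planted-category recovery (called-as-planted / planted):",
          {k: f"{v}/{int((ant_truth == k).sum())}" for k, v in rec.items()})

    top = table.head(3)
    print("strongest PL-enriched antigens:")
    for _, row in top.iterrows():
        print(f"  {row.antigen_id}: ratio {row.ratio:.2f} "
              f"(mean log10 PL {row.mean_pl:.3f} vs SF {row.mean_sf:.3f})")

    outliers = differential.patient_outliers(cohort)
    n_out = {p: len(v) for p, v in outliers.items()}
    print("per-patient outlier antibodies (|PL-SF| > 3 robust sd):", n_out)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "differential_calls.tsv"
    differential.write_differential_table(table, out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
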