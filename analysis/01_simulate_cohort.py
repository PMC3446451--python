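#!/usr/bin/env python
"""Simulate the study cohort and write it to disk as spot tables.

Generates one synthetic cohort at the default study-condition preset —
768 antigens printed in duplicate plus controls and nonspots, probed with
paired plasma (PL) and synovial-fluid (SF) samples from 10 patients — and
writes the array design, the 20 per-array spot tables, sample metadata and
the planted ground truth under scratch/cohort/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import COHORT_SEED, ensure_cohort, load_cohort  # noqa: E402


def main() -> None:
    out = ensure_cohort()
    design, arrays, meta, (ant_truth, patient_truth) = load_cohort()
    print(f"cohort written to {out} (seed {COHORT_SEED})")
    print(f"  {design.n_antigens} antigens in duplicate; "
          f"{len(design.features)} spots per array")
    print(f"  {len(arrays)} arrays: "
          f"{sum(m.fluid == 'PL' for m in meta)} PL + "
          f"{sum(m.fluid == 'SF' for m in meta)} SF")
    counts = ant_truth.value_counts()
    print("  planted antigens:",
          {k: int(counts.get(k, 0)) for k in ("pl_higher", "sf_higher", "similar")})
    print("  patient groups:", patient_truth.value_counts().to_dict())


if __name__ == "__main__":
    main()
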