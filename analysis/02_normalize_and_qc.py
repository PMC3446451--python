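#!/usr/bin/env python
"""Normalize every array and measure reproducibility correlations.

Background-subtracts (first quartile of the nonspots), log10-transforms and
collapses duplicates on all 20 arrays, then computes the intra-array
duplicate-spot correlation per array and the per-patient PL/SF correlation
of collapsed values.  Writes results/qc_summary.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, load_cohort  # noqa: E402

from seroarray import normalize, qc  # noqa: E402


def main() -> None:
    design, arrays, meta, _ = load_cohort()
    normalized, cohort = normalize.normalize_cohort(arrays, design, meta)
    report = qc.qc_summary(normalized, cohort)

    print(f"normalized {len(normalized)} arrays "
          f"({cohort.values.shape[0]} collapsed antigen values each)")
    bgs = [a.background for a in normalized]
    print(f"  background estimates: {min(bgs):.1f}-{max(bgs):.1f} raw units; "
          f"floored antigen spots: {sum(a.n_floored for a in normalized)}")
    lo, hi = report.range_duplicate_r
    print(f"  duplicate-spot correlation: mean r = {report.mean_duplicate_r:.3f} "
          f"(range {lo:.3f}-{hi:.3f}, n = {len(report.per_sample_duplicate_r)})")
    lo, hi = report.range_fluid_r
    print(f"  PL/SF correlation:          mean r = {report.mean_fluid_r:.3f} "
          f"(range {lo:.3f}-{hi:.3f}, n = {len(report.per_patient_fluid_r)})")

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "qc_summary.json"
    out.write_text(json.dumps(report.to_dict(), indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
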