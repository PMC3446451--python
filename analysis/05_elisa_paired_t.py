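#!/usr/bin/env python
"""ELISA verification stage on a synthetic plate: paired t-test of PL vs SF.

Simulates a single-antigen ELISA plate (duplicate wells for each of the 10
paired patient fluids, with a planted plasma-ward shift), averages the
duplicate absorbances and runs the two-sided paired t-test.  Writes
results/elisa_ttest.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import COHORT_SEED, RESULTS  # noqa: E402

from seroarray import elisa, synthetic  # noqa: E402


def main() -> None:
    plate = synthetic.simulate_plate(seed=COHORT_SEED)
    means = elisa.mean_absorbance(plate).unstack("fluid")
    print(f"duplicate-mean A450 over {len(means)} patients: "
          f"PL {means['PL'].mean():.3f} vs SF {means['SF'].mean():.3f}")
    res = elisa.plate_t_test(plate)
    print(f"paired t-test: t = {res.t:.3f}, df = {res.df}, "
          f"two-sided P = {res.p_two_sided:.4f}")

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "elisa_ttest.json"
    out.write_text(json.dumps(res.to_dict(), indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
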