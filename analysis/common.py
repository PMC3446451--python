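"""Shared paths and cohort loading for the numbered analysis scripts."""

from __future__ import annotations

from pathlib import Path

from seroarray import array_io, synthetic

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
FIGURES = ROOT / "scratch" / "figures"

COHORT_SEED = 42


def ensure_cohort() -> Path:
    """Simulate and write the study cohort if it is not on disk yet."""
    if not (COHORT_DIR / "design.tsv").exists():
        sim = synthetic.generate_cohort(synthetic.study_preset(COHORT_SEED))
        (COHORT_DIR / "spots").mkdir(parents=True, exist_ok=True)
        array_io.write_design(sim.design, COHORT_DIR / "design.tsv")
        for table in sim.arrays:
            array_io.write_spot_table(table, COHORT_DIR / "spots" / f"{table.sample_id}.tsv")
        array_io.write_sample_meta(sim.meta, COHORT_DIR / "meta.tsv")
        synthetic.truth_report(sim.truth, COHORT_DIR / "truth.tsv")
    return COHORT_DIR


def load_cohort():
    ensure_cohort()
    design = array_io.read_design(COHORT_DIR / "design.tsv")
    meta = array_io.read_sample_meta(COHORT_DIR / "meta.tsv")
    arrays = [
        array_io.read_spot_table(
            COHORT_DIR / "spots" / f"{m.sample_id}.tsv", design, sample_id=m.sample_id
        )
        for m in meta
    ]
    truth = synthetic.load_truth_report(COHORT_DIR / "truth.tsv")
    return design, arrays, meta, truth
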