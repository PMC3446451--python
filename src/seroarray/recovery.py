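"""Parameter-recovery evaluations of the full pipeline on preset cohorts.

These helpers generate cohorts at a study-condition preset, push them
through normalization and the downstream modules, and measure how well the
pipeline recovers the quantities the generator planted: the duplicate and
inter-fluid correlation set-points, the planted differential categories,
and the planted patient groups.  They back both the test suite and the
results-reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import clustering, differential, qc, synthetic
from .normalize import normalize_cohort


def cohort_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2^31) derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _preset_cohort(seed: int, preset=None):
    cfg = preset(seed) if preset else synthetic.study_preset(seed)
    sim = synthetic.generate_cohort(cfg)
    normalized, cohort = normalize_cohort(sim.arrays, sim.design, sim.meta)
    return sim, normalized, cohort


@dataclass
class CorrelationRecovery:
    per_array_duplicate_r: list[float]  # all arrays, all cohorts
    cohort_mean_duplicate_r: list[float]
    cohort_mean_fluid_r: list[float]

    @property
    def grand_mean_duplicate_r(self) -> float:
        return float(np.mean(self.cohort_mean_duplicate_r))

    @property
    def grand_mean_fluid_r(self) -> float:
        return float(np.mean(self.cohort_mean_fluid_r))


def correlation_recovery(seeds: list[int], preset=None) -> CorrelationRecovery:
    """Duplicate- and fluid-correlation estimates over preset cohorts."""
    per_array, dup_means, fluid_means = [], [], []
    for seed in seeds:
        _, normalized, cohort = _preset_cohort(seed, preset)
        report = qc.qc_summary(normalized, cohort)
        per_array.extend(report.per_sample_duplicate_r.values())
        dup_means.append(report.mean_duplicate_r)
        fluid_means.append(report.mean_fluid_r)
    return CorrelationRecovery(per_array, dup_means, fluid_means)


def differential_recovery(seeds: list[int], preset=None) -> list[bool]:
    """Whether each cohort's planted categories are recovered exactly."""
    exact = []
    for seed in seeds:
        sim, _, cohort = _preset_cohort(seed, preset)
        table = differential.differential_table(cohort)
        rec = differential.category_recovery(table, sim.truth.antigen_categories)
        cfg = sim.truth.config
        exact.append(
            rec
            == {
                "pl_higher": cfg.n_pl_higher,
                "sf_higher": cfg.n_sf_higher,
                "similar": cfg.n_similar,
            }
        )
    return exact


def clustering_recovery(seeds: list[int], fluid: str = "PL", preset=None) -> list[float]:
    """ARI between the k=2 sample-tree cut and planted patient groups."""
    scores = []
    for seed in seeds:
        sim, _, cohort = _preset_cohort(seed, preset)
        dm = clustering.euclidean_distances(cohort.fluid_columns(fluid), axis="samples")
        cut = clustering.cut_tree(clustering.upgma(dm), 2)
        truth = [sim.truth.patient_groups[s[: -len(fluid)]] for s in cut]
        scores.append(adjusted_rand_score(truth, [cut[s] for s in cut]))
    return scores
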