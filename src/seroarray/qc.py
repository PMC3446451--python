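"""Reproducibility and cross-fluid correlation QC.

Two correlations summarize array quality: the intra-array correlation
between the two printed replicates of every antigen (computed on per-spot
normalized values, before duplicate collapse), and the per-patient
correlation between the plasma and synovial-fluid reactivity vectors
(computed on collapsed per-antigen values).  Pearson correlation on the
log scale is the default; Spearman is available as a sensitivity option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .normalize import CohortMatrix, NormalizedArray


def pearson_r(x, y, method: str = "pearson") -> float:
    """Sample correlation of two equal-length vectors.

    Returns NaN (with a warning) when either vector has zero variance, where
    the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def duplicate_pairs(array: NormalizedArray) -> np.ndarray:
    """(n_antigens, 2) matrix of replicate-0 / replicate-1 normalized values."""
    ant = array.spots[array.spots["feature_class"] == "antigen"]
    wide = ant.pivot_table(
        index="feature_id", columns="replicate_index", values="normalized"
    )
    if 0 not in wide.columns or 1 not in wide.columns:
        raise ValueError("array has no duplicate spots")
    return wide[[0, 1]].dropna().to_numpy()


def duplicate_correlation(array: NormalizedArray, method: str = "pearson") -> float:
    """Intra-array correlation of duplicate antigen spots (pre-collapse)."""
    pairs = duplicate_pairs(array)
    if len(pairs) < 3:
        raise ValueError("fewer than 3 complete duplicate pairs")
    return pearson_r(pairs[:, 0], pairs[:, 1], method=method)


def fluid_correlation(
    cohort: CohortMatrix, patient_id: str, method: str = "pearson"
) -> float | None:
    """PL-vs-SF correlation of collapsed antigen values for one patient.

    Returns None (with a warning) if the patient lacks either fluid.
    """
    pair = cohort.patient_pair(patient_id)
    if pair is None:
        warnings.warn(f"patient {patient_id} lacks a PL/SF pair", stacklevel=2)
        return None
    pair = pair.dropna()
    return pearson_r(pair["PL"], pair["SF"], method=method)


@dataclass
class CorrelationReport:
    per_sample_duplicate_r: dict[str, float]
    mean_duplicate_r: float
    range_duplicate_r: tuple[float, float]
    per_patient_fluid_r: dict[str, float]
    mean_fluid_r: float
    range_fluid_r: tuple[float, float]

    def to_dict(self) -> dict:
        return asdict(self)


def qc_summary(
    arrays: list[NormalizedArray],
    cohort: CohortMatrix,
    method: str = "pearson",
) -> CorrelationReport:
    """Per-array duplicate correlations and per-patient fluid correlations."""
    dup = {a.sample_id: duplicate_correlation(a, method) for a in arrays}
    fluid = {}
    for pid in cohort.patients:
        r = fluid_correlation(cohort, pid, method)
        if r is not None:
            fluid[pid] = r
    dv = np.array(list(dup.values()))
    fv = np.array(list(fluid.values()))
    return CorrelationReport(
        per_sample_duplicate_r=dup,
        mean_duplicate_r=float(dv.mean()),
        range_duplicate_r=(float(dv.min()), float(dv.max())),
        per_patient_fluid_r=fluid,
        mean_fluid_r=float(fv.mean()) if fv.size else float("nan"),
        range_fluid_r=(
            (float(fv.min()), float(fv.max())) if fv.size else (float("nan"),) * 2
        ),
    )
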