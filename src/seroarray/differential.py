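"""Fold-change classification of antigens between plasma and synovial fluid.

For each antigen the per-fluid mean of collapsed log reactivities is taken
over patients and the difference back-transformed into a PL/SF fold change
(a geometric-mean ratio).  Antigens are then binned by two thresholds:

* ``pl_higher``  — ratio strictly greater than the fold threshold (1.45,
  i.e. a >45% difference favouring plasma);
* ``sf_higher``  — ratio strictly below its reciprocal;
* ``similar``    — ratio within +/-10% of unity (strictly);
* ``unclassified`` — the band in between.

A 1.45-fold change and a 45% difference are the same rule under this ratio
definition.  This is a fold-change filter, not a hypothesis test: no
p-values and no multiple-testing correction are involved, and calls should
be read as a screening shortlist, not as significance statements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import CohortMatrix

CATEGORIES = ("pl_higher", "sf_higher", "similar", "unclassified")


@dataclass(frozen=True)
class DifferentialCall:
    antigen_id: str
    mean_pl: float
    mean_sf: float
    ratio: float  # back-transformed fold change PL/SF
    category: str


def classify_ratio(
    ratio: float, fold_threshold: float = 1.45, similar_threshold: float = 1.10
) -> str:
    if not (fold_threshold > 1 and similar_threshold > 1):
        raise ValueError("thresholds must exceed 1")
    if not np.isfinite(ratio) or ratio <= 0:
        return "unclassified"
    if ratio > fold_threshold:
        return "pl_higher"
    if ratio < 1.0 / fold_threshold:
        return "sf_higher"
    if max(ratio, 1.0 / ratio) < similar_threshold:
        return "similar"
    return "unclassified"


def classify_antigen(
    mean_pl: float,
    mean_sf: float,
    fold_threshold: float = 1.45,
    similar_threshold: float = 1.10,
    log_base: float = 10.0,
    antigen_id: str = "",
) -> DifferentialCall:
    """Classify one antigen from its per-fluid mean log reactivities."""
    if not (np.isfinite(mean_pl) and np.isfinite(mean_sf)):
        return DifferentialCall(antigen_id, mean_pl, mean_sf, float("nan"), "unclassified")
    ratio = float(log_base ** (mean_pl - mean_sf))
    return DifferentialCall(
        antigen_id, float(mean_pl), float(mean_sf), ratio,
        classify_ratio(ratio, fold_threshold, similar_threshold),
    )


def differential_table(
    cohort: CohortMatrix,
    fold_threshold: float = 1.45,
    similar_threshold: float = 1.10,
    log_base: float = 10.0,
    max_missing_frac: float = 0.5,
) -> pd.DataFrame:
    """One call per antigen, sorted by descending PL/SF ratio.

    Antigens missing in more than *max_missing_frac* of either fluid's
    samples are left unclassified with a warning.
    """
    pl = cohort.fluid_columns("PL")
    sf = cohort.fluid_columns("SF")
    mean_pl = pl.mean(axis=1)
    mean_sf = sf.mean(axis=1)
    too_missing = (pl.isna().mean(axis=1) > max_missing_frac) | (
        sf.isna().mean(axis=1) > max_missing_frac
    )
    if too_missing.any():
        warnings.warn(
            f"{int(too_missing.sum())} antigen(s) missing in >50% of samples; "
            "left unclassified",
            stacklevel=2,
        )

    diff = mean_pl - mean_sf
    ratio = np.power(log_base, diff)
    cats = [
        "unclassified" if tm else classify_ratio(r, fold_threshold, similar_threshold)
        for r, tm in zip(ratio, too_missing)
    ]
    out = pd.DataFrame(
        {
            "antigen_id": mean_pl.index,
            "mean_pl": mean_pl.to_numpy(),
            "mean_sf": mean_sf.to_numpy(),
            "ratio": ratio.to_numpy(),
            "category": cats,
        }
    )
    return out.sort_values("ratio", ascending=False).reset_index(drop=True)


def category_recovery(table: pd.DataFrame, truth_categories: pd.Series) -> dict[str, int]:
    """Per-category count of planted antigens recovered in their category.

    *truth_categories* maps antigen id -> planted category (background
    antigens carry the label ``background`` and are ignored here).
    """
    called = table.set_index("antigen_id")["category"]
    out = {}
    for cat in ("pl_higher", "sf_higher", "similar"):
        planted = truth_categories[truth_categories == cat].index
        out[cat] = int((called.reindex(planted) == cat).sum())
    return out


def patient_outliers(
    cohort: CohortMatrix, k_mad: float = 3.0
) -> dict[str, list[str]]:
    """Per-patient antigens with an extreme PL-SF log difference.

    An antigen is flagged when its |PL - SF| difference deviates from the
    patient's median difference by more than *k_mad* scaled median absolute
    deviations (MAD x 1.4826, consistent with a normal sigma).  This
    formalizes the scatter-plot outliers: antibodies detected at much
    higher levels in one fluid within a specific individual.
    """
    out: dict[str, list[str]] = {}
    for pid in cohort.patients:
        pair = cohort.patient_pair(pid)
        if pair is None:
            continue
        d = (pair["PL"] - pair["SF"]).dropna()
        med = d.median()
        mad = float((d - med).abs().median()) * 1.4826
        if mad == 0:
            out[pid] = []
            continue
        flagged = d[(d - med).abs() > k_mad * mad]
        out[pid] = sorted(flagged.index)
    return out


def write_differential_table(table: pd.DataFrame, path) -> None:
    """TSV export with the published category headings alongside codes."""
    from .array_io import CATEGORY_LABELS

    df = table.copy()
    df["category_label"] = df["category"].map(
        lambda c: CATEGORY_LABELS.get(c, "Unclassified")
    )
    for col in ("mean_pl", "mean_sf", "ratio"):
        df[col] = df[col].round(4)
    df.to_csv(path, sep="\t", index=False)
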