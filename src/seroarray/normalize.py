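"""Per-array normalization of spot volumes.

The normalized volume of a spot is computed per array by (1) estimating the
array background as the first quartile of the nonspot signals, (2)
subtracting it from every raw volume, and (3) log-transforming the result,
with values at or below the background clamped to a positive floor before
the log.  Duplicate antigen spots are collapsed to one reactivity per
antigen by averaging the log values.

Conventions pinned here: the first quartile uses linear interpolation
between order statistics (numpy's default); the log base is 10 and the
floor is one raw-volume unit.  The base only rescales log values and never
reorders them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import ArrayDesign, SampleMeta, SpotTable


@dataclass(frozen=True)
class NormalizeConfig:
    floor: float = 1.0  # raw-volume units; clamp before log
    log_base: float = 10.0
    background_quantile: float = 0.25

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        if not 0 < self.background_quantile < 1:
            raise ValueError("background quantile must be in (0, 1)")


DEFAULT_CONFIG = NormalizeConfig()


def estimate_background(nonspot_volumes, quantile: float = 0.25) -> float:
    """First quartile of the nonspot raw volumes (linear interpolation)."""
    v = np.asarray(nonspot_volumes, dtype=float)
    if v.size == 0:
        raise ValueError("no nonspot volumes; cannot estimate background")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite nonspot volume")
    return float(np.quantile(v, quantile))


def normalize_spot(
    raw_volume: float, background: float, floor: float = 1.0, log_base: float = 10.0
) -> tuple[float, bool]:
    """log(max(raw - background, floor)); returns (value, was_floored)."""
    if not np.isfinite(raw_volume) or not np.isfinite(background):
        raise ValueError("non-finite input to normalize_spot")
    if floor <= 0:
        raise ValueError("floor must be positive")
    net = raw_volume - background
    floored = net <= floor
    return float(_log(max(net, floor), log_base)), bool(floored)


def _log(x, base: float):
    if base == 10.0:
        return np.log10(x)
    if base == 2.0:
        return np.log2(x)
    return np.log(x) / np.log(base)


def collapse_duplicates(values) -> float:
    """Arithmetic mean of the available duplicate log values (1 or 2).

    An antigen with no surviving spots is 'missing' and yields NaN; callers
    decide how to treat missingness.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    return float(v.mean())


@dataclass
class NormalizedArray:
    """Log-normalized reactivities for one probed array.

    ``spots`` holds per-spot normalized values (all classes, pre-collapse;
    duplicate-reproducibility QC runs on these).  ``collapsed`` is the
    per-antigen mean of duplicate log values, indexed by antigen id, one
    entry per antigen in the design.  Control spots are normalized too but
    reported separately and never enter antigen statistics; ``n_floored``
    counts clamped antigen spots only (nonspots and empty-vector controls
    sit at background level and clamp by construction).
    """

    sample_id: str
    background: float
    spots: pd.DataFrame  # feature_id, feature_class, replicate_index, normalized
    collapsed: pd.Series
    n_floored: int
    config: NormalizeConfig = field(default=DEFAULT_CONFIG)

    @property
    def control_summary(self) -> pd.DataFrame:
        ctrl = self.spots[self.spots["feature_class"] != "antigen"]
        return (
            ctrl.groupby("feature_class")["normalized"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


def normalize_array(
    spots: SpotTable, design: ArrayDesign | None = None,
    config: NormalizeConfig = DEFAULT_CONFIG,
) -> NormalizedArray:
    """Background-subtract, log-transform and collapse one spot table.

    *design* is accepted for interface symmetry but the spot table already
    carries its design join; flagged-excluded spots are dropped before any
    statistic.
    """
    df = spots.data
    df = df[df["flag"] == "ok"]
    ns = df.loc[df["feature_class"] == "nonspot", "raw_volume"].to_numpy()
    background = estimate_background(ns, config.background_quantile)

    net = df["raw_volume"].to_numpy(dtype=float) - background
    floored = net <= config.floor
    vals = _log(np.maximum(net, config.floor), config.log_base)
    out = df[["feature_id", "feature_class", "replicate_index"]].copy()
    out["normalized"] = vals

    ant_mask = (df["feature_class"] == "antigen").to_numpy()
    ant = out[out["feature_class"] == "antigen"]
    collapsed = ant.groupby("feature_id")["normalized"].mean()
    if design is not None:
        collapsed = collapsed.reindex(design.antigen_ids)
    collapsed.name = spots.sample_id

    return NormalizedArray(
        sample_id=spots.sample_id,
        background=background,
        spots=out.reset_index(drop=True),
        collapsed=collapsed,
        n_floored=int((floored & ant_mask).sum()),
        config=config,
    )


@dataclass
class CohortMatrix:
    """Antigens x samples matrix of collapsed reactivities plus metadata.

    ``values``: DataFrame indexed by antigen id, one column per sample id.
    ``samples``: DataFrame with sample_id, patient_id, fluid.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("sample metadata does not match matrix columns")

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.samples["patient_id"]))

    def fluid_columns(self, fluid: str) -> pd.DataFrame:
        ids = self.samples.loc[self.samples["fluid"] == fluid, "sample_id"]
        return self.values[list(ids)]

    def patient_pair(self, patient_id: str) -> pd.DataFrame | None:
        """PL and SF columns for one patient, or None if either is absent."""
        sub = self.samples[self.samples["patient_id"] == patient_id]
        by_fluid = dict(zip(sub["fluid"], sub["sample_id"]))
        if "PL" not in by_fluid or "SF" not in by_fluid:
            return None
        return self.values[[by_fluid["PL"], by_fluid["SF"]]].set_axis(
            ["PL", "SF"], axis=1
        )


def build_cohort(
    arrays: list[NormalizedArray], meta: list[SampleMeta]
) -> CohortMatrix:
    """Assemble collapsed per-antigen vectors into a cohort matrix."""
    meta_by_id = {m.sample_id: m for m in meta if m.fluid is not None}
    cols, rows = [], []
    for arr in arrays:
        m = meta_by_id.get(arr.sample_id)
        if m is None:
            raise ValueError(f"no sample metadata for array {arr.sample_id}")
        cols.append(arr.collapsed)
        rows.append(
            {"sample_id": m.sample_id, "patient_id": m.patient_id, "fluid": m.fluid}
        )
    values = pd.concat(cols, axis=1)
    return CohortMatrix(values=values, samples=pd.DataFrame(rows))


def normalize_cohort(
    arrays: list[SpotTable],
    design: ArrayDesign,
    meta: list[SampleMeta],
    config: NormalizeConfig = DEFAULT_CONFIG,
) -> tuple[list[NormalizedArray], CohortMatrix]:
    normalized = [normalize_array(a, design, config) for a in arrays]
    return normalized, build_cohort(normalized, meta)
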