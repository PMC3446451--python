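"""Reading and writing spot-quantification tables, array designs and metadata.

The on-disk dialect is tab-separated text with a mandatory header, decimal
point, no thousands separators.  Grid coordinates are 0-based
``(block, row, col)`` triples.  The in-memory model is a single spot-table
schema; an adapter (:func:`read_spot_table_mapped`) renames columns from
quantification-software exports (GenePix/ArrayPro style) into it.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

FEATURE_CLASSES = (
    "antigen",
    "positive_control",
    "negative_control",
    "registration",
    "nonspot",
)

POSITION_COLS = ["block", "row", "col"]
DESIGN_COLS = ["feature_id", "feature_class", "replicate_index"] + POSITION_COLS


class ArrayIOError(ValueError):
    """Malformed design or spot table."""


@dataclass
class ArrayDesign:
    """Printed layout of one array: which feature sits at which position.

    ``features`` has columns ``feature_id, feature_class, replicate_index,
    block, row, col``.  Antigens are expected in duplicate
    (``replicate_index`` 0 and 1); deviations are recorded in ``qc_warnings``
    rather than rejected, because real print runs drop pins.
    """

    features: pd.DataFrame
    qc_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.features
        missing = [c for c in DESIGN_COLS if c not in df.columns]
        if missing:
            raise ArrayIOError(f"design missing columns: {missing}")
        bad = set(df["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise ArrayIOError(f"unknown feature classes: {sorted(bad)}")
        dup = df.duplicated(subset=POSITION_COLS)
        if dup.any():
            pos = df.loc[dup, POSITION_COLS].itertuples(index=False)
            raise ArrayIOError(
                "duplicate grid positions: "
                + ", ".join(str(tuple(p)) for p in pos)
            )
        if not (df["feature_class"] == "nonspot").any():
            raise ArrayIOError(
                "design has no nonspot features; background cannot be estimated"
            )
        counts = df[df["feature_class"] == "antigen"]["feature_id"].value_counts()
        odd = counts[counts != 2]
        for fid, n in odd.items():
            msg = f"antigen {fid} printed with {n} replicate(s), expected 2"
            self.qc_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)

    @property
    def antigen_ids(self) -> list[str]:
        ids = self.features.loc[
            self.features["feature_class"] == "antigen", "feature_id"
        ]
        return sorted(ids.unique())

    @property
    def n_antigens(self) -> int:
        return len(self.antigen_ids)


@dataclass
class SpotTable:
    """Quantified spot volumes for one probed array, joined to its design."""

    sample_id: str
    data: pd.DataFrame  # DESIGN_COLS + raw_volume, flag

    def __post_init__(self) -> None:
        df = self.data
        if "flag" not in df.columns:
            df = df.assign(flag="ok")
            self.data = df
        if not df["flag"].isin(["ok", "excluded"]).all():
            raise ArrayIOError("flag must be 'ok' or 'excluded'")
        vols = df["raw_volume"]
        if not pd.api.types.is_numeric_dtype(vols) or not vols.map(
            lambda v: v == v and abs(v) != float("inf")
        ).all():
            raise ArrayIOError("raw volumes must be finite numbers")
        if (vols < 0).any():
            n = int((vols < 0).sum())
            raise ArrayIOError(f"{n} negative raw volume(s)")


@dataclass
class SampleMeta:
    """Clinical metadata for one patient sample.

    ``fluid`` is ``"PL"``/``"SF"`` for a probed array, or ``None`` for a
    patient-level demographics record.
    """

    patient_id: str
    fluid: str | None = None
    subtype: str | None = None  # oligo / extended_oligo / poly
    sex: str | None = None
    age_years: float | None = None
    wbc: float | None = None
    esr_mm_hr: float | None = None
    crp_mg_l: float | None = None
    rf: float | str | None = None
    ana_titer: str | None = None

    @property
    def sample_id(self) -> str:
        if self.fluid is None:
            return self.patient_id
        return f"{self.patient_id}{self.fluid}"


def read_design(path: str | Path) -> ArrayDesign:
    """Read a TSV array design; validates positions, classes and duplicates."""
    df = pd.read_csv(path, sep="\t")
    return ArrayDesign(df[DESIGN_COLS].copy())


def write_design(design: ArrayDesign, path: str | Path) -> None:
    design.features.to_csv(path, sep="\t", index=False)


def read_spot_table(
    path: str | Path, design: ArrayDesign, sample_id: str | None = None
) -> SpotTable:
    """Read one array's spot volumes and join them 1:1 onto *design*.

    Every design position must be present exactly once; orphan rows (positions
    not in the design) and missing positions are hard errors naming the
    offending coordinates.
    """
    raw = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return join_spots(raw, design, sample_id or _infer_sample_id(raw, path))


def read_spot_table_mapped(
    path: str | Path,
    design: ArrayDesign,
    column_map: dict[str, str],
    sample_id: str | None = None,
) -> SpotTable:
    """Import adapter for third-party quantification exports.

    *column_map* maps source column names to the internal schema, e.g.
    ``{"Block": "block", "Row": "row", "Column": "col", "Volume": "raw_volume"}``.
    """
    raw = pd.read_csv(path, sep="\t", float_precision="round_trip").rename(
        columns=column_map
    )
    return join_spots(raw, design, sample_id or _infer_sample_id(raw, path))


def _infer_sample_id(df: pd.DataFrame, path: str | Path) -> str:
    if "sample_id" in df.columns:
        ids = df["sample_id"].unique()
        if len(ids) == 1:
            return str(ids[0])
    return Path(path).stem


def join_spots(raw: pd.DataFrame, design: ArrayDesign, sample_id: str) -> SpotTable:
    """Join raw (block,row,col,raw_volume[,flag]) rows onto a design."""
    need = POSITION_COLS + ["raw_volume"]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise ArrayIOError(f"spot table missing columns: {missing}")
    cols = need + (["flag"] if "flag" in raw.columns else [])
    merged = design.features.merge(
        raw[cols], on=POSITION_COLS, how="outer", indicator=True
    )
    orphans = merged[merged["_merge"] == "right_only"]
    if len(orphans):
        pos = [tuple(int(v) for v in p) for p in orphans[POSITION_COLS].values]
        raise ArrayIOError(f"spot rows at positions not in design: {pos}")
    absent = merged[merged["_merge"] == "left_only"]
    if len(absent):
        pos = [tuple(int(v) for v in p) for p in absent[POSITION_COLS].values]
        raise ArrayIOError(f"design positions missing from spot table: {pos}")
    return SpotTable(sample_id, merged.drop(columns="_merge"))


def write_spot_table(table: SpotTable, path: str | Path) -> None:
    """Write a spot table; volumes at full float precision so that a
    write/read round-trip is the identity on values and positions."""
    df = table.data.copy()
    df.insert(0, "sample_id", table.sample_id)
    df["raw_volume"] = df["raw_volume"].map(lambda v: f"{v:.17g}")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures: the published differential-antibody list and the
# patient demographics table.
# ---------------------------------------------------------------------------

CATEGORY_LABELS = {
    "pl_higher": "Higher in PL (> 45%)",
    "sf_higher": "Higher in SF (> 45%)",
    "similar": "Similar levels in PL and SF (< 10%)",
}
LABEL_TO_CATEGORY = {v: k for k, v in CATEGORY_LABELS.items()}


def _fixture_path(name: str):
    return resources.files("seroarray.data").joinpath(name)


def fixture_sha256(name: str) -> str:
    return hashlib.sha256(_fixture_path(name).read_bytes()).hexdigest()


def load_table1_fixture() -> pd.DataFrame:
    """The published 36-entry differential autoantibody list.

    Columns: ``autoantigen, uniprot, gene, category, category_label`` where
    ``category`` is the machine code (pl_higher / sf_higher / similar) and
    ``category_label`` the printed heading.
    """
    with resources.as_file(
        _fixture_path("table1_differential_antibodies.tsv")
    ) as p:
        df = pd.read_csv(p, sep="\t")
    df = df.rename(columns={"category": "category_label"})
    df["category"] = df["category_label"].map(LABEL_TO_CATEGORY)
    if df["category"].isna().any():
        raise ArrayIOError("unrecognized category label in fixture")
    return df[["autoantigen", "uniprot", "gene", "category", "category_label"]]


def load_table2_fixture() -> list[SampleMeta]:
    """The 10-patient demographics table as patient-level SampleMeta records."""
    with resources.as_file(
        _fixture_path("table2_patient_demographics.tsv")
    ) as p:
        df = pd.read_csv(p, sep="\t")
    out = []
    for rec in df.to_dict("records"):
        rf = rec["rf"]
        try:
            rf = float(rf)
        except (TypeError, ValueError):
            pass  # "Negative"
        out.append(
            SampleMeta(
                patient_id=str(rec["patient_id"]),
                fluid=None,
                subtype=str(rec["subtype"]),
                sex=str(rec["sex"]),
                age_years=float(rec["age_years"]),
                wbc=float(rec["wbc"]),
                esr_mm_hr=float(rec["esr_mm_hr"]),
                crp_mg_l=float(rec["crp_mg_l"]),
                rf=rf,
                ana_titer=str(rec["ana_titer"]),
            )
        )
    return out


def write_sample_meta(meta: Iterable[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in meta:
        rows.append(
            {
                "sample_id": m.sample_id,
                "patient_id": m.patient_id,
                "fluid": m.fluid if m.fluid is not None else "",
                "subtype": m.subtype,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        SampleMeta(
            patient_id=str(r["patient_id"]),
            fluid=str(r["fluid"]) or None,
            subtype=str(r.get("subtype", "")) or None,
        )
        for _, r in df.iterrows()
    ]
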