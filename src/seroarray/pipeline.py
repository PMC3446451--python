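"""End-to-end pipeline orchestration: normalize -> QC -> differential -> clustering.

A run reads a cohort (design + one spot table per array + sample metadata),
applies per-array normalization, computes the correlation QC report, the
fold-change differential table and UPGMA trees over antigens and samples,
and writes everything to a run directory together with a manifest carrying
the configuration hash and package versions, so any run can be reproduced
from its own output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import array_io, clustering, differential, elisa, normalize, qc


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the calibration values."""

    design: str = "design.tsv"
    spots_dir: str = "spots"
    meta: str = "meta.tsv"
    elisa_plate: str | None = None
    out_dir: str = "run"
    fold_threshold: float = 1.45
    similar_threshold: float = 1.10
    background_quantile: float = 0.25
    log_base: float = 10.0
    floor: float = 1.0
    correlation: str = "pearson"
    rank_transform: bool = False
    cluster_fluid: str = "PL"  # samples clustered within this fluid
    k_sample_clusters: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_cohort(config: RunConfig):
    design_path = Path(config.design)
    if not design_path.exists():
        raise FileNotFoundError(f"design file not found: {design_path}")
    design = array_io.read_design(design_path)
    meta = array_io.read_sample_meta(config.meta)
    arrays = []
    for m in meta:
        p = Path(config.spots_dir) / f"{m.sample_id}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"spot table not found: {p}")
        arrays.append(array_io.read_spot_table(p, design, sample_id=m.sample_id))
    return design, arrays, meta


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure aborts with the stage name and the underlying cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        design, arrays, meta = load_cohort(config)

        stage = "normalize"
        ncfg = normalize.NormalizeConfig(
            floor=config.floor,
            log_base=config.log_base,
            background_quantile=config.background_quantile,
        )
        normalized, cohort = normalize.normalize_cohort(arrays, design, meta, ncfg)
        cohort.values.round(4).to_csv(out / "collapsed.tsv", sep="\t")

        stage = "qc"
        report = qc.qc_summary(normalized, cohort, method=config.correlation)
        qc_block = report.to_dict()
        qc_block["per_array"] = {
            a.sample_id: {"background": a.background, "n_floored": a.n_floored}
            for a in normalized
        }
        (out / "qc.json").write_text(json.dumps(qc_block, indent=2))

        stage = "differential"
        table = differential.differential_table(
            cohort,
            fold_threshold=config.fold_threshold,
            similar_threshold=config.similar_threshold,
            log_base=config.log_base,
        )
        differential.write_differential_table(table, out / "differential.tsv")
        outliers = differential.patient_outliers(cohort)
        (out / "patient_outliers.json").write_text(json.dumps(outliers, indent=2))

        stage = "clustering"
        d_ant = clustering.euclidean_distances(
            cohort, axis="antigens", rank_transform=config.rank_transform
        )
        ant_tree = clustering.upgma(d_ant)
        sample_matrix = cohort.fluid_columns(config.cluster_fluid)
        d_smp = clustering.euclidean_distances(
            sample_matrix, axis="samples", rank_transform=config.rank_transform
        )
        smp_tree = clustering.upgma(d_smp)
        (out / "trees.nwk").write_text(
            clustering.to_newick(ant_tree) + "\n" + clustering.to_newick(smp_tree) + "\n"
        )
        cuts = clustering.cut_tree(smp_tree, config.k_sample_clusters)
        pd.Series(cuts, name="cluster").rename_axis("sample_id").to_csv(
            out / "sample_clusters.tsv", sep="\t"
        )

        if config.elisa_plate:
            stage = "elisa"
            plate = elisa.read_plate(config.elisa_plate)
            res = elisa.plate_t_test(plate)
            (out / "elisa.json").write_text(json.dumps(res.to_dict(), indent=2))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "seroarray_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "n_arrays": len(arrays),
        "n_antigens": design.n_antigens,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
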