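"""Synthetic cohort generator with the statistical structure the pipeline assumes.

Cohorts emulate a duplicate-spotted 768-antigen array probed with paired
plasma (PL) and synovial-fluid (SF) samples from a small cohort.  The
hierarchical signal model lives on the log10 scale and is exponentiated to
raw volumes on top of an additive background:

    z_ij    = mu_j + g_i + u_ij          patient i, antigen j
    y_ijf   = z_ij + delta_jf + e_ijf    fluid f
    spot    = y_ijf + eps_r              printed replicate r in {0, 1}

``mu_j`` is the antigen baseline, ``g_i`` a group shift splitting patients
into low/high global-antibody groups, ``u_ij`` patient x antigen variation,
``delta_jf`` the planted fluid effect (+log10(fold) on the favoured fluid
for planted antigens, 0 elsewhere) and ``e_ijf``/``eps_r`` fluid- and
replicate-level noise.

The noise scales are parameterized by target correlations rather than raw
variances: ``duplicate_rho`` is the intended intra-array correlation of
duplicate spots and ``fluid_rho`` the intended per-patient PL/SF
correlation of collapsed values.  The replicate noise variance follows the
variance partition ``sigma_d^2 = var(y) (1 - rho_d)/rho_d`` per array; the
fluid noise variance is solved numerically from the exact expected-
correlation expression, which also accounts for the between-fluid variance
contributed by the planted fold changes and by replicate noise surviving
duplicate collapse — with those terms ignored, a cohort generated at the
default preset would not actually reproduce its own target correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .array_io import ArrayDesign, DESIGN_COLS, SampleMeta, SpotTable

# The canonical 10-patient cohort: oligoarticular (O), extended
# oligoarticular (E) and polyarticular (P) subtypes, with the 6/4 split into
# low/high global antibody groups used throughout.
CANONICAL_PATIENTS = ("O1", "O2", "O3", "E1", "E2", "E3", "P1", "P2", "P3", "P4")
CANONICAL_LOW_GROUP = ("O1", "O3", "E1", "E2", "E3", "P3")

_SUBTYPE = {"O": "oligo", "E": "extended_oligo", "P": "poly"}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition preset for the synthetic cohort.

    Defaults are the study-calibration preset: 768 antigens in duplicate,
    10 patients with paired PL/SF arrays, intra-array duplicate correlation
    0.98, inter-fluid correlation 0.96, planted differential antigens
    (29 PL-higher, 1 SF-higher, 6 near-equal) at 1.8-fold, and a 6/4
    patient-group split shifted by 4 patient-level sigmas.
    """

    n_antigens: int = 768
    n_patients: int = 10
    duplicate_rho: float = 0.98
    fluid_rho: float = 0.96
    n_pl_higher: int = 29
    n_sf_higher: int = 1
    n_similar: int = 6
    planted_fold: float = 1.8
    group_sizes: tuple[int, int] = (6, 4)  # (low, high)
    group_shift_sigma: float = 4.0  # in units of sigma_patient
    baseline_log_mean: float = 3.5  # log10 raw-volume units
    antigen_spread: float = 0.20  # s.d. of antigen baselines mu_j
    sigma_patient: float = 0.08  # s.d. of patient x antigen effects u_ij
    background_mean: float = 50.0  # raw-volume units
    noise_sd: float = 5.0  # s.d. of additive raw-scale background
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplicate_rho", "fluid_rho"):
            rho = getattr(self, name)
            if not 0 < rho <= 1:
                raise ValueError(
                    f"{name}={rho}: variance decomposition infeasible "
                    "(rho must be in (0, 1])"
                )
        if self.n_pl_higher + self.n_sf_higher + self.n_similar > self.n_antigens:
            raise ValueError("planted category counts exceed n_antigens")
        if self.planted_fold <= 1:
            raise ValueError("planted_fold must exceed 1")
        if sum(self.group_sizes) != self.n_patients:
            raise ValueError("group sizes must sum to n_patients")

    def to_dict(self) -> dict:
        return asdict(self)


def study_preset(seed: int = 0) -> SimConfig:
    """The study-calibration preset (the class defaults) at a given seed."""
    return SimConfig(seed=seed)


@dataclass
class GroundTruth:
    antigen_categories: pd.Series  # antigen id -> pl_higher/sf_higher/similar/background
    patient_groups: pd.Series  # patient id -> low/high
    true_log: pd.DataFrame  # antigens x sample_ids, true y (log10)
    sigma_fluid: float
    config: SimConfig


@dataclass
class CohortSim:
    arrays: list[SpotTable]
    design: ArrayDesign
    meta: list[SampleMeta]
    truth: GroundTruth


# control features printed on every array
N_NONSPOT = 32
N_POSITIVE = 8
N_NEGATIVE = 8
N_REGISTRATION = 8
POSITIVE_LOG = 4.5  # EBNA1-like: high on every array
REGISTRATION_RAW = 60000.0  # IgG registration spots, constant-high


def antigen_ids(n: int) -> list[str]:
    return [f"AG{i + 1:04d}" for i in range(n)]


def make_design(n_antigens: int) -> ArrayDesign:
    """Duplicate-spotted design: every antigen twice, plus control classes."""
    rows = []
    for rep in (0, 1):
        for fid in antigen_ids(n_antigens):
            rows.append((fid, "antigen", rep))
    for i in range(N_POSITIVE):
        rows.append(("EBNA1", "positive_control", i))
    for i in range(N_NEGATIVE):
        rows.append(("EMPTY", "negative_control", i))
    for i in range(N_REGISTRATION):
        rows.append(("IGG", "registration", i))
    for i in range(N_NONSPOT):
        rows.append(("NONSPOT", "nonspot", i))
    df = pd.DataFrame(rows, columns=["feature_id", "feature_class", "replicate_index"])
    idx = np.arange(len(df))
    df["block"] = idx // 100
    df["row"] = (idx % 100) // 10
    df["col"] = idx % 10
    return ArrayDesign(df[DESIGN_COLS])


def _patient_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    """Patient ids and the low-group members."""
    if config.n_patients == 10 and tuple(config.group_sizes) == (6, 4):
        return list(CANONICAL_PATIENTS), list(CANONICAL_LOW_GROUP)
    ids = [f"S{i + 1:02d}" for i in range(config.n_patients)]
    return ids, ids[: config.group_sizes[0]]


def solve_fluid_noise(config: SimConfig, d_pl: float, d_sf: float) -> float:
    """Fluid-level noise s.d. delivering the target PL/SF correlation.

    *d_pl*, *d_sf* are the across-antigen variances of the planted offsets
    in each fluid.  The expected per-patient correlation of collapsed
    values is  S / sqrt((S + N_pl + d_pl)(S + N_sf + d_sf))  with shared
    variance S = antigen_spread^2 + sigma_patient^2 and per-fluid
    independent variance N_f = sigma_f^2 + sigma_d,f^2 / 2 (replicate noise
    halved by duplicate collapse, with sigma_d,f^2 tied to the per-array
    variance through duplicate_rho).
    """
    s = config.antigen_spread**2 + config.sigma_patient**2
    rho_f, rho_d = config.fluid_rho, config.duplicate_rho
    if rho_f == 1.0:
        return 0.0
    lam = (1.0 - rho_d) / rho_d  # sigma_d^2 = lam * var(y)

    def expected_r(x: float) -> float:
        n_pl = x + lam * (s + x + d_pl) / 2.0
        n_sf = x + lam * (s + x + d_sf) / 2.0
        return s / np.sqrt((s + n_pl + d_pl) * (s + n_sf + d_sf))

    if expected_r(0.0) < rho_f:
        raise ValueError(
            "variance decomposition infeasible: planted effects and replicate "
            f"noise already push the expected PL/SF correlation below "
            f"fluid_rho={rho_f}"
        )
    hi = max(s, 1.0)
    while expected_r(hi) > rho_f:
        hi *= 2.0
    x = brentq(lambda v: expected_r(v) - rho_f, 0.0, hi, xtol=1e-14)
    return float(np.sqrt(x))


def generate_cohort(config: SimConfig) -> CohortSim:
    """Generate one cohort: paired PL/SF spot tables for every patient.

    Deterministic at fixed config (all randomness flows from ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    n_a, n_p = config.n_antigens, config.n_patients
    ids = antigen_ids(n_a)
    patients, low_group = _patient_ids(config)

    # planted differential assignment
    n_planted = config.n_pl_higher + config.n_sf_higher + config.n_similar
    planted = rng.choice(n_a, size=n_planted, replace=False)
    categories = np.full(n_a, "background", dtype=object)
    categories[planted[: config.n_pl_higher]] = "pl_higher"
    categories[planted[config.n_pl_higher : config.n_pl_higher + config.n_sf_higher]] = (
        "sf_higher"
    )
    categories[planted[config.n_pl_higher + config.n_sf_higher :]] = "similar"
    delta = np.log10(config.planted_fold)
    delta_pl = np.where(categories == "pl_higher", delta, 0.0)
    delta_sf = np.where(categories == "sf_higher", delta, 0.0)

    sigma_f = solve_fluid_noise(
        config, float(np.var(delta_pl)), float(np.var(delta_sf))
    )

    # log-scale signal hierarchy
    mu = rng.normal(config.baseline_log_mean, config.antigen_spread, size=n_a)
    shift = config.group_shift_sigma * config.sigma_patient
    g = np.array([0.0 if p in low_group else shift for p in patients])
    u = rng.normal(0.0, config.sigma_patient, size=(n_p, n_a))
    e = rng.normal(0.0, sigma_f, size=(n_p, n_a, 2))
    y = (
        mu[None, :, None]
        + g[:, None, None]
        + u[:, :, None]
        + np.stack([delta_pl, delta_sf], axis=-1)[None, :, :]
        + e
    )  # (patient, antigen, fluid); fluid 0 = PL, 1 = SF

    design = make_design(n_a)
    lam_d = (1.0 - config.duplicate_rho) / config.duplicate_rho
    ant_mask = (design.features["feature_class"] == "antigen").to_numpy()
    rep_idx = design.features["replicate_index"].to_numpy()
    fid_order = design.features["feature_id"].to_numpy()
    # map antigen rows of the design onto the antigen axis
    pos_of = {fid: k for k, fid in enumerate(ids)}
    ant_j = np.array([pos_of[f] for f in fid_order[ant_mask]])
    ant_r = rep_idx[ant_mask]

    arrays: list[SpotTable] = []
    meta: list[SampleMeta] = []
    sample_cols: dict[str, np.ndarray] = {}
    for i, pid in enumerate(patients):
        for fi, fluid in enumerate(("PL", "SF")):
            yv = y[i, :, fi]
            sigma_d = float(np.sqrt(lam_d * np.var(yv)))
            eps = rng.normal(0.0, sigma_d, size=(n_a, 2))
            spot_log = yv[ant_j] + eps[ant_j, ant_r]

            raw = np.empty(len(design.features))
            bg = np.clip(
                rng.normal(config.background_mean, config.noise_sd, size=raw.shape),
                0.0,
                None,
            )
            raw[ant_mask] = 10.0 ** spot_log
            cls = design.features["feature_class"].to_numpy()
            raw[cls == "positive_control"] = 10.0**POSITIVE_LOG
            raw[cls == "registration"] = REGISTRATION_RAW
            raw[(cls == "negative_control") | (cls == "nonspot")] = 0.0
            raw = raw + bg

            sid = f"{pid}{fluid}"
            df = design.features.copy()
            df["raw_volume"] = raw
            df["flag"] = "ok"
            arrays.append(SpotTable(sid, df))
            meta.append(_sample_meta(pid, fluid, rng))
            sample_cols[sid] = yv

    truth = GroundTruth(
        antigen_categories=pd.Series(categories, index=ids, name="category"),
        patient_groups=pd.Series(
            ["low" if p in low_group else "high" for p in patients],
            index=patients,
            name="group",
        ),
        true_log=pd.DataFrame(sample_cols, index=ids),
        sigma_fluid=sigma_f,
        config=config,
    )
    return CohortSim(arrays=arrays, design=design, meta=meta, truth=truth)


def _sample_meta(pid: str, fluid: str, rng: np.random.Generator) -> SampleMeta:
    """Clinical covariates sampled loosely within plausible paediatric ranges
    (no epidemiological realism claimed)."""
    subtype = _SUBTYPE.get(pid[0], "oligo")
    return SampleMeta(
        patient_id=pid,
        fluid=fluid,
        subtype=subtype,
        sex=str(rng.choice(["Female", "Male"])),
        age_years=float(np.round(rng.uniform(2.0, 16.0), 1)),
        wbc=float(np.round(rng.normal(10.0, 2.0), 1)),
        esr_mm_hr=float(np.round(rng.gamma(2.0, 15.0), 1)),
        crp_mg_l=float(np.round(rng.gamma(1.5, 12.0), 1)),
        rf="Negative",
        ana_titer="Negative",
    )


def truth_report(truth: GroundTruth, path: str | Path) -> None:
    """TSV of planted per-antigen categories and per-patient groups."""
    path = Path(path)
    rows = [
        {"kind": "antigen", "id": aid, "label": cat}
        for aid, cat in truth.antigen_categories.items()
    ] + [
        {"kind": "patient", "id": pid, "label": grp}
        for pid, grp in truth.patient_groups.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_truth_report(path: str | Path) -> tuple[pd.Series, pd.Series]:
    df = pd.read_csv(path, sep="\t")
    ant = df[df["kind"] == "antigen"].set_index("id")["label"]
    pat = df[df["kind"] == "patient"].set_index("id")["label"]
    ant.name, pat.name = "category", "group"
    ant.index.name = pat.index.name = None
    return ant, pat


def simulate_plate(
    n_patients: int = 10,
    pl_shift: float = 0.03,
    base_mean: float = 0.55,
    between_sd: float = 0.15,
    within_sd: float = 0.04,
    n_replicates: int = 2,
    seed: int = 0,
):
    """Synthetic single-antigen ELISA plate with a configurable PL-SF shift.

    Patient baselines vary (between_sd) so pairing is informative; PL wells
    sit *pl_shift* absorbance units above SF on average.
    """
    from .elisa import ElisaPlate

    rng = np.random.default_rng(seed)
    patients, _ = _patient_ids(
        SimConfig(n_patients=n_patients, group_sizes=(n_patients - n_patients // 2,
                                                      n_patients // 2))
        if n_patients != 10
        else SimConfig()
    )
    rows = []
    for pid in patients:
        base = rng.normal(base_mean, between_sd)
        for fluid, shift in (("PL", pl_shift), ("SF", 0.0)):
            level = base + shift
            for rep in range(n_replicates):
                a450 = max(rng.normal(level, within_sd), 0.0)
                rows.append(
                    {"patient_id": pid, "fluid": fluid, "replicate": rep, "a450": a450}
                )
    return ElisaPlate(pd.DataFrame(rows))
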