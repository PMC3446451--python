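"""ELISA verification stage: duplicate-mean absorbances and a paired t-test.

Single-antigen ELISA readings (optical density at 450 nm, duplicate wells
per patient fluid) verify an array-derived differential call.  Replicate
wells are averaged per (patient, fluid) and the paired two-sided Student
t-test compares the per-patient PL and SF means.

The t statistic is ``mean(d) / (sd(d)/sqrt(n))`` with sample s.d. and
``df = n - 1``; the two-sided p-value is the Student-t tail probability
``I_{df/(df+t^2)}(df/2, 1/2)`` via the regularized incomplete beta function.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import betainc


@dataclass
class ElisaPlate:
    """Long-form plate readings: patient_id, fluid, replicate, a450."""

    readings: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["patient_id", "fluid", "replicate", "a450"]
        missing = [c for c in need if c not in self.readings.columns]
        if missing:
            raise ValueError(f"plate missing columns: {missing}")
        a = self.readings["a450"]
        if not np.all(np.isfinite(a)) or (a < 0).any():
            raise ValueError("absorbances must be finite and non-negative")


def read_plate(path: str | Path) -> ElisaPlate:
    return ElisaPlate(pd.read_csv(path, sep="\t"))


def write_plate(plate: ElisaPlate, path: str | Path) -> None:
    plate.readings.to_csv(path, sep="\t", index=False)


def mean_absorbance(plate: ElisaPlate) -> pd.Series:
    """Arithmetic mean over replicate wells, indexed by (patient, fluid)."""
    return plate.readings.groupby(["patient_id", "fluid"])["a450"].mean()


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_two_sided: float
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p_two_sided": self.p_two_sided,
            "n": self.n,
            "degenerate": self.degenerate,
        }


def student_t_sf2(t: float, df: int) -> float:
    """Two-sided Student-t tail P(|T| > t) via the incomplete beta function."""
    t = abs(float(t))
    if t == 0:
        return 1.0
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))


def paired_t_test(x, y) -> PairedTResult:
    """Two-sided paired Student t-test on equal-length samples.

    All-identical differences (zero s.d.) make the statistic undefined; the
    result is flagged degenerate with NaN t and p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        return PairedTResult(float("nan"), df, float("nan"), n, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    return PairedTResult(t, df, student_t_sf2(t, df), n)


def plate_t_test(plate: ElisaPlate) -> PairedTResult:
    """Paired t-test of duplicate-mean PL vs SF absorbances."""
    means = mean_absorbance(plate).unstack("fluid")
    if "PL" not in means.columns or "SF" not in means.columns:
        raise ValueError("plate must contain both PL and SF readings")
    means = means.dropna()
    return paired_t_test(means["PL"], means["SF"])
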