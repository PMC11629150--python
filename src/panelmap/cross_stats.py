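"""F2 phenotype statistics: fruit-shape-index descriptives, round/oval
classification, the 3:1 Mendelian chi-square test, and small qPCR helpers.

The fruit shape index (FSI) is the longitudinal diameter divided by the
transverse diameter; FSI > 1 means an elongated (oval) fruit. In a cross
where oval is controlled by a single dominant allele, the F2 segregates
3 oval : 1 round, which the chi-square goodness-of-fit test checks against
the 5% critical value of 3.841 (df = 1, no continuity correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

CHI2_CRITICAL_5PCT_DF1 = 3.841


@dataclass
class PhenotypeTable:
    individuals: list[str]
    fsi: np.ndarray

    def __post_init__(self) -> None:
        self.fsi = np.asarray(self.fsi, dtype=float)
        if len(self.individuals) != len(self.fsi):
            raise ValueError("ids and FSI values differ in length")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        if not np.all(np.isfinite(self.fsi)) or np.any(self.fsi <= 0):
            raise ValueError("FSI values must be finite and positive")

    def __len__(self) -> int:
        return len(self.individuals)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t")
        id_col, fsi_col = df.columns[:2]
        return cls(df[id_col].astype(str).tolist(), df[fsi_col].to_numpy(float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"id": self.individuals, "fsi": self.fsi}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class DescriptiveStats:
    n: int
    mean: float
    sd: float  # sample SD (n−1)
    min: float
    max: float
    skew: float  # NaN when undefined (constant data)
    kurtosis: float  # excess; NaN when undefined
    cv_percent: float


def describe_fsi(values: Sequence[float] | PhenotypeTable, bias_corrected: bool = False) -> DescriptiveStats:
    """Moment descriptives of an FSI sample.

    Skew and excess kurtosis use divisor-n central moments by default
    (g1 = m3/m2^1.5, g2 = m4/m2² − 3); ``bias_corrected=True`` switches to
    the small-sample adjusted G1/G2. SD uses n−1; CV% = 100·sd/mean.
    """
    x = values.fsi if isinstance(values, PhenotypeTable) else np.asarray(values, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        skew = kurt = float("nan")
    else:
        skew = float(sps.skew(x, bias=not bias_corrected))
        kurt = float(sps.kurtosis(x, fisher=True, bias=not bias_corrected))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return DescriptiveStats(
        n=n, mean=mean, sd=sd, min=float(np.min(x)), max=float(np.max(x)),
        skew=skew, kurtosis=kurt, cv_percent=cv,
    )


def classify_shape(fsi, threshold: float = 1.0):
    """'oval' when FSI > threshold, 'round' when FSI ≤ threshold.

    Accepts a scalar or an array (vectorised)."""
    arr = np.asarray(fsi, dtype=float)
    out = np.where(arr > threshold, "oval", "round")
    if arr.ndim == 0:
        return str(out)
    return out


@dataclass
class SegregationResult:
    n_dominant: int
    n_recessive: int
    expected: tuple[float, float]
    chi2: float
    df: int
    critical: float
    conforms: bool

    @property
    def n(self) -> int:
        return self.n_dominant + self.n_recessive


def chi_square_3to1(
    n_dominant: int, n_recessive: int, critical: float = CHI2_CRITICAL_5PCT_DF1
) -> SegregationResult:
    """Chi-square goodness of fit against a 3:1 dominant:recessive ratio.

    No continuity correction is applied; conformity means chi2 < critical
    (default 3.841, the 5% point of chi-square with one degree of freedom).
    """
    n = n_dominant + n_recessive
    if n < 1:
        raise ValueError("at least one individual required")
    exp_dom, exp_rec = 0.75 * n, 0.25 * n
    chi2 = (n_dominant - exp_dom) ** 2 / exp_dom + (n_recessive - exp_rec) ** 2 / exp_rec
    return SegregationResult(
        n_dominant=n_dominant,
        n_recessive=n_recessive,
        expected=(exp_dom, exp_rec),
        chi2=float(chi2),
        df=1,
        critical=critical,
        conforms=bool(chi2 < critical),
    )


def segregation_test(
    table: PhenotypeTable, threshold: float = 1.0
) -> SegregationResult:
    """Classify every individual by FSI and test the 3:1 ratio."""
    labels = classify_shape(table.fsi, threshold)
    n_dom = int(np.sum(labels == "oval"))
    return chi_square_3to1(n_dom, len(table) - n_dom)


def ddct_fold_change(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_calib: float,
    ct_ref_calib: float,
) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_reference) in the test sample minus the same
    difference in the calibrator; the fold change is 2 to the −ΔΔCt."""
    for ct in (ct_target_test, ct_ref_test, ct_target_calib, ct_ref_calib):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_calib - ct_ref_calib)
    return 2.0 ** (-ddct)


def percent(part: float, whole: float, decimals: int = 2) -> float:
    """Percentage-report utility: 100·part/whole rounded to ``decimals``."""
    if whole == 0:
        raise ValueError("whole must be non-zero")
    return round(100.0 * part / whole, decimals)
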