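"""Bulked-segregant mapping with the Euclidean-distance (ED) statistic.

Two pools of phenotypically extreme F2 progeny are sequenced; at every SNP
informative between the pools, each pool's reads are summarised as a base
frequency vector p = (pA, pC, pG, pT). The per-site statistic is

    ED = sqrt( Σ_b (p1_b − p2_b)² ),  b ∈ {A, C, G, T},

which is 0 when the pools agree and √2 for fixed opposite alleles. The ED is
raised to a power (default 2 — the "correlation value") to suppress
background noise, smoothed with a SNP-count windowed median (the SNPNUM
fit), and thresholded into candidate intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genomeio import VariantSet

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

ED_MAX = float(np.sqrt(2.0))


# ---------------------------------------------------------------------------
# Per-site statistic
# ---------------------------------------------------------------------------

def base_frequencies(depths: Sequence[int]) -> np.ndarray | None:
    """Normalise (dA, dC, dG, dT) read depths to frequencies summing to 1.

    Returns None for a zero-depth site (unusable)."""
    d = np.asarray(depths, dtype=float)
    if d.shape != (4,) or (d < 0).any():
        raise ValueError("depths must be four non-negative counts")
    total = d.sum()
    if total == 0:
        return None
    return d / total


def ed_site(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Euclidean distance between two base-frequency vectors."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum()))


# ---------------------------------------------------------------------------
# Pool depths and profiles
# ---------------------------------------------------------------------------

#: Column layout of a pool-depth table: one row per site, per-base read
#: depths for the two bulks.
DEPTH_COLUMNS = [
    "chrom", "pos",
    "a1", "c1", "g1", "t1",
    "a2", "c2", "g2", "t2",
]


@dataclass
class EDProfile:
    """Ordered per-site ED values along the genome.

    ``data`` columns: chrom, pos, ed, ed2 (= ed**power), fitted (NaN until
    :func:`fit_snpnum` fills it)."""

    data: pd.DataFrame
    power: float = 2.0
    threshold: float | None = None

    def __post_init__(self) -> None:
        for chrom, grp in self.data.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"profile positions not strictly increasing on {chrom}")


def informative_sites(
    variants: VariantSet, pool1: str, pool2: str
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Extract per-base pool depths at sites informative between two bulks.

    A site is kept when both pools have a called genotype, the calls differ,
    and both carry AD. Ref/alt allele depths are projected onto the A/C/G/T
    axes at the ref and alt bases (other bases get depth 0). Returns the
    depth table plus a skip tally.
    """
    try:
        i1 = variants.samples.index(pool1)
        i2 = variants.samples.index(pool2)
    except ValueError as exc:
        raise KeyError(f"pool sample not in VCF: {exc}") from exc
    rows = []
    skip = {"same_genotype": 0, "missing_gt": 0, "missing_ad": 0}
    for site in variants.sites:
        g1, g2 = int(site.genotypes[i1]), int(site.genotypes[i2])
        if g1 < 0 or g2 < 0:
            skip["missing_gt"] += 1
            continue
        if g1 == g2:
            skip["same_genotype"] += 1
            continue
        if site.allele_depths is None:
            skip["missing_ad"] += 1
            continue
        ad1, ad2 = site.allele_depths[i1], site.allele_depths[i2]
        if (ad1 < 0).any() or (ad2 < 0).any():
            skip["missing_ad"] += 1
            continue
        row = {"chrom": site.chrom, "pos": site.pos}
        for b in BASES:
            row[b.lower() + "1"] = 0
            row[b.lower() + "2"] = 0
        row[site.ref.lower() + "1"] = int(ad1[0])
        row[site.alt.lower() + "1"] = int(ad1[1])
        row[site.ref.lower() + "2"] = int(ad2[0])
        row[site.alt.lower() + "2"] = int(ad2[1])
        rows.append(row)
    df = pd.DataFrame(rows, columns=DEPTH_COLUMNS)
    return df, skip


def ed_profile(
    depths: pd.DataFrame, power: float = 2.0, min_depth: int = 10
) -> EDProfile:
    """Compute the per-site ED and ED^power profile from a pool-depth table.

    Sites where either pool's total depth is below ``min_depth`` are
    excluded (frequency-noise control)."""
    d = depths.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    m1 = d[["a1", "c1", "g1", "t1"]].to_numpy(float)
    m2 = d[["a2", "c2", "g2", "t2"]].to_numpy(float)
    t1 = m1.sum(axis=1)
    t2 = m2.sum(axis=1)
    usable = (t1 >= max(min_depth, 1)) & (t2 >= max(min_depth, 1))
    with np.errstate(invalid="ignore"):
        p1 = m1 / t1[:, None]
        p2 = m2 / t2[:, None]
    ed = np.sqrt(((p1 - p2) ** 2).sum(axis=1))
    out = pd.DataFrame(
        {
            "chrom": d.loc[usable, "chrom"].to_numpy(),
            "pos": d.loc[usable, "pos"].to_numpy(),
            "ed": ed[usable],
        }
    )
    out["ed2"] = out["ed"] ** power
    out["fitted"] = np.nan
    return EDProfile(data=out.reset_index(drop=True), power=power)


# ---------------------------------------------------------------------------
# SNPNUM windowed fit
# ---------------------------------------------------------------------------

def _windowed_median(values: np.ndarray, window: int) -> np.ndarray:
    """Median over a window of ``window`` consecutive entries centred on each
    index, shrunk symmetrically near the ends; a window spanning the whole
    array collapses to the global median."""
    n = len(values)
    if window >= n:
        return np.full(n, np.median(values))
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = np.median(values[i - k : i + k + 1])
    return out


def fit_snpnum(
    profile: EDProfile, window_snps: int = 101, step_snps: int = 1
) -> EDProfile:
    """Fit the ED^power profile with a SNP-count windowed median, per
    chromosome (windows never span a chromosome boundary).

    With ``step_snps`` > 1 the median is evaluated every ``step_snps``-th
    site and intermediate sites take the nearest evaluated value.
    """
    if window_snps < 3:
        raise ValueError("window_snps must be at least 3")
    if step_snps < 1:
        raise ValueError("step_snps must be at least 1")
    data = profile.data.copy()
    fitted = np.empty(len(data))
    for chrom, grp in data.groupby("chrom", sort=False):
        vals = grp["ed2"].to_numpy(float)
        fit = _windowed_median(vals, window_snps)
        if step_snps > 1:
            idx = np.arange(0, len(vals), step_snps)
            nearest = np.abs(np.arange(len(vals))[:, None] - idx[None, :]).argmin(axis=1)
            fit = fit[idx][nearest]
        fitted[grp.index.to_numpy()] = fit
    data["fitted"] = fitted
    return EDProfile(data=data, power=profile.power, threshold=profile.threshold)


# ---------------------------------------------------------------------------
# Threshold and interval calling
# ---------------------------------------------------------------------------

def call_threshold(
    fitted: Sequence[float],
    method: str = "median_sd",
    n_sd: float = 3.0,
    quantile: float = 0.999,
) -> float:
    """Genome-wide significance threshold for the fitted profile.

    Default is median + ``n_sd``·SD; ``method='quantile'`` uses the
    empirical ``quantile`` instead. (The published analysis does not print
    its threshold rule; this default is the toolkit's documented choice.)
    """
    vals = np.asarray(fitted, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 30:
        warnings.warn(f"threshold computed from only {len(vals)} fitted values")
    if method == "median_sd":
        return float(np.median(vals) + n_sd * np.std(vals))
    if method == "quantile":
        return float(np.quantile(vals, quantile))
    raise ValueError(f"unknown threshold method {method!r}")


@dataclass
class CandidateInterval:
    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_fitted: float
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return round(self.length / 1_000_000, 1)


def call_intervals(
    profile: EDProfile,
    threshold: float | None = None,
    min_sites: int = 5,
    gap_sites: int = 2,
) -> list[CandidateInterval]:
    """Candidate QTL intervals: maximal runs of consecutive sites with
    fitted > threshold (strict), per chromosome.

    Runs separated by fewer than ``gap_sites`` below-threshold sites are
    merged; merged runs with fewer than ``min_sites`` above-threshold
    members are discarded. Each interval spans the first to last site of its
    run and carries the peak fitted site."""
    if threshold is None:
        threshold = profile.threshold
        if threshold is None:
            threshold = call_threshold(profile.data["fitted"])
    intervals: list[CandidateInterval] = []
    for chrom, grp in profile.data.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        fit = grp["fitted"].to_numpy(float)
        above = fit > threshold
        runs: list[list[int]] = []  # index lists of above-threshold sites
        current: list[int] = []
        gap = 0
        for i, flag in enumerate(above):
            if flag:
                if current and gap >= gap_sites:
                    runs.append(current)
                    current = []
                current.append(i)
                gap = 0
            elif current:
                gap += 1
        if current:
            runs.append(current)
        for run in runs:
            if len(run) < min_sites:
                continue
            first, last = run[0], run[-1]
            seg = slice(first, last + 1)
            peak_rel = int(np.nanargmax(fit[seg])) + first
            intervals.append(
                CandidateInterval(
                    chrom=chrom,
                    start=int(pos[first]),
                    end=int(pos[last]),
                    peak_pos=int(pos[peak_rel]),
                    peak_fitted=float(fit[peak_rel]),
                    n_sites=len(run),
                )
            )
    return intervals


def top_interval(intervals: Sequence[CandidateInterval]) -> CandidateInterval | None:
    """The interval with the highest fitted peak, or None."""
    if not intervals:
        return None
    return max(intervals, key=lambda iv: iv.peak_fitted)


def plot_profile(profile: EDProfile, path, threshold: float | None = None) -> None:
    """Quick per-chromosome scatter of ED^power with the fitted line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(profile.data["chrom"]))
    fig, axes = plt.subplots(1, len(chroms), figsize=(4 * len(chroms), 3), sharey=True)
    if len(chroms) == 1:
        axes = [axes]
    for ax, chrom in zip(axes, chroms):
        grp = profile.data[profile.data["chrom"] == chrom]
        ax.scatter(grp["pos"] / 1e6, grp["ed2"], s=2, alpha=0.3, label="ED^k")
        ax.plot(grp["pos"] / 1e6, grp["fitted"], color="red", lw=1, label="fitted")
        thr = threshold if threshold is not None else profile.threshold
        if thr is not None:
            ax.axhline(thr, color="grey", ls="--", lw=0.8)
        ax.set_title(chrom)
        ax.set_xlabel("position (Mb)")
    axes[0].set_ylabel("ED^k")
    axes[0].legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
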