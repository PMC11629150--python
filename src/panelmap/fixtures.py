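"""Synthetic-data generators with recorded ground truth.

Every pipeline stage is testable without external downloads: a random
diploid multi-chromosome genome with planted duplicated regions, N runs and
GC-extreme windows; a multi-sample population VCF with a controlled
MAF/missingness spectrum (and, in construction mode, sites built to violate
exactly one panel rule each); an F2 cross segregating a single dominant
fruit-shape locus; and pooled read depths for two extreme-phenotype bulks.

Two genotype modes are used for the population generator:

* ``construction`` — genotype counts are set deterministically to hit an
  exact MAF and missing rate, so every filter decision is predictable and
  the cascade can be checked against a truth table with no sampling noise;
* ``sampling`` — genotypes are Hardy–Weinberg draws at a true allele
  frequency, for statistical calibration tests.

The F2 cross uses a Haldane (no-interference) recombination model at
1 cM/Mb, the mapping-population scale of the study this emulates: 1435
individuals, a dominant oval-fruit locus, parental FSI means 1.2 (oval)
and 0.9 (round) with noise sigma 0.04, and 30+30 extreme bulks sequenced
to ~30x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bsa_ed
from .cross_stats import PhenotypeTable, classify_shape
from .fine_mapping import CrossRecord, MarkerMap
from .genomeio import GenomeSequence, VariantSet, VariantSite

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Genome generator
# ---------------------------------------------------------------------------

@dataclass
class Duplication:
    src_chrom: str
    src_start: int  # 1-based
    length: int
    dst_chrom: str
    dst_start: int


@dataclass
class GenomeTruth:
    seed: int
    duplications: list[Duplication] = field(default_factory=list)
    n_runs: list[tuple[str, int, int]] = field(default_factory=list)  # chrom, start, length
    gc_regions: list[tuple[str, int, int, float]] = field(default_factory=list)

    def planted_intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for d in self.duplications:
            out.append((d.src_chrom, d.src_start, d.src_start + d.length - 1))
            out.append((d.dst_chrom, d.dst_start, d.dst_start + d.length - 1))
        for chrom, start, length in self.n_runs:
            out.append((chrom, start, start + length - 1))
        for chrom, start, length, _ in self.gc_regions:
            out.append((chrom, start, start + length - 1))
        return out


def _check_no_overlap(intervals: list[tuple[str, int, int]]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"planted features overlap on {chrom}: ({s1},{e1}) and ({s2},{e2})")


def make_genome(
    n_chrom: int = 2,
    length: int = 100_000,
    seed: int = 0,
    duplications: Sequence[Duplication] | None = None,
    n_runs: Sequence[tuple[str, int, int]] | None = None,
    gc_regions: Sequence[tuple[str, int, int, float]] | None = None,
) -> tuple[GenomeSequence, GenomeTruth]:
    """Random uniform-base genome with requested features planted verbatim.

    ``n_runs`` entries are (chrom, start, length); ``gc_regions`` are
    (chrom, start, length, gc) with bases redrawn at P(G or C) = gc.
    Duplications copy the source block onto the destination after all other
    planting. Planted features must not overlap. Reproducible given seed.
    """
    if length < 10_000:
        raise ValueError("chromosome length must be at least 10 kb")
    rng = np.random.default_rng(seed)
    truth = GenomeTruth(
        seed=seed,
        duplications=list(duplications or []),
        n_runs=list(n_runs or []),
        gc_regions=list(gc_regions or []),
    )
    _check_no_overlap(truth.planted_intervals())
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    arrays = {name: _BASES[rng.integers(0, 4, size=length)].copy() for name in names}
    for chrom, start, seg_len, gc in truth.gc_regions:
        is_gc = rng.random(seg_len) < gc
        strong = np.where(rng.random(seg_len) < 0.5, "G", "C")
        weak = np.where(rng.random(seg_len) < 0.5, "A", "T")
        arrays[chrom][start - 1 : start - 1 + seg_len] = np.where(is_gc, strong, weak)
    for chrom, start, seg_len in truth.n_runs:
        arrays[chrom][start - 1 : start - 1 + seg_len] = "N"
    for d in truth.duplications:
        block = arrays[d.src_chrom][d.src_start - 1 : d.src_start - 1 + d.length].copy()
        arrays[d.dst_chrom][d.dst_start - 1 : d.dst_start - 1 + d.length] = block
    genome = GenomeSequence(
        chrom_names=names, sequences={n: "".join(arrays[n]) for n in names}
    )
    return genome, truth


def make_annotation(
    genome: GenomeSequence,
    n_genes: int,
    seed: int = 0,
    interval: tuple[str, int, int] | None = None,
    gene_length: tuple[int, int] = (900, 3000),
) -> list["GeneModel"]:
    """Random non-overlapping gene models (one mRNA, 1–3 CDS segments whose
    total length is a codon multiple), optionally confined to an interval."""
    from .genomeio import GeneModel

    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    attempts = 0
    while len(genes) < n_genes and attempts < n_genes * 200:
        attempts += 1
        if interval is not None:
            chrom, lo, hi = interval
        else:
            chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
            lo, hi = 1, genome.lengths[chrom]
        span = int(rng.integers(gene_length[0], gene_length[1] + 1))
        if hi - lo + 1 < span + 2:
            raise ValueError("interval too small for requested genes")
        start = int(rng.integers(lo, hi - span + 1))
        end = start + span - 1
        if any(s <= end and e >= start for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        n_seg = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(np.arange(start + 30, end - 30), size=2 * n_seg, replace=False))
        segs = []
        for k in range(n_seg):
            s, e = int(bounds[2 * k]), int(bounds[2 * k + 1])
            segs.append((s, e))
        # trim the last segment so the CDS length is a codon multiple
        total = sum(e - s + 1 for s, e in segs)
        trim = total % 3
        if trim:
            s, e = segs[-1]
            segs[-1] = (s, e - trim)
        genes.append(
            GeneModel(
                gene_id=f"G{len(genes) + 1:04d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                cds_segments=segs,
                gene_span=(start, end),
            )
        )
    if len(genes) < n_genes:
        raise ValueError("could not place requested number of genes")
    return genes


# ---------------------------------------------------------------------------
# Population VCF generator
# ---------------------------------------------------------------------------

@dataclass
class PopulationTruth:
    seed: int
    mode: str
    site_rules: dict[tuple[str, int], str | None] = field(default_factory=dict)
    true_maf: dict[tuple[str, int], float] = field(default_factory=dict)
    true_missing: dict[tuple[str, int], float] = field(default_factory=dict)

    def expected_survivors(self) -> list[tuple[str, int]]:
        return sorted(k for k, v in self.site_rules.items() if v is None)

    def expected_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for v in self.site_rules.values():
            if v is not None:
                tally[v] = tally.get(v, 0) + 1
        return tally


def _local_gc(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    return sum(seq.count(b) for b in "GC") / acgt if acgt else float("nan")


def _flanks_clean(genome: GenomeSequence, chrom: str, pos: int, flank: int,
                  gc_lo: float, gc_hi: float) -> bool:
    L = genome.lengths[chrom]
    if pos - flank < 1 or pos + flank > L:
        return False
    up = genome.fetch(chrom, pos - flank, pos - 1)
    down = genome.fetch(chrom, pos + 1, pos + flank)
    if "N" in up or "N" in down or genome.base_at(chrom, pos) == "N":
        return False
    return gc_lo < _local_gc(up) < gc_hi and gc_lo < _local_gc(down) < gc_hi


def _construct_genotypes(
    rng: np.random.Generator, n_samples: int, alt_count: int, n_missing: int
) -> np.ndarray:
    """Deterministic genotype vector with the exact alt-allele count and
    missing count (alt_count over called alleles, alt frequency ≤ 0.5)."""
    n_called = n_samples - n_missing
    if alt_count > n_called:  # keep p_alt ≤ 0.5 so maf == alt freq
        raise ValueError("alt_count must be ≤ n_called")
    max_hom = alt_count // 2
    n_hom = int(rng.integers(0, max_hom + 1))
    n_het = alt_count - 2 * n_hom
    while n_hom + n_het > n_called:
        n_hom += 1
        n_het -= 2
    geno = np.full(n_samples, 0, dtype=np.int8)
    geno[:n_missing] = -1
    geno[n_missing : n_missing + n_hom] = 2
    geno[n_missing + n_hom : n_missing + n_hom + n_het] = 1
    rng.shuffle(geno)
    return geno


def make_population_vcf(
    genome: GenomeSequence,
    n_samples: int = 60,
    n_sites: int = 500,
    seed: int = 0,
    mode: str = "construction",
    maf_range: tuple[float, float] = (0.10, 0.40),
    missing_rate: float = 0.10,
    violations: dict[str, int] | None = None,
    genome_truth: GenomeTruth | None = None,
    maf_min: float = 0.05,
    missing_max: float = 0.50,
    flank: int = 100,
    gc_lo: float = 0.40,
    gc_hi: float = 0.60,
) -> tuple[VariantSet, PopulationTruth]:
    """Population genotypes with per-site ground truth for the panel cascade.

    ``n_sites`` counts rule-passing sites; ``violations`` adds sites built to
    fail exactly one rule each, keyed by reason: ``maf``, ``missing``,
    ``gc`` (needs planted GC-extreme regions), ``n`` (needs planted N runs)
    and ``copy`` (needs planted duplications of length ≥ 2·flank+1; one
    violation per duplication). Construction mode sets genotype counts
    exactly; sampling mode draws Hardy–Weinberg genotypes.
    """
    if mode not in ("construction", "sampling"):
        raise ValueError("mode must be 'construction' or 'sampling'")
    violations = dict(violations or {})
    if violations and genome_truth is None and set(violations) & {"gc", "n", "copy"}:
        raise ValueError("gc/n/copy violations need the genome's planted-feature truth")
    rng = np.random.default_rng(seed)
    truth = PopulationTruth(seed=seed, mode=mode)
    used_pos: set[tuple[str, int]] = set()

    avoid: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    if genome_truth is not None:
        for chrom, s, e in genome_truth.planted_intervals():
            avoid[chrom].append((s - flank, e + flank))

    def is_avoided(chrom: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in avoid[chrom])

    def place_clean() -> tuple[str, int]:
        for _ in range(2000):
            chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
            L = genome.lengths[chrom]
            pos = int(rng.integers(flank + 1, L - flank + 1))
            if (chrom, pos) in used_pos or is_avoided(chrom, pos):
                continue
            if _flanks_clean(genome, chrom, pos, flank, gc_lo, gc_hi):
                return chrom, pos
        raise ValueError("could not place a clean site; genome too constrained")

    def clean_geno() -> tuple[np.ndarray, float, float]:
        if mode == "sampling":
            p = rng.uniform(*maf_range)
            g = rng.binomial(1, p, (n_samples, 2)).sum(axis=1).astype(np.int8)
            miss = rng.random(n_samples) < missing_rate
            g[miss] = -1
            return g, p, float(miss.mean())
        n_missing = int(rng.integers(0, max(1, int(0.3 * n_samples))))
        n_called = n_samples - n_missing
        m = rng.uniform(*maf_range)
        alt = max(int(np.ceil(maf_min * 2 * n_called)), round(m * 2 * n_called))
        alt = min(alt, n_called)
        g = _construct_genotypes(rng, n_samples, alt, n_missing)
        return g, alt / (2 * n_called), n_missing / n_samples

    placements: list[tuple[str, int, str | None, np.ndarray, float, float]] = []

    for _ in range(n_sites):
        chrom, pos = place_clean()
        used_pos.add((chrom, pos))
        g, maf, miss = clean_geno()
        placements.append((chrom, pos, None, g, maf, miss))

    for _ in range(violations.pop("maf", 0)):
        chrom, pos = place_clean()
        used_pos.add((chrom, pos))
        n_called = n_samples
        alt = max(0, int(np.ceil(maf_min * 2 * n_called)) - 1)
        g = _construct_genotypes(rng, n_samples, alt, 0)
        placements.append((chrom, pos, "maf", g, alt / (2 * n_called), 0.0))

    for _ in range(violations.pop("missing", 0)):
        chrom, pos = place_clean()
        used_pos.add((chrom, pos))
        n_missing = int(np.ceil(missing_max * n_samples))
        n_called = n_samples - n_missing
        alt = min(n_called, max(int(np.ceil(maf_min * 2 * n_called)), round(0.25 * 2 * n_called)))
        g = _construct_genotypes(rng, n_samples, alt, n_missing)
        placements.append((chrom, pos, "missing", g, alt / (2 * n_called), n_missing / n_samples))

    n_gc = violations.pop("gc", 0)
    if n_gc:
        regions = [r for r in genome_truth.gc_regions if r[2] >= 2 * flank + 2]
        if not regions:
            raise ValueError("gc violations need a planted GC region of length ≥ 2·flank+2")
        placed = 0
        for _ in range(n_gc * 50):
            if placed == n_gc:
                break
            chrom, start, seg_len, _gc = regions[int(rng.integers(len(regions)))]
            pos = int(rng.integers(start + flank, start + seg_len - flank))
            if (chrom, pos) in used_pos:
                continue
            up = genome.fetch(chrom, pos - flank, pos - 1)
            down = genome.fetch(chrom, pos + 1, pos + flank)
            ok = not (gc_lo < _local_gc(up) < gc_hi) or not (gc_lo < _local_gc(down) < gc_hi)
            if not ok or genome.base_at(chrom, pos) == "N":
                continue
            used_pos.add((chrom, pos))
            g, maf, miss = clean_geno()
            placements.append((chrom, pos, "gc", g, maf, miss))
            placed += 1
        if placed < n_gc:
            raise ValueError("could not place all gc-violating sites")

    n_nv = violations.pop("n", 0)
    if n_nv:
        if not genome_truth.n_runs:
            raise ValueError("n violations need a planted N run")
        placed = 0
        for _ in range(n_nv * 50):
            if placed == n_nv:
                break
            chrom, start, seg_len = genome_truth.n_runs[int(rng.integers(len(genome_truth.n_runs)))]
            offset = int(rng.integers(1, flank + 1))
            pos = start - offset if rng.random() < 0.5 else start + seg_len - 1 + offset
            L = genome.lengths[chrom]
            if not (flank + 1 <= pos <= L - flank) or (chrom, pos) in used_pos:
                continue
            if genome.base_at(chrom, pos) == "N":
                continue
            used_pos.add((chrom, pos))
            g, maf, miss = clean_geno()
            placements.append((chrom, pos, "n", g, maf, miss))
            placed += 1
        if placed < n_nv:
            raise ValueError("could not place all N-flank sites")

    n_copy = violations.pop("copy", 0)
    if n_copy:
        usable = [d for d in genome_truth.duplications if d.length >= 2 * flank + 1]
        good = []
        for d in usable:
            pos = d.src_start + d.length // 2
            if _flanks_clean(genome, d.src_chrom, pos, flank, gc_lo, gc_hi):
                good.append((d.src_chrom, pos))
        if len(good) < n_copy:
            raise ValueError(
                f"need {n_copy} duplications of length ≥ {2 * flank + 1} with clean "
                f"flanks; only {len(good)} available"
            )
        for chrom, pos in good[:n_copy]:
            used_pos.add((chrom, pos))
            g, maf, miss = clean_geno()
            placements.append((chrom, pos, "copy", g, maf, miss))

    if violations:
        raise ValueError(f"unknown violation kinds: {sorted(violations)}")

    placements.sort(key=lambda t: (t[0], t[1]))
    sites: list[VariantSite] = []
    for chrom, pos, rule, g, maf, miss in placements:
        ref = genome.base_at(chrom, pos)
        alt_base = str(rng.choice([b for b in "ACGT" if b != ref]))
        sites.append(VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt_base, genotypes=g))
        truth.site_rules[(chrom, pos)] = rule
        truth.true_maf[(chrom, pos)] = maf
        truth.true_missing[(chrom, pos)] = miss
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    return VariantSet(sites=sites, samples=samples, skip_report={}), truth


def make_panel_fixture(
    seed: int = 0,
    n_samples: int = 60,
    n_clean: int = 500,
    violations: dict[str, int] | None = None,
    n_chrom: int = 2,
    length: int = 120_000,
) -> tuple[GenomeSequence, GenomeTruth, VariantSet, PopulationTruth]:
    """Genome + population VCF with every violation kind planted, ready for
    an end-to-end check of the selection cascade against its truth table."""
    violations = violations or {"maf": 20, "missing": 20, "gc": 15, "n": 15, "copy": 10}
    n_copy = violations.get("copy", 0)
    rng = np.random.default_rng(seed)
    dups = []
    # duplication sources on chr1, targets on chr2, laid out on a fixed grid
    # wide enough to keep 201-bp blocks and their flanks disjoint
    pitch = 600
    n_dup = n_copy + max(4, n_copy // 2)  # margin: some sources fail the GC check
    if (2 * n_dup + 2) * pitch > length:
        raise ValueError("chromosome too short for requested duplications")
    for i in range(n_dup):
        dups.append(
            Duplication(
                src_chrom="chr1",
                src_start=pitch * (2 * i + 1),
                length=201,
                dst_chrom="chr2" if n_chrom > 1 else "chr1",
                dst_start=pitch * (2 * i + 2) if n_chrom == 1 else pitch * (2 * i + 1),
            )
        )
    mid = length // 2
    gc_regions = [
        ("chr1", mid, 250, 0.80),
        ("chr1", mid + 2_000, 250, 0.15),
        ("chr2", mid, 250, 0.80),
    ]
    n_runs = [("chr2", mid + 2_000, 60), ("chr2", mid + 4_000, 25)]
    genome, gtruth = make_genome(
        n_chrom=n_chrom,
        length=length,
        seed=int(rng.integers(2**31)),
        duplications=dups,
        n_runs=n_runs,
        gc_regions=gc_regions,
    )
    variants, ptruth = make_population_vcf(
        genome,
        n_samples=n_samples,
        n_sites=n_clean,
        seed=int(rng.integers(2**31)),
        mode="construction",
        violations=violations,
        genome_truth=gtruth,
    )
    return genome, gtruth, variants, ptruth


# ---------------------------------------------------------------------------
# F2 cross generator
# ---------------------------------------------------------------------------

@dataclass
class FsiModel:
    """Single-dominant-locus phenotype model: FSI ~ N(oval_mean, sigma) with
    at least one maternal allele at the causal locus, else N(round_mean,
    sigma). Defaults are the parental means (1.2 oval / 0.9 round) with the
    oval parent's SD 0.04."""

    oval_mean: float = 1.2
    round_mean: float = 0.9
    sigma: float = 0.04
    threshold: float = 1.0


def make_marker_map(
    chrom_lengths: dict[str, int],
    n_markers: int,
    seed: int = 0,
    margin: int = 1000,
) -> pd.DataFrame:
    """Random genome-wide marker table (marker, chrom, pos, ref, alt,
    maternal_is_alt), markers allocated to chromosomes proportionally to
    length and sorted by position."""
    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths.values())
    rows = []
    k = 0
    chroms = list(chrom_lengths)
    counts = {c: max(2, round(n_markers * chrom_lengths[c] / total)) for c in chroms}
    for chrom in chroms:
        L = chrom_lengths[chrom]
        want = counts[chrom]
        pos = np.unique(rng.integers(margin, L - margin + 1, size=want * 2))
        while len(pos) < want:  # collisions are rare at genome scale
            pos = np.unique(np.append(pos, rng.integers(margin, L - margin + 1, size=want)))
        pos = np.sort(rng.choice(pos, size=want, replace=False))
        for p in pos:
            k += 1
            ref, alt_b = rng.choice(list("ACGT"), size=2, replace=False)
            rows.append(
                {
                    "marker": f"M{k:05d}",
                    "chrom": chrom,
                    "pos": int(p),
                    "ref": str(ref),
                    "alt": str(alt_b),
                    "maternal_is_alt": bool(rng.random() < 0.5),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class F2Cross:
    """A simulated F2 mapping population.

    ``genotypes`` holds the paternal-allele dosage per individual and marker
    (0 = maternal hom, 1 = het, 2 = paternal hom); ``causal_genotype`` is
    the same code at the causal locus itself."""

    ids: list[str]
    marker_map: pd.DataFrame
    causal: tuple[str, int]
    genotypes: np.ndarray  # (n, m) int8
    causal_genotype: np.ndarray  # (n,) int8
    fsi: np.ndarray
    fsi_model: FsiModel
    seed: int

    @property
    def phenotypes(self) -> np.ndarray:
        return classify_shape(self.fsi, self.fsi_model.threshold)

    def phenotype_table(self) -> PhenotypeTable:
        return PhenotypeTable(self.ids, self.fsi)

    def finemap_inputs(
        self, chrom: str | None = None
    ) -> tuple[list[CrossRecord], MarkerMap]:
        """Cross records (A/H/B codes) and the single-chromosome marker map
        needed by the fine-mapping module; defaults to the causal chromosome."""
        chrom = chrom or self.causal[0]
        mask = (self.marker_map["chrom"] == chrom).to_numpy()
        ids = self.marker_map.loc[mask, "marker"].tolist()
        positions = self.marker_map.loc[mask, "pos"].to_numpy()
        mm = MarkerMap(ids, chrom, positions)
        codes = np.array(["A", "H", "B"])
        labels = self.phenotypes
        records = [
            CrossRecord(
                self.ids[i],
                str(labels[i]),
                [str(c) for c in codes[self.genotypes[i, mask]]],
            )
            for i in range(len(self.ids))
        ]
        return records, mm


def _simulate_gametes(
    rng: np.random.Generator, n_gametes: int, positions: np.ndarray, cm_per_mb: float
) -> np.ndarray:
    """Haldane-model F1 gametes over ordered loci: per-interval switch
    probability r = (1 − exp(−2d))/2 at d Morgans = bp · cM/Mb · 1e-8."""
    m = len(positions)
    out = np.empty((n_gametes, m), dtype=np.int8)
    out[:, 0] = rng.integers(0, 2, size=n_gametes)
    if m > 1:
        d_morgan = np.diff(positions).astype(float) * cm_per_mb * 1e-8
        r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
        switches = rng.random((n_gametes, m - 1)) < r[None, :]
        out[:, 1:] = switches
        out = np.cumsum(out, axis=1, dtype=np.int64) % 2
    return out.astype(np.int8)


def make_f2_cross(
    n_individuals: int,
    marker_map: pd.DataFrame,
    causal: tuple[str, int],
    fsi_model: FsiModel | None = None,
    seed: int = 0,
    cm_per_mb: float = 1.0,
) -> F2Cross:
    """Simulate an F2 population segregating one dominant fruit-shape locus.

    Each individual is the union of two independent recombination-aware F1
    gametes over the marker map (Haldane model, default 1 cM/Mb); its FSI is
    drawn from the phenotype model given its causal-locus genotype.
    """
    fsi_model = fsi_model or FsiModel()
    rng = np.random.default_rng(seed)
    mm = marker_map.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    c_chrom, c_pos = causal
    chrom_list = list(dict.fromkeys(mm["chrom"]))
    if c_chrom not in chrom_list:
        raise ValueError(f"causal chromosome {c_chrom} has no markers")
    span = mm.loc[mm["chrom"] == c_chrom, "pos"]
    if not (span.min() <= c_pos <= span.max()):
        raise ValueError("causal position must lie inside the marker map span")

    geno_cols: list[np.ndarray] = []
    causal_geno: np.ndarray | None = None
    for chrom in chrom_list:
        pos = mm.loc[mm["chrom"] == chrom, "pos"].to_numpy()
        if chrom == c_chrom:
            allpos = np.sort(np.unique(np.append(pos, c_pos)))
            ci = int(np.searchsorted(allpos, c_pos))
        else:
            allpos, ci = pos, None
        g1 = _simulate_gametes(rng, n_individuals, allpos, cm_per_mb)
        g2 = _simulate_gametes(rng, n_individuals, allpos, cm_per_mb)
        g = (g1 + g2).astype(np.int8)  # paternal dosage
        if ci is not None:
            causal_geno = g[:, ci].copy()
            if c_pos not in pos:
                g = np.delete(g, ci, axis=1)
        geno_cols.append(g)
    genotypes = np.hstack(geno_cols)
    dominant = causal_geno < 2  # at least one maternal allele
    means = np.where(dominant, fsi_model.oval_mean, fsi_model.round_mean)
    fsi = means + (rng.normal(0.0, fsi_model.sigma, n_individuals) if fsi_model.sigma > 0 else 0.0)
    fsi = np.maximum(fsi, 0.01)
    ids = [f"F2_{i + 1:04d}" for i in range(n_individuals)]
    return F2Cross(
        ids=ids,
        marker_map=mm,
        causal=causal,
        genotypes=genotypes,
        causal_genotype=causal_geno,
        fsi=fsi,
        fsi_model=fsi_model,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Pooled sequencing generator
# ---------------------------------------------------------------------------

@dataclass
class PoolTruth:
    seed: int
    oval_ids: list[str]
    round_ids: list[str]
    causal: tuple[str, int]


def make_pools(
    cross: F2Cross,
    n_extreme: int = 30,
    depth_mean: float = 30.0,
    seed: int = 0,
    sites: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, PoolTruth]:
    """Pooled per-base read depths for the two extreme-phenotype bulks.

    The ``n_extreme`` highest-FSI individuals form the oval pool (pool 1)
    and the ``n_extreme`` lowest-FSI the round pool (pool 2); at each marker
    the pool's maternal-allele frequency is the mean maternal dosage of its
    members, read depth is Poisson(``depth_mean``) and maternal read counts
    are binomial. Returns a depth table in the layout ``bsa_ed`` consumes.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    labels = cross.phenotypes
    n_oval = int(np.sum(labels == "oval"))
    n_round = len(labels) - n_oval
    if min(n_oval, n_round) < n_extreme:
        raise ValueError(
            f"need ≥ {n_extreme} individuals in each phenotype tail "
            f"(have {n_oval} oval, {n_round} round); simulate a larger cross"
        )
    rng = np.random.default_rng(seed)
    order = np.argsort(cross.fsi, kind="stable")
    low_idx = order[:n_extreme]
    high_idx = order[-n_extreme:]
    mm = sites if sites is not None else cross.marker_map
    marker_mask = cross.marker_map["marker"].isin(mm["marker"]).to_numpy()
    sub = cross.marker_map.loc[marker_mask].reset_index(drop=True)
    maternal = 2 - cross.genotypes[:, marker_mask]  # maternal dosage 0..2
    p_mat_1 = maternal[high_idx].mean(axis=0) / 2.0
    p_mat_2 = maternal[low_idx].mean(axis=0) / 2.0
    m = len(sub)
    rows = {c: np.zeros(m, dtype=np.int64) for c in "acgt"}
    depth1 = rng.poisson(depth_mean, m)
    depth2 = rng.poisson(depth_mean, m)
    k1 = rng.binomial(depth1, p_mat_1)
    k2 = rng.binomial(depth2, p_mat_2)
    mat_base = np.where(sub["maternal_is_alt"], sub["alt"], sub["ref"]).astype(str)
    pat_base = np.where(sub["maternal_is_alt"], sub["ref"], sub["alt"]).astype(str)
    table = {"chrom": sub["chrom"].to_numpy(), "pos": sub["pos"].to_numpy()}
    for suffix, k, depth in (("1", k1, depth1), ("2", k2, depth2)):
        cols = {b: np.zeros(m, dtype=np.int64) for b in "ACGT"}
        for b in "ACGT":
            cols[b] += np.where(mat_base == b, k, 0)
            cols[b] += np.where(pat_base == b, depth - k, 0)
        for b in "ACGT":
            table[b.lower() + suffix] = cols[b]
    depths = pd.DataFrame(table, columns=bsa_ed.DEPTH_COLUMNS)
    truth = PoolTruth(
        seed=seed,
        oval_ids=[cross.ids[i] for i in high_idx],
        round_ids=[cross.ids[i] for i in low_idx],
        causal=cross.causal,
    )
    return depths, truth


def truth_to_json(truth, path: str | Path) -> None:
    """Serialise any fixture truth object alongside its artifact."""

    def normalize(o):
        if hasattr(o, "__dataclass_fields__"):
            return normalize(asdict(o))
        if isinstance(o, dict):
            return {str(k): normalize(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [normalize(v) for v in o]
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return o

    with open(path, "w") as fh:
        json.dump(normalize(truth), fh, indent=2)
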