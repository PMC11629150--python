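"""SNP panel selection: the filtering cascade that turns a population VCF plus
reference genome into array-grade markers.

A candidate SNP survives when, in order:

1. it is a biallelic SNP (enforced at VCF load),
2. minor-allele frequency ≥ ``maf_min`` (default 0.05) and genotype missing
   rate < ``missing_max`` (default 0.50),
3. both 100-bp flanks lie fully inside the chromosome, contain no N, and each
   has GC content strictly between ``gc_lo`` (0.40) and ``gc_hi`` (0.60),
4. the 201-bp probe context (flank + SNP + flank) is single-copy in the
   genome: no second locus aligns over ≥ ``min_copy_len`` bp (default 120,
   i.e. 60% of the probe),

after which each survivor is annotated with a functional class from the gene
annotation (intergenic / noncoding_genic / synonymous / nonsynonymous /
start_codon_change / stop_codon_change).

Every rejected site is tallied under the first rule it fails, so
``survivors + sum(tallies) == inputs`` always holds, and the filters are pure
per-site predicates — the final survivor set does not depend on cascade
order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genomeio import (
    GT_MISSING,
    GeneModel,
    GenomeSequence,
    VariantSet,
    VariantSite,
    reverse_complement,
)

FUNC_CLASSES = (
    "intergenic",
    "synonymous",
    "nonsynonymous",
    "start_codon_change",
    "stop_codon_change",
    "noncoding_genic",
)


@dataclass
class PanelConfig:
    """Tunables of the selection cascade (defaults are the published rules)."""

    maf_min: float = 0.05
    missing_max: float = 0.50
    flank: int = 100
    gc_lo: float = 0.40
    gc_hi: float = 0.60
    min_copy_len: int = 120
    check_copies: bool = True


# ---------------------------------------------------------------------------
# Per-site statistics (MAF / missingness)
# ---------------------------------------------------------------------------

@dataclass
class SiteStats:
    maf: float  # NaN when no genotype is called
    missing_rate: float
    n_called: int

    @property
    def maf_defined(self) -> bool:
        return not math.isnan(self.maf)


def site_stats(site: VariantSite, n_samples: int | None = None) -> SiteStats:
    """Minor-allele frequency and missing rate from diploid genotype codes.

    The allele frequency is computed over called genotypes only; half-called
    genotypes were already collapsed to missing at load time.
    """
    geno = site.genotypes
    if n_samples is None:
        n_samples = len(geno)
    called = geno != GT_MISSING
    n_called = int(called.sum())
    missing_rate = 1.0 - n_called / n_samples
    if n_called == 0:
        return SiteStats(maf=float("nan"), missing_rate=1.0, n_called=0)
    alt_alleles = int(geno[called].sum())  # codes are alt-allele dosages
    p_alt = alt_alleles / (2 * n_called)
    return SiteStats(maf=min(p_alt, 1.0 - p_alt), missing_rate=missing_rate, n_called=n_called)


def stats_filter_reason(stats: SiteStats, maf_min: float, missing_max: float) -> str | None:
    """First failing rule ('maf' or 'missing') or None when the site passes.

    Keep iff maf ≥ maf_min AND missing_rate < missing_max (MAF boundary
    inclusive, missing-rate boundary exclusive).
    """
    if not stats.maf_defined or stats.maf < maf_min:
        return "maf"
    if stats.missing_rate >= missing_max:
        return "missing"
    return None


def filter_stats(
    sites: Sequence[VariantSite],
    maf_min: float = 0.05,
    missing_max: float = 0.50,
    n_samples: int | None = None,
) -> tuple[list[VariantSite], dict[str, int]]:
    """Apply the MAF/missingness filter; return survivors and a rejection tally."""
    kept: list[VariantSite] = []
    tally: dict[str, int] = {}
    for site in sites:
        reason = stats_filter_reason(site_stats(site, n_samples), maf_min, missing_max)
        if reason is None:
            kept.append(site)
        else:
            tally[reason] = tally.get(reason, 0) + 1
    return kept, tally


# ---------------------------------------------------------------------------
# Flank context (GC / N / completeness)
# ---------------------------------------------------------------------------

@dataclass
class FlankContext:
    up_seq: str
    down_seq: str
    gc_up: float
    gc_down: float
    has_n: bool
    complete: bool


def gc_fraction(seq: str) -> float:
    """GC fraction of a sequence, excluding N from the denominator.

    Returns NaN for an all-N sequence; raises on an empty one.
    """
    if not seq:
        raise ValueError("gc_fraction of empty sequence")
    gc = sum(seq.count(b) for b in "GC")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return gc / acgt


def extract_flanks(genome: GenomeSequence, site: VariantSite, flank: int = 100) -> FlankContext:
    chrom_len = genome.lengths[site.chrom]
    if not 1 <= site.pos <= chrom_len:
        raise ValueError(f"position {site.chrom}:{site.pos} outside chromosome")
    up_start = site.pos - flank
    down_end = site.pos + flank
    complete = up_start >= 1 and down_end <= chrom_len
    up_seq = genome.fetch(site.chrom, max(1, up_start), site.pos - 1) if site.pos > 1 else ""
    down_seq = (
        genome.fetch(site.chrom, site.pos + 1, min(chrom_len, down_end))
        if site.pos < chrom_len
        else ""
    )
    gc_up = gc_fraction(up_seq) if up_seq else float("nan")
    gc_down = gc_fraction(down_seq) if down_seq else float("nan")
    has_n = "N" in up_seq or "N" in down_seq
    return FlankContext(up_seq, down_seq, gc_up, gc_down, has_n, complete)


def flank_filter_reason(
    context: FlankContext, gc_lo: float = 0.40, gc_hi: float = 0.60
) -> str | None:
    """First failing flank rule ('incomplete', 'n', 'gc') or None.

    Each flank is tested independently against the strict GC bounds.
    """
    if not context.complete:
        return "incomplete"
    if context.has_n:
        return "n"
    for gc in (context.gc_up, context.gc_down):
        if math.isnan(gc) or not (gc_lo < gc < gc_hi):
            return "gc"
    return None


def flank_filter(context: FlankContext, gc_lo: float = 0.40, gc_hi: float = 0.60):
    """(passed, reason) for the flank completeness/N/GC rule."""
    reason = flank_filter_reason(context, gc_lo, gc_hi)
    return reason is None, reason


# ---------------------------------------------------------------------------
# Single-copy check
# ---------------------------------------------------------------------------

@dataclass
class CopyHit:
    chrom: str
    start: int  # 1-based start of the aligned genomic block
    aligned_length: int
    strand: str = "+"
    is_self: bool = False


@dataclass
class CopyReport:
    hits: list[CopyHit]
    is_single_copy: bool


class CopyIndex:
    """Exact maximal-match search over a genome, for probe uniqueness checks.

    The probe's k-mers are sampled every k positions and looked up in a
    genome-wide k-mer index; each hit is extended along its diagonal to the
    maximal exact run. Any exact match of length ≥ 2k−1 bases contains a
    sampled k-mer, so with the default k=31 every exact duplicate of at
    least ``min_copy_len`` = 120 bp is guaranteed to be found. Both strands
    are searched. Inexact (diverged) homologies are out of contract; hit
    tables from an external aligner can be supplied via
    :func:`copy_report_from_hits` instead.
    """

    def __init__(self, genome: GenomeSequence, k: int = 31):
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom in genome.chrom_names:
            seq = genome.sequences[chrom]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def _extend(self, chrom: str, gpos: int, probe: str, ppos: int) -> tuple[int, int]:
        """Maximal exact run through the seed; returns (genome_start0, length)."""
        seq = self.genome.sequences[chrom]
        left = 0
        while ppos - left - 1 >= 0 and gpos - left - 1 >= 0 and probe[ppos - left - 1] == seq[gpos - left - 1]:
            left += 1
        right = self.k
        while (
            ppos + right < len(probe)
            and gpos + right < len(seq)
            and probe[ppos + right] == seq[gpos + right]
        ):
            right += 1
        return gpos - left, left + right

    def find(
        self,
        probe_seq: str,
        self_locus: tuple[str, int, int],
        min_copy_len: int = 120,
    ) -> CopyReport:
        """Report genomic loci matching ``probe_seq`` over ≥ ``min_copy_len`` bases.

        ``self_locus`` is (chrom, start, end), 1-based inclusive, the region
        the probe was extracted from; it always appears exactly once in hits.
        """
        if len(probe_seq) < min_copy_len:
            raise ValueError(
                f"probe length {len(probe_seq)} is below min_copy_len {min_copy_len}"
            )
        if min_copy_len < 2 * self.k - 1:
            raise ValueError(f"min_copy_len must be ≥ {2 * self.k - 1} for k={self.k}")
        runs: set[tuple[str, str, int, int]] = set()
        for strand, probe in (("+", probe_seq), ("-", reverse_complement(probe_seq))):
            offsets = list(range(0, len(probe) - self.k + 1, self.k))
            last = len(probe) - self.k
            if last not in offsets:
                offsets.append(last)
            for off in offsets:
                kmer = probe[off : off + self.k]
                for chrom, gpos in self._index.get(kmer, ()):
                    start0, length = self._extend(chrom, gpos, probe, off)
                    runs.add((strand, chrom, start0, length))
        s_chrom, s_start, s_end = self_locus
        hits: list[CopyHit] = []
        self_seen = False
        for strand, chrom, start0, length in sorted(runs):
            if length < min_copy_len:
                continue
            start1, end1 = start0 + 1, start0 + length
            is_self = (
                strand == "+" and chrom == s_chrom and start1 <= s_end and end1 >= s_start
            )
            if is_self:
                if self_seen:
                    continue  # keep exactly one self hit
                self_seen = True
            hits.append(CopyHit(chrom, start1, length, strand, is_self))
        if not self_seen:
            # probe not extracted verbatim from the genome; record the locus anyway
            hits.append(CopyHit(s_chrom, s_start, len(probe_seq), "+", True))
        is_single = not any((not h.is_self) and h.aligned_length >= min_copy_len for h in hits)
        return CopyReport(hits=hits, is_single_copy=is_single)


def find_copies(
    genome: GenomeSequence,
    probe_seq: str,
    self_locus: tuple[str, int, int],
    min_copy_len: int = 120,
    index: CopyIndex | None = None,
) -> CopyReport:
    """Convenience wrapper building a :class:`CopyIndex` when none is supplied."""
    if index is None:
        index = CopyIndex(genome)
    return index.find(probe_seq, self_locus, min_copy_len)


def copy_report_from_hits(
    hits: Iterable[tuple[str, int, int]],
    self_locus: tuple[str, int, int],
    min_copy_len: int = 120,
) -> CopyReport:
    """Adapter: build a CopyReport from an external aligner's (chrom, start,
    aligned_length) hit table, e.g. parsed BLAST tabular output."""
    s_chrom, s_start, s_end = self_locus
    out: list[CopyHit] = []
    self_seen = False
    for chrom, start, length in hits:
        is_self = chrom == s_chrom and start <= s_end and start + length - 1 >= s_start
        if is_self:
            if self_seen:
                continue
            self_seen = True
        out.append(CopyHit(chrom, start, length, "+", is_self))
    if not self_seen:
        out.append(CopyHit(s_chrom, s_start, s_end - s_start + 1, "+", True))
    is_single = not any((not h.is_self) and h.aligned_length >= min_copy_len for h in out)
    return CopyReport(hits=out, is_single_copy=is_single)


# ---------------------------------------------------------------------------
# Functional classification
# ---------------------------------------------------------------------------

def _spliced_cds(genome: GenomeSequence, gene: GeneModel) -> str:
    parts = [genome.fetch(gene.chrom, s, e) for s, e in gene.cds_segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = reverse_complement(cds)
    return cds


def _cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of ``pos`` within the spliced, strand-oriented CDS."""
    off = 0
    for s, e in gene.cds_segments:
        if s <= pos <= e:
            off += pos - s
            break
        off += e - s + 1
    total = gene.cds_length
    return off if gene.strand == "+" else total - 1 - off


def classify_site(
    site: VariantSite,
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
) -> str:
    """Functional class of a SNP against the gene annotation.

    CDS hits are translated strand-aware under the standard genetic code; a
    change in the first codon is a start-codon change, a codon gaining or
    losing a stop is a stop-codon change. Genes whose CDS chain is internally
    inconsistent fall back to noncoding_genic with a warning.
    """
    containing = [g for g in genes if g.chrom == site.chrom and g.contains(site.pos)]
    if not containing:
        return "intergenic"
    for gene in containing:
        if not gene.in_cds(site.pos):
            continue
        if not gene.coding_complete:
            warnings.warn(f"gene {gene.gene_id}: CDS length not a codon multiple; "
                          f"classifying {site.chrom}:{site.pos} as noncoding_genic")
            continue
        cds = _spliced_cds(genome, gene)
        off = _cds_offset(gene, site.pos)
        ref_base = site.ref if gene.strand == "+" else reverse_complement(site.ref)
        alt_base = site.alt if gene.strand == "+" else reverse_complement(site.alt)
        if cds[off] != ref_base:
            warnings.warn(
                f"gene {gene.gene_id}: CDS base at offset {off} disagrees with "
                f"ref allele of {site.chrom}:{site.pos}; classifying as noncoding_genic"
            )
            continue
        codon_idx = off // 3
        within = off % 3
        ref_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        if codon_idx == 0:
            return "start_codon_change"
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if "*" in (ref_aa, alt_aa):
            return "stop_codon_change"
        return "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return "noncoding_genic"


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

@dataclass
class PanelSNP:
    site: VariantSite
    stats: SiteStats
    context: FlankContext
    func_class: str
    copy_report: CopyReport | None = None


@dataclass
class PanelResult:
    panel: list[PanelSNP]
    audit: pd.DataFrame  # per-stage input and survivor counts
    rejections: dict[str, int]  # first-failing-rule tallies
    rejected_sites: dict[tuple[str, int], str] = field(default_factory=dict)


_STAGES = ("stats", "flank", "copy")


def site_rejection_reason(
    site: VariantSite,
    genome: GenomeSequence,
    config: PanelConfig,
    copy_index: CopyIndex | None,
) -> str | None:
    """First cascade rule the site fails, or None when it survives them all.

    Reasons: 'maf', 'missing', 'incomplete', 'n', 'gc', 'copy'. Because each
    rule is a pure predicate of the site alone, the survivor set is
    independent of the order the rules are applied in.
    """
    reason = stats_filter_reason(site_stats(site), config.maf_min, config.missing_max)
    if reason is not None:
        return reason
    ctx = extract_flanks(genome, site, config.flank)
    reason = flank_filter_reason(ctx, config.gc_lo, config.gc_hi)
    if reason is not None:
        return reason
    if config.check_copies:
        probe = ctx.up_seq + genome.base_at(site.chrom, site.pos) + ctx.down_seq
        locus = (site.chrom, site.pos - config.flank, site.pos + config.flank)
        report = find_copies(genome, probe, locus, config.min_copy_len, index=copy_index)
        if not report.is_single_copy:
            return "copy"
    return None


def select_panel(
    variants: VariantSet,
    genome: GenomeSequence,
    genes: Sequence[GeneModel] | None = None,
    config: PanelConfig | None = None,
) -> PanelResult:
    """Run the whole cascade and annotate survivors with functional classes."""
    config = config or PanelConfig()
    copy_index = CopyIndex(genome) if config.check_copies else None
    survivors: list[PanelSNP] = []
    tally: dict[str, int] = {}
    rejected: dict[tuple[str, int], str] = {}
    stage_counts = {s: 0 for s in _STAGES}
    n_in = len(variants.sites)
    for site in variants.sites:
        stats = site_stats(site)
        reason = stats_filter_reason(stats, config.maf_min, config.missing_max)
        if reason is not None:
            tally[reason] = tally.get(reason, 0) + 1
            rejected[(site.chrom, site.pos)] = reason
            continue
        stage_counts["stats"] += 1
        ctx = extract_flanks(genome, site, config.flank)
        reason = flank_filter_reason(ctx, config.gc_lo, config.gc_hi)
        if reason is not None:
            tally[reason] = tally.get(reason, 0) + 1
            rejected[(site.chrom, site.pos)] = reason
            continue
        stage_counts["flank"] += 1
        report = None
        if config.check_copies:
            probe = ctx.up_seq + genome.base_at(site.chrom, site.pos) + ctx.down_seq
            locus = (site.chrom, site.pos - config.flank, site.pos + config.flank)
            report = copy_index.find(probe, locus, config.min_copy_len)
            if not report.is_single_copy:
                tally["copy"] = tally.get("copy", 0) + 1
                rejected[(site.chrom, site.pos)] = "copy"
                continue
        stage_counts["copy"] += 1
        func = classify_site(site, genes, genome) if genes is not None else "intergenic"
        survivors.append(PanelSNP(site, stats, ctx, func, report))
    if not survivors:
        warnings.warn("panel selection produced an empty panel")
    audit_rows = []
    remaining = n_in
    for stage in _STAGES:
        audit_rows.append({"stage": stage, "input": remaining, "survivors": stage_counts[stage]})
        remaining = stage_counts[stage]
    audit = pd.DataFrame(audit_rows)
    return PanelResult(panel=survivors, audit=audit, rejections=tally, rejected_sites=rejected)


def panel_table(result: PanelResult) -> pd.DataFrame:
    """Flatten a panel into the exported TSV layout."""
    rows = []
    for p in result.panel:
        rows.append(
            {
                "chrom": p.site.chrom,
                "pos": p.site.pos,
                "ref": p.site.ref,
                "alt": p.site.alt,
                "maf": p.stats.maf,
                "missing_rate": p.stats.missing_rate,
                "gc_up": p.context.gc_up,
                "gc_down": p.context.gc_down,
                "func_class": p.func_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "maf", "missing_rate",
            "gc_up", "gc_down", "func_class",
        ],
    )


def density_report(
    panel: Sequence[PanelSNP], genome: GenomeSequence, bin_size: int = 1_000_000
) -> pd.DataFrame:
    """Per-chromosome SNP counts in fixed-width bins (density-plot input)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    by_chrom: dict[str, list[int]] = {c: [] for c in genome.chrom_names}
    for p in panel:
        by_chrom[p.site.chrom].append(p.site.pos)
    for chrom in genome.chrom_names:
        length = genome.lengths[chrom]
        n_bins = max(1, -(-length // bin_size))
        counts = np.zeros(n_bins, dtype=int)
        for pos in by_chrom[chrom]:
            counts[(pos - 1) // bin_size] += 1
        for b in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": b * bin_size + 1,
                    "bin_end": min((b + 1) * bin_size, length),
                    "count": int(counts[b]),
                }
            )
    return pd.DataFrame(rows)


def thin_panel(panel: Sequence[PanelSNP], min_spacing: int) -> list[PanelSNP]:
    """Optional greedy uniform-spacing thinning (keep the first SNP, then each
    next SNP at least ``min_spacing`` bp after the last kept one). The
    published array size was reached by an unstated final selection; this is
    the toolkit's explicit stand-in."""
    kept: list[PanelSNP] = []
    last: dict[str, int] = {}
    for p in sorted(panel, key=lambda q: (q.site.chrom, q.site.pos)):
        prev = last.get(p.site.chrom)
        if prev is None or p.site.pos - prev >= min_spacing:
            kept.append(p)
            last[p.site.chrom] = p.site.pos
    return kept
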