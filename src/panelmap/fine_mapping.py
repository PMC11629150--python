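"""Fine mapping of a dominant locus with F2 recombinants, plus candidate-gene
utilities (interval gene listing, promoter W-box scanning, allele diffing).

Marker genotypes are coded per individual as:

====  ==================================
code  meaning
====  ==================================
 A    homozygous maternal (dominant parent)
 H    heterozygous
 B    homozygous paternal (recessive parent)
 -    missing
====  ==================================

Under a single locus with the maternal allele dominant, a recessive-class
individual must be B at the causal position, and a dominant-class individual
cannot be B there. Each marker where a record violates its constraint is
excluded; the causal locus is confined to the span of markers consistent
with every record, reported as the physical interval between the flanking
(first excluded) markers on either side.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .genomeio import GeneModel, reverse_complement

GENO_CODES = ("A", "H", "B", "-")

W_BOX_MOTIF = "TTGACC"
W_BOX_CONSENSUS = "[CT]TGAC[TC]"
W_BOX_CORE = "TGAC"


# ---------------------------------------------------------------------------
# Marker map and cross records
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    marker_ids: list[str]
    chrom: str
    positions: np.ndarray  # 1-based bp, strictly increasing

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.marker_ids) != len(self.positions):
            raise ValueError("marker ids and positions differ in length")
        if len(self.positions) < 2:
            raise ValueError("a marker map needs at least two markers")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("marker positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerMap":
        df = pd.read_csv(path, sep="\t")
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("fine-mapping marker map must be on a single chromosome")
        return cls(df["marker"].astype(str).tolist(), str(chroms[0]), df["pos"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"marker": self.marker_ids, "chrom": self.chrom, "pos": self.positions}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class CrossRecord:
    individual: str
    phenotype: str  # 'oval' (dominant class) or 'round' (recessive class)
    genotypes: list[str]  # one code per marker

    def __post_init__(self) -> None:
        bad = set(self.genotypes) - set(GENO_CODES)
        if bad:
            raise ValueError(f"{self.individual}: invalid genotype codes {bad}")
        if self.phenotype not in ("oval", "round"):
            raise ValueError(f"{self.individual}: phenotype must be oval/round")


def read_genotype_tsv(path: str | Path, phenotypes: dict[str, str]) -> list[CrossRecord]:
    """Load a marker-genotype TSV (rows = individuals, columns = markers)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    records = []
    for ind, row in df.iterrows():
        records.append(CrossRecord(str(ind), phenotypes[str(ind)], [str(v) for v in row]))
    return records


# ---------------------------------------------------------------------------
# Recombinant detection
# ---------------------------------------------------------------------------

@dataclass
class Recombinant:
    individual: str
    breakpoints: list[tuple[int, int]]  # (left_pos, right_pos) flanking each crossover

    @property
    def is_double(self) -> bool:
        return len(self.breakpoints) >= 2


def find_recombinants(
    records: Sequence[CrossRecord], marker_map: MarkerMap
) -> tuple[dict[str, Recombinant], int]:
    """Breakpoint intervals per individual.

    An individual is a recombinant when its genotype class changes between
    consecutive non-missing markers; each change is localised to the
    physical interval between those two markers. Individuals missing at
    every marker are skipped and counted. Returns (recombinants by id,
    number skipped)."""
    recombinants: dict[str, Recombinant] = {}
    n_skipped = 0
    for rec in records:
        if len(rec.genotypes) != len(marker_map):
            raise ValueError(f"{rec.individual}: genotype vector length mismatch")
        called = [(j, g) for j, g in enumerate(rec.genotypes) if g != "-"]
        if not called:
            n_skipped += 1
            continue
        breaks = []
        for (j1, g1), (j2, g2) in zip(called, called[1:]):
            if g1 != g2:
                breaks.append(
                    (int(marker_map.positions[j1]), int(marker_map.positions[j2]))
                )
        if breaks:
            recombinants[rec.individual] = Recombinant(rec.individual, breaks)
    return recombinants, n_skipped


# ---------------------------------------------------------------------------
# Interval narrowing
# ---------------------------------------------------------------------------

class InconsistentCrossError(ValueError):
    """No marker is compatible with every record under the one-locus model."""

    def __init__(self, conflicts: dict[str, list[str]]):
        self.conflicts = conflicts

        def preview(ids):
            head = ", ".join(ids[:5])
            return head + (f", … ({len(ids)} total)" if len(ids) > 5 else "")

        msg = "; ".join(
            f"marker {m}: excluded by {preview(ids)}" for m, ids in conflicts.items()
        )
        super().__init__(f"no marker consistent with all records ({msg})")


@dataclass
class FineMapResult:
    chrom: str
    left_marker: str
    right_marker: str
    interval: tuple[int, int]
    recombinants_used: dict[str, Recombinant] = field(default_factory=dict)
    consistent_markers: list[str] = field(default_factory=list)
    n_excluded_double: int = 0

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0] + 1

    @property
    def length_kb(self) -> float:
        return round(self.length / 1000, 1)


def _marker_consistent(genotype: str, phenotype: str) -> bool:
    """Could the causal locus sit at a marker with this genotype?

    Recessive-class (round) individuals must be B at the locus; dominant-
    class (oval) individuals must not be B. Het or maternal genotypes of
    dominant individuals are uninformative (dominance masks Aa vs AA), as
    are missing calls."""
    if genotype == "-":
        return True
    if phenotype == "round":
        return genotype == "B"
    return genotype != "B"


def candidate_elements(records: Sequence[CrossRecord], marker_map: MarkerMap) -> np.ndarray:
    """Consistency of every map element with all records.

    Elements alternate marker, gap, marker, …: even index 2j is marker j,
    odd index 2j+1 the open interval between markers j and j+1 (2m−1
    elements for m markers). A marker is consistent with a record when the
    genotype there is compatible with the phenotype; a gap is consistent
    when either flanking marker is (a single crossover inside the gap can
    carry the causal genotype even when one flank excludes it)."""
    m = len(marker_map)
    elements = np.ones(2 * m - 1, dtype=bool)
    for rec in records:
        marker_ok = [_marker_consistent(g, rec.phenotype) for g in rec.genotypes]
        for j in range(m):
            elements[2 * j] &= marker_ok[j]
        for j in range(m - 1):
            elements[2 * j + 1] &= marker_ok[j] or marker_ok[j + 1]
    return elements


def narrow_interval(
    records: Sequence[CrossRecord],
    marker_map: MarkerMap,
    bsa_interval: tuple[int, int] | None = None,
    exclude_double_recombinants: bool = True,
) -> FineMapResult:
    """Confine the causal locus using every informative record.

    Each marker position and each inter-marker gap is tested for
    compatibility with every used record (see :func:`candidate_elements`);
    the reported physical interval runs between the nearest fully excluded
    marker on each side of the consistent block (falling back to the
    enclosing BSA interval, or the map ends, when nothing is excluded on
    that side). Double recombinants (two or more breakpoints — likely
    genotyping errors) are excluded by default.
    """
    recombinants, _ = find_recombinants(records, marker_map)
    doubles = {r.individual for r in recombinants.values() if r.is_double}
    if doubles and exclude_double_recombinants:
        shown = sorted(doubles)[:5]
        suffix = ", …" if len(doubles) > 5 else ""
        warnings.warn(
            f"excluding {len(doubles)} double recombinant(s): {shown}{suffix}"
        )
        used = [r for r in records if r.individual not in doubles]
    else:
        used = list(records)
    for rec in used:
        if len(rec.genotypes) != len(marker_map):
            raise ValueError(f"{rec.individual}: genotype vector length mismatch")

    m = len(marker_map)
    elements = candidate_elements(used, marker_map)
    if not elements.any():
        excluded_by: dict[str, list[str]] = {}
        for rec in used:
            for j, g in enumerate(rec.genotypes):
                if not _marker_consistent(g, rec.phenotype):
                    excluded_by.setdefault(
                        marker_map.marker_ids[j], []
                    ).append(rec.individual)
        raise InconsistentCrossError(excluded_by)

    idx = np.flatnonzero(elements)
    first, last = int(idx[0]), int(idx[-1])
    if len(idx) != last - first + 1:
        warnings.warn("consistent region is non-contiguous; reporting its full span")

    lo, hi = bsa_interval if bsa_interval is not None else (
        int(marker_map.positions[0]), int(marker_map.positions[-1])
    )
    # nearest excluded marker on each side of the consistent block
    left_j = (first - 1) // 2 if first > 0 else None  # marker left of element `first`
    right_j = (last + 2) // 2 if last < 2 * m - 2 else None
    if left_j is not None:
        left_marker = marker_map.marker_ids[left_j]
        start = int(marker_map.positions[left_j])
    else:
        left_marker = marker_map.marker_ids[0]
        start = lo
    if right_j is not None:
        right_marker = marker_map.marker_ids[right_j]
        end = int(marker_map.positions[right_j])
    else:
        right_marker = marker_map.marker_ids[-1]
        end = hi

    used_ids = {r.individual for r in used}
    return FineMapResult(
        chrom=marker_map.chrom,
        left_marker=left_marker,
        right_marker=right_marker,
        interval=(start, end),
        recombinants_used={k: v for k, v in recombinants.items() if k in used_ids},
        consistent_markers=[
            marker_map.marker_ids[j] for j in range(m) if elements[2 * j]
        ],
        n_excluded_double=len(doubles) if exclude_double_recombinants else 0,
    )


# ---------------------------------------------------------------------------
# Candidate genes
# ---------------------------------------------------------------------------

def genes_in_interval(
    genes: Iterable[GeneModel],
    interval: tuple[str, int, int],
    mode: str = "overlap",
) -> list[GeneModel]:
    """Genes overlapping (default) or fully contained in (chrom, start, end)."""
    chrom, start, end = interval
    out = []
    for g in genes:
        if g.chrom != chrom:
            continue
        gs, ge = g.gene_span
        if mode == "overlap":
            hit = gs <= end and ge >= start
        elif mode == "contained":
            hit = gs >= start and ge <= end
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if hit:
            out.append(g)
    return sorted(out, key=lambda g: g.gene_span[0])


# ---------------------------------------------------------------------------
# W-box promoter scan
# ---------------------------------------------------------------------------

@dataclass
class WBoxScan:
    """1-based start positions (forward coordinates) with strand labels."""

    motif_hits: list[tuple[int, str]]  # exact TTGACC
    consensus_hits: list[tuple[int, str]]  # [CT]TGAC[TC]
    core_hits: list[tuple[int, str]]  # TGAC

    @property
    def n_motif(self) -> int:
        return len(self.motif_hits)


def _scan_both_strands(seq: str, pattern: str) -> list[tuple[int, str]]:
    m_len = len(pattern.replace("[CT]", "N").replace("[TC]", "N"))
    rx = re.compile(f"(?=({pattern}))")
    hits = [(m.start() + 1, "+") for m in rx.finditer(seq)]
    rc = reverse_complement(seq)
    L = len(seq)
    for m in rx.finditer(rc):
        hits.append((L - m.start() - m_len + 1, "-"))
    return sorted(hits)


def scan_wbox(
    promoter_seq: str,
    motif: str = W_BOX_MOTIF,
    core: str = W_BOX_CORE,
) -> WBoxScan:
    """Scan a promoter for W-box elements on both strands.

    Reports the exact literal motif (default TTGACC), the degenerate
    consensus [CT]TGAC[TC], and the conserved TGAC core separately.
    Overlapping occurrences are all reported; minus-strand hits are given at
    their forward-coordinate start."""
    seq = promoter_seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("promoter sequence must be over A/C/G/T/N")
    return WBoxScan(
        motif_hits=_scan_both_strands(seq, motif),
        consensus_hits=_scan_both_strands(seq, W_BOX_CONSENSUS),
        core_hits=_scan_both_strands(seq, core),
    )


# ---------------------------------------------------------------------------
# Allele comparison
# ---------------------------------------------------------------------------

@dataclass
class AlleleVariant:
    kind: str  # 'snp', 'del' (absent from seq2), 'ins' (extra in seq2)
    pos: int  # 1-based position in seq1 (for ins: position after which it inserts)
    length: int
    ref: str
    alt: str


def diff_alleles(seq_parent1: str, seq_parent2: str) -> list[AlleleVariant]:
    """SNPs and indels between two alleles of the same locus, from a global
    pairwise alignment (unit match/mismatch scores, affine gaps)."""
    a, b = seq_parent1.upper(), seq_parent2.upper()
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    if a == b:
        return []
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2.5,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(a, b)[0]
    blocks1, blocks2 = aln.aligned
    variants: list[AlleleVariant] = []
    prev1 = prev2 = 0

    def flush_gap(s1: int, s2: int) -> None:
        nonlocal prev1, prev2
        if s1 > prev1:
            variants.append(
                AlleleVariant("del", prev1 + 1, s1 - prev1, a[prev1:s1], "")
            )
        if s2 > prev2:
            variants.append(
                AlleleVariant("ins", prev1, s2 - prev2, "", b[prev2:s2])
            )
        prev1, prev2 = s1, s2

    for (s1, e1), (s2, e2) in zip(blocks1, blocks2):
        flush_gap(s1, s2)
        for k in range(e1 - s1):
            if a[s1 + k] != b[s2 + k]:
                variants.append(AlleleVariant("snp", s1 + k + 1, 1, a[s1 + k], b[s2 + k]))
        prev1, prev2 = e1, e2
    flush_gap(len(a), len(b))
    return variants
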