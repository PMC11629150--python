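"""Readers, writers and the in-memory genotype model shared by the toolkit.

All coordinates are 1-based inclusive internally (the VCF/GFF convention).
BED's 0-based half-open convention is applied only at write time.

Genotypes are encoded per sample as small integers:

====  ==========================
code  meaning
====  ==========================
 0    homozygous reference
 1    heterozygous
 2    homozygous alternate
-1    missing (``./.``, ``.|.``, ``.`` or half-called)
====  ==========================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO

GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A malformed input file (FASTA/VCF/GFF)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome (FASTA)
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """A small in-memory genome: ordered chromosomes of A/C/G/T/N."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            seq = self.sequences[name]
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(f"chromosome {name} contains invalid bases {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(self.sequences[name]) for name in self.chrom_names}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``chrom`` from ``start`` to ``end`` (1-based inclusive)."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or end < start:
            raise ValueError(f"window {chrom}:{start}-{end} outside chromosome (len {len(seq)})")
        return seq[start - 1 : end]

    def base_at(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


def _normalize_sequence(raw: str) -> str:
    """Uppercase and map non-ACGTN IUPAC codes to N (soft-masking is discarded)."""
    seq = raw.upper()
    if set(seq) - _VALID_BASES:
        seq = "".join(b if b in _VALID_BASES else "N" for b in seq)
    return seq


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Raises :class:`FormatError` for an empty file or a file whose first
    non-blank line is not a header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}: line {lineno} is not a FASTA header")
                break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    names: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = _normalize_sequence(str(rec.seq))
    if not names:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeSequence(chrom_names=names, sequences=seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Variants (VCF)
# ---------------------------------------------------------------------------

@dataclass
class VariantSite:
    """One biallelic SNP with per-sample genotype codes and optional allele depths.

    ``allele_depths`` is an (n_samples, 2) int array of (ref, alt) read depths
    with -1 for missing, or None when the VCF carries no AD field.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: np.ndarray
    allele_depths: np.ndarray | None = None
    site_id: str = "."

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt")
        for b in (self.ref, self.alt):
            if len(b) != 1 or b not in "ACGT":
                raise ValueError(f"{self.chrom}:{self.pos}: allele {b!r} is not a single A/C/G/T base")
        if self.allele_depths is not None:
            self.allele_depths = np.asarray(self.allele_depths, dtype=np.int32)
            if self.allele_depths.shape != (len(self.genotypes), 2):
                raise ValueError("allele_depths shape must be (n_samples, 2)")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)


@dataclass
class VariantSet:
    """An ordered collection of biallelic SNPs plus the records skipped loading them."""

    sites: list[VariantSite]
    samples: list[str]
    skip_report: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


def _code_gt(gt: tuple | None) -> int:
    if gt is None:
        return GT_MISSING
    alleles = [a for a in gt]
    if len(alleles) != 2 or any(a is None for a in alleles):
        return GT_MISSING  # half-called counts as missing
    return int(alleles[0]) + int(alleles[1])


def read_vcf(path: str | Path) -> VariantSet:
    """Read a VCF, keeping biallelic SNPs only.

    Multiallelic records and indels are excluded and counted in
    ``skip_report`` (keys ``multiallelic``, ``indel``); the invariant
    ``len(sites) + sum(skip_report.values()) == total records`` holds.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a parseable VCF ({exc})") from exc
    samples = list(vf.header.samples)
    sites: list[VariantSite] = []
    skip: dict[str, int] = {}
    has_ad = "AD" in vf.header.formats
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            skip["multiallelic"] = skip.get("multiallelic", 0) + 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            skip["indel"] = skip.get("indel", 0) + 1
            continue
        if "GT" not in rec.format:
            raise FormatError(f"{path}: record {rec.chrom}:{rec.pos} has no GT field")
        genos = np.empty(len(samples), dtype=np.int8)
        depths = np.full((len(samples), 2), -1, dtype=np.int32) if has_ad else None
        for i, name in enumerate(samples):
            call = rec.samples[name]
            genos[i] = _code_gt(call.get("GT"))
            if has_ad:
                ad = call.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
                    depths[i] = (ad[0], ad[1])
        sites.append(
            VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=ref,
                alt=alt,
                genotypes=genos,
                allele_depths=depths,
                site_id=rec.id or ".",
            )
        )
    vf.close()
    return VariantSet(sites=sites, samples=samples, skip_report=skip)


_GT_STRINGS = {GT_MISSING: "./.", GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1"}


def write_vcf(
    variants: VariantSet,
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write a minimal VCF v4.2 with GT (and AD where present)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelmap\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            seen: dict[str, int] = {}
            for s in variants.sites:
                seen[s.chrom] = max(seen.get(s.chrom, 0), s.pos)
            for name, length in seen.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        any_ad = any(s.allele_depths is not None for s in variants.sites)
        if any_ad:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(variants.samples) + "\n")
        for s in variants.sites:
            fmt = "GT:AD" if (any_ad and s.allele_depths is not None) else "GT"
            cols = [s.chrom, str(s.pos), s.site_id, s.ref, s.alt, ".", "PASS", ".", fmt]
            for i in range(s.n_samples):
                cell = _GT_STRINGS[int(s.genotypes[i])]
                if fmt == "GT:AD":
                    rd, ad = s.allele_depths[i]
                    cell += f":{rd},{ad}" if rd >= 0 else ":.,."
                cols.append(cell)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Annotation (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene reduced to its longest mRNA's CDS chain."""

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    gene_span: tuple[int, int]

    def __post_init__(self) -> None:
        self.cds_segments = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(self.cds_segments, self.cds_segments[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS segments")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def coding_complete(self) -> bool:
        return self.cds_length > 0 and self.cds_length % 3 == 0

    def contains(self, pos: int) -> bool:
        return self.gene_span[0] <= pos <= self.gene_span[1]

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_segments)


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 into gene models, taking the longest mRNA's CDS per gene.

    CDS features without a resolvable parent are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    known_parents = {f.id for f in db.all_features() if f.featuretype in ("gene", "mRNA")}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not any(p in known_parents for p in parents):
            warnings.warn(f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no parent; skipped")
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: list[tuple[int, int]] = []
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            for m in mrnas:
                segs = [(c.start, c.end) for c in db.children(m, featuretype="CDS")]
                if sum(e - s + 1 for s, e in segs) > sum(e - s + 1 for s, e in best):
                    best = segs
        else:  # genes with CDS children directly
            best = [(c.start, c.end) for c in db.children(gene, featuretype="CDS")]
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                cds_segments=sorted(best),
                gene_span=(gene.start, gene.end),
            )
        )
    return genes


def write_gff(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene → mRNA → CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.gene_span
            fh.write(
                f"{g.chrom}\tpanelmap\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tpanelmap\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for cs, ce in g.cds_segments:
                fh.write(
                    f"{g.chrom}\tpanelmap\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\t"
                    f"Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# Intervals (BED)
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Sequence[tuple], path: str | Path, header_comment: str | None = None
) -> None:
    """Write (chrom, start, end[, name]) 1-based inclusive intervals as BED.

    BED is 0-based half-open, so each line is (chrom, start-1, end).
    An empty interval list yields a file with only a header comment.
    """
    with open(path, "w") as fh:
        if header_comment or not intervals:
            fh.write(f"# {header_comment or 'no intervals'}\n")
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if end < start:
                raise ValueError(f"interval {chrom}:{start}-{end} has end < start")
            rest = "\t".join(str(x) for x in iv[3:])
            fh.write(f"{chrom}\t{start - 1}\t{end}" + (f"\t{rest}" if rest else "") + "\n")
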