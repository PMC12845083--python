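"""VCF ingestion and emission for bulk-segregant sequencing data.

The central record is :class:`BulkSnp`: one biallelic site with per-bulk
(ref, alt) read depths taken from the per-sample ``AD`` field of a
multi-sample VCF.  Ingestion keeps biallelic SNPs only by default, drops
records with malformed allelic depths (never zero-fills them), and can
polarize alleles so that the ALT allele is the one carried by the
designated high-trait parent — the convention under which the signed
ΔSNP-index is well defined.

Coordinates: VCF positions are 1-based and stay 1-based in ``BulkSnp``;
window arithmetic downstream uses 0-based half-open intervals internally.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

__all__ = [
    "BulkSnp",
    "IngestReport",
    "read_bulk_vcf",
    "filter_depth",
    "polarize",
    "write_vcf",
    "write_site_table",
    "site_arrays",
]


@dataclass(frozen=True)
class BulkSnp:
    """A polarized biallelic site with per-bulk allelic read depths.

    ``polarized`` is True when ``alt_allele`` is known to be the allele of
    the high-trait parent; ``unpolarizable`` marks sites where the parent
    calls could not orient the site (kept for |Δ|, G and ED scans, excluded
    from signed-Δ scans).
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    depth_a_ref: int
    depth_a_alt: int
    depth_b_ref: int
    depth_b_alt: int
    polarized: bool = False
    unpolarizable: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for d in (self.depth_a_ref, self.depth_a_alt, self.depth_b_ref, self.depth_b_alt):
            if d < 0:
                raise ValueError("read depths must be non-negative")

    @property
    def total_a(self) -> int:
        return self.depth_a_ref + self.depth_a_alt

    @property
    def total_b(self) -> int:
        return self.depth_b_ref + self.depth_b_alt


@dataclass
class IngestReport:
    """Bookkeeping for every record class seen during VCF ingestion."""

    n_total: int = 0
    n_multiallelic_dropped: int = 0
    n_indel_dropped: int = 0
    n_missing_ad_dropped: int = 0
    n_depth_filtered: int = 0
    n_retained: int = 0

    def check(self) -> None:
        dropped = (
            self.n_multiallelic_dropped
            + self.n_indel_dropped
            + self.n_missing_ad_dropped
            + self.n_depth_filtered
        )
        if self.n_retained + dropped != self.n_total:
            raise AssertionError("ingest report counts do not sum to n_total")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _ad_pair(sample_record) -> Optional[tuple[int, int]]:
    """Extract a (ref, alt) AD pair; None when missing or malformed."""
    try:
        ad = sample_record["AD"]
    except KeyError:
        return None
    if ad is None:
        return None
    vals = tuple(ad)
    if len(vals) < 2 or any(v is None for v in vals[:2]):
        return None
    try:
        return int(vals[0]), int(vals[1])
    except (TypeError, ValueError):
        return None


def _gt_pair(sample_record) -> Optional[tuple]:
    try:
        gt = sample_record["GT"]
    except KeyError:
        return None
    if gt is None or any(a is None for a in gt):
        return None
    return tuple(gt)


def read_bulk_vcf(
    path: str | os.PathLike,
    bulk_a: str,
    bulk_b: str,
    parent_high: Optional[str] = None,
    parent_low: Optional[str] = None,
    keep_indels: bool = False,
) -> tuple[list[BulkSnp], IngestReport]:
    """Read a multi-sample VCF into a sorted list of :class:`BulkSnp`.

    Biallelic SNPs only (``keep_indels`` re-admits length-changing
    alleles); records with missing/malformed AD in either bulk are dropped
    and counted.  When parent sample names are given, each site is
    polarized from their genotype calls (see :func:`polarize`).

    Raises
    ------
    ValueError
        If a named sample is absent from the VCF header.
    """
    vcf = pysam.VariantFile(os.fspath(path))
    samples = list(vcf.header.samples)
    for name in filter(None, (bulk_a, bulk_b, parent_high, parent_low)):
        if name not in samples:
            raise ValueError(f"sample {name!r} not found in VCF header (has {samples})")
    if "AD" not in vcf.header.formats:
        raise ValueError("VCF header does not define the per-sample AD format field")

    sites: list[BulkSnp] = []
    report = IngestReport()
    for rec in vcf:
        report.n_total += 1
        alts = rec.alts or ()
        if len(alts) != 1:
            report.n_multiallelic_dropped += 1
            continue
        ref, alt = rec.ref, alts[0]
        is_indel = len(ref) != 1 or len(alt) != 1 or alt.startswith("<")
        if is_indel and not keep_indels:
            report.n_indel_dropped += 1
            continue
        ad_a = _ad_pair(rec.samples[bulk_a])
        ad_b = _ad_pair(rec.samples[bulk_b])
        if ad_a is None or ad_b is None:
            report.n_missing_ad_dropped += 1
            continue
        site = BulkSnp(
            chrom=rec.chrom,
            pos=rec.pos,
            ref_allele=ref,
            alt_allele=alt,
            depth_a_ref=ad_a[0],
            depth_a_alt=ad_a[1],
            depth_b_ref=ad_b[0],
            depth_b_alt=ad_b[1],
        )
        if parent_high is not None:
            gt_hi = _gt_pair(rec.samples[parent_high])
            gt_lo = _gt_pair(rec.samples[parent_low]) if parent_low else None
            site = polarize(site, gt_hi, gt_lo)
        sites.append(site)
        report.n_retained += 1
    vcf.close()
    sites.sort(key=lambda s: (s.chrom, s.pos))
    report.check()
    return sites, report


def filter_depth(
    sites: Sequence[BulkSnp], min_depth: int = 10
) -> tuple[list[BulkSnp], int]:
    """Discard sites whose total depth is below ``min_depth`` in either bulk.

    The comparison is strict (< min_depth is discarded), so totals equal to
    the threshold are retained.  Order is preserved.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    kept = [s for s in sites if s.total_a >= min_depth and s.total_b >= min_depth]
    return kept, len(sites) - len(kept)


def _swap(site: BulkSnp, **flags) -> BulkSnp:
    return replace(
        site,
        ref_allele=site.alt_allele,
        alt_allele=site.ref_allele,
        depth_a_ref=site.depth_a_alt,
        depth_a_alt=site.depth_a_ref,
        depth_b_ref=site.depth_b_alt,
        depth_b_alt=site.depth_b_ref,
        **flags,
    )


def polarize(
    site: BulkSnp,
    parent_high_genotype: Optional[tuple],
    parent_low_genotype: Optional[tuple] = None,
) -> BulkSnp:
    """Orient a site so that ALT is the homozygous allele of the high parent.

    Genotypes are tuples of allele indices (``(0, 0)`` hom-ref, ``(1, 1)``
    hom-alt, anything mixed is heterozygous).  A heterozygous or missing
    high-parent call — or both parents homozygous for the same allele —
    leaves the depths untouched and flags the site ``unpolarizable``.
    """
    gt_hi = parent_high_genotype
    if gt_hi is None or len(set(gt_hi)) != 1:
        return replace(site, polarized=False, unpolarizable=True)
    hi_allele = gt_hi[0]
    if parent_low_genotype is not None and len(set(parent_low_genotype)) == 1:
        if parent_low_genotype[0] == hi_allele:
            # parents agree: the site carries no polarizing information
            return replace(site, polarized=False, unpolarizable=True)
    if hi_allele == 1:
        return replace(site, polarized=True, unpolarizable=False)
    if hi_allele == 0:
        return _swap(site, polarized=True, unpolarizable=False)
    return replace(site, polarized=False, unpolarizable=True)


def write_vcf(
    sites: Sequence[BulkSnp],
    path: str | os.PathLike,
    contig_lengths: dict[str, int],
    bulk_a: str = "bulk_a",
    bulk_b: str = "bulk_b",
) -> None:
    """Write sites as a VCF 4.2 file with GT and AD for the two bulks.

    Input must be sorted by (chrom, pos) and every position must fall
    within its declared contig length; ``read_bulk_vcf`` on the output
    recovers the input depths exactly.
    """
    order = [(s.chrom, s.pos) for s in sites]
    if order != sorted(order):
        raise ValueError("sites must be sorted by (chrom, pos) before writing")
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths for the ref and alt alleles")
    header.add_sample(bulk_a)
    header.add_sample(bulk_b)

    out = pysam.VariantFile(os.fspath(path), "w", header=header)
    try:
        for s in sites:
            if s.chrom not in contig_lengths:
                raise ValueError(f"no contig length declared for {s.chrom}")
            if s.pos > contig_lengths[s.chrom]:
                raise ValueError(
                    f"{s.chrom}:{s.pos} exceeds contig length {contig_lengths[s.chrom]}"
                )
            rec = out.new_record(
                contig=s.chrom, start=s.pos - 1, alleles=(s.ref_allele, s.alt_allele)
            )
            rec.samples[bulk_a]["GT"] = (None, None)
            rec.samples[bulk_a]["AD"] = (s.depth_a_ref, s.depth_a_alt)
            rec.samples[bulk_b]["GT"] = (None, None)
            rec.samples[bulk_b]["AD"] = (s.depth_b_ref, s.depth_b_alt)
            out.write(rec)
    finally:
        out.close()


def write_site_table(sites: Iterable[BulkSnp], path: str | os.PathLike) -> None:
    """Write the TSV site table (one row per site, depths and flags)."""
    cols = (
        "chrom\tpos\tref\talt\tad_a_ref\tad_a_alt\tad_b_ref\tad_b_alt\tpolarized\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t"
                f"{s.depth_a_ref}\t{s.depth_a_alt}\t{s.depth_b_ref}\t{s.depth_b_alt}\t"
                f"{int(s.polarized)}\n"
            )


def site_arrays(sites: Sequence[BulkSnp]) -> dict[str, np.ndarray]:
    """Columnar view of a site list for the vectorized scan machinery."""
    return {
        "chrom": np.asarray([s.chrom for s in sites], dtype=object),
        "pos": np.asarray([s.pos for s in sites], dtype=np.int64),
        "a_ref": np.asarray([s.depth_a_ref for s in sites], dtype=np.int64),
        "a_alt": np.asarray([s.depth_a_alt for s in sites], dtype=np.int64),
        "b_ref": np.asarray([s.depth_b_ref for s in sites], dtype=np.int64),
        "b_alt": np.asarray([s.depth_b_alt for s in sites], dtype=np.int64),
    }
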