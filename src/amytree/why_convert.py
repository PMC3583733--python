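"""WHY conversion tool: variant-call formats -> SNP calling profile.

Whole-genome SNP callers mostly emit VCF; Complete Genomics pipelines emit
their own tab-separated ``var`` format. The converter keeps only single-base
substitutions on the Y chromosome that the sample actually carries and
writes them as the three-column profile consumed by the assignment pipeline.
Everything else is counted, never fatal.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from cyvcf2 import VCF

from .core_model import BASES, SnpCall, SnpProfile

logger = logging.getLogger("amytree")

__all__ = ["ConversionStats", "convert_vcf", "convert_cga", "is_y_chromosome"]

_Y_NAMES = {"Y", "CHRY", "24", "CHR24"}

# Columns the Complete Genomics ``var`` reader needs (extra columns tolerated).
CGA_REQUIRED_COLUMNS = ("chromosome", "begin", "end", "varType", "reference", "alleleSeq")


@dataclass
class ConversionStats:
    """Classification counts for one conversion run.

    Every input record lands in exactly one bucket, so
    ``n_input_records == n_y_snps_kept + n_non_y_skipped + n_non_snp_skipped``.
    ``n_non_snp_skipped`` covers every Y-chromosome record that is not a
    usable haploid SNP call: indels and multi-base alleles, heterozygous
    genotypes (artifacts on a haploid chromosome), and records whose
    genotype does not carry an alternate allele.
    """

    n_input_records: int = 0
    n_y_snps_kept: int = 0
    n_non_y_skipped: int = 0
    n_non_snp_skipped: int = 0

    def check(self) -> None:
        assert self.n_input_records == (
            self.n_y_snps_kept + self.n_non_y_skipped + self.n_non_snp_skipped
        ), "conversion classification is not a partition"


def is_y_chromosome(chrom: str) -> bool:
    """Accept the common spellings of the Y chromosome (Y, chrY, 24)."""
    return chrom.strip().upper() in _Y_NAMES


def convert_vcf(path: str | Path, build: str,
                sample: Optional[str] = None) -> tuple[SnpProfile, ConversionStats]:
    """Convert a VCF into a Y-SNP profile.

    Kept records have a Y-chromosome CHROM, single-base REF and ALT, and a
    genotype that carries the ALT (haploid or homozygous alternate).
    Heterozygous genotypes are skipped with a warning; for multi-allelic
    records the first alternate allele present in the genotype is taken,
    with a warning. A sites-only VCF (no sample columns) is treated as
    carrying the first ALT of every record.
    """
    stats = ConversionStats()
    vcf = VCF(str(path))
    if sample is not None:
        if sample not in vcf.samples:
            raise ValueError(f"{path}: sample {sample!r} not in VCF (has {vcf.samples})")
        vcf.set_samples([sample])
    sample_id = (sample or (vcf.samples[0] if vcf.samples else None)) or Path(path).stem
    profile = SnpProfile(build, sample_id=sample_id)

    for variant in vcf:
        stats.n_input_records += 1
        if not is_y_chromosome(variant.CHROM):
            stats.n_non_y_skipped += 1
            continue
        ref = variant.REF.upper()
        alts = [a.upper() for a in variant.ALT]
        if len(ref) != 1 or ref not in BASES or not alts:
            stats.n_non_snp_skipped += 1
            continue
        alt = _carried_alt(variant, alts)
        if alt is None or len(alt) != 1 or alt not in BASES:
            stats.n_non_snp_skipped += 1
            continue
        if len(alts) > 1:
            logger.warning("%s: multi-allelic record at %s:%d; taking carried ALT %s",
                           path, variant.CHROM, variant.POS, alt)
        profile.add(SnpCall(variant.POS, ref, alt))
        stats.n_y_snps_kept += 1

    stats.check()
    logger.info("%s: %d records -> %d Y-SNPs kept, %d non-Y, %d non-SNP",
                path, stats.n_input_records, stats.n_y_snps_kept,
                stats.n_non_y_skipped, stats.n_non_snp_skipped)
    return profile, stats


def _carried_alt(variant, alts: list[str]) -> Optional[str]:
    """The alternate allele the sample's genotype carries, or None."""
    genotypes = variant.genotypes
    if not genotypes:  # sites-only VCF
        return alts[0]
    alleles = [int(a) for a in genotypes[0][:-1] if int(a) >= 0]
    if not alleles:
        return None
    non_ref = sorted({a for a in alleles if a > 0})
    if not non_ref:
        return None  # homozygous reference
    if 0 in alleles or len(non_ref) > 1:
        logger.warning("heterozygous genotype on the haploid Y at position %d; skipped",
                       variant.POS)
        return None
    return alts[non_ref[0] - 1]


def convert_cga(path: str | Path, build: str) -> tuple[SnpProfile, ConversionStats]:
    """Convert a Complete Genomics ``var`` file into a Y-SNP profile.

    Comment lines starting with ``#`` are skipped; the header row (its
    leading ``>`` is tolerated) must contain the columns
    ``chromosome, begin, end, varType, reference, alleleSeq``. Rows with
    varType ``snp`` on the Y chromosome become calls. Coordinates are
    0-based half-open, so a one-base SNP with begin b, end b+1 maps to the
    1-based position b+1 (= end).
    """
    stats = ConversionStats()
    profile = SnpProfile(build, sample_id=Path(path).stem)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for row in reader:
            if not row or not "".join(row).strip():
                continue
            if row[0].startswith("#"):
                continue
            if header is None:
                header = [c.lstrip(">").strip() for c in row]
                missing = [c for c in CGA_REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}: unknown var-file layout, missing columns {missing}; "
                        f"expected at least {list(CGA_REQUIRED_COLUMNS)}"
                    )
                idx = {c: header.index(c) for c in CGA_REQUIRED_COLUMNS}
                continue
            stats.n_input_records += 1
            try:
                chrom = row[idx["chromosome"]]
                end = int(row[idx["end"]])
                var_type = row[idx["varType"]]
                ref = row[idx["reference"]].upper()
                obs = row[idx["alleleSeq"]].upper()
            except (IndexError, ValueError):
                stats.n_non_snp_skipped += 1
                continue
            if not is_y_chromosome(chrom):
                stats.n_non_y_skipped += 1
                continue
            if var_type != "snp" or len(ref) != 1 or len(obs) != 1 \
                    or ref not in BASES or obs not in BASES:
                stats.n_non_snp_skipped += 1
                continue
            profile.add(SnpCall(end, ref, obs))
            stats.n_y_snps_kept += 1
    stats.check()
    return profile, stats
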