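"""Reading, filtering and polarizing pooled-sequencing variant records.

The association stage consumes a VCF carrying four samples: the two homozygous
parents (genotypes only) and the two phenotype bulks (AD/DP allele depths).
Before any statistic is computed, sites are reduced to informative biallelic
SNPs (parents homozygous for opposite alleles, both pools adequately covered)
and *polarized*: at every site the "A" allele denotes the fruiting parent's
allele, so that the SNP-index of the fruiting pool approaches 1 at the causal
locus regardless of which allele the reference assembly happens to carry.

After :func:`polarize`, pool AD pairs are stored as ``(non-A count, A count)``;
the pair is swapped wherever the fruiting parent is homozygous reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site with parental genotypes and per-pool allele depths.

    ``pool_*_ad`` pairs are in VCF (ref, alt) order until :func:`polarize`
    marks the record ``oriented``, after which they are (non-A, A) with A the
    fruiting-parent allele.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    parent_F_gt: str
    parent_N_gt: str
    pool_F_ad: tuple[int, int] | None
    pool_N_ad: tuple[int, int] | None
    is_snp: bool
    multiallelic: bool = False
    oriented: bool = False
    a_is_alt: bool | None = None


@dataclass(frozen=True)
class FilterCriteria:
    """Rules reducing raw VCF sites to informative markers.

    Defaults follow conventional BSA-seq practice: biallelic SNPs whose parents
    are homozygous for opposite alleles, with each pool covered between 10x and
    roughly three times the expected mean depth.
    """

    min_pool_depth: int = 10
    max_pool_depth: int = 206  # ~3x the default expected 68.8x pool depth
    require_snp: bool = True
    require_informative_parents: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.min_pool_depth <= self.max_pool_depth):
            raise ValueError("need 0 <= min_pool_depth <= max_pool_depth")


def _classify_gt(gt: tuple | None) -> str:
    if gt is None:
        return MISSING
    alleles = [a for a in gt if a is not None]
    if not alleles or len(alleles) < len(gt):
        return MISSING
    if all(a == 0 for a in alleles):
        return HOM_REF
    if all(a == alleles[0] for a in alleles):
        return HOM_ALT
    return HET


def _parse_ad(ad) -> tuple[int, int] | None:
    if ad is None:
        return None
    vals = tuple(ad) if isinstance(ad, (tuple, list)) else (ad,)
    if len(vals) < 2 or any(v is None for v in vals[:2]):
        return None
    r, a = int(vals[0]), int(vals[1])
    if r < 0 or a < 0:
        raise ValueError(f"malformed AD {vals!r}")
    return (r, a)


def read_variants(
    vcf_path: str | Path,
    parent_F: str,
    parent_N: str,
    pool_F: str,
    pool_N: str,
) -> list[VariantRecord]:
    """Read one :class:`VariantRecord` per VCF data line.

    Multi-allelic sites are retained but flagged (the first ALT is carried);
    missing AD is recorded as ``None``, never as zero depth. The file must be
    coordinate-sorted within each scaffold.
    """
    vcf_path = Path(vcf_path)
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for name in (parent_F, parent_N, pool_F, pool_N):
            if name not in samples:
                raise ValueError(
                    f"sample {name!r} not in {vcf_path.name} (has {samples})"
                )
        seen_chroms: list[str] = []
        last_pos = 0
        for rec in vcf:
            if not seen_chroms or rec.chrom != seen_chroms[-1]:
                if rec.chrom in seen_chroms:
                    raise ValueError(f"unsorted VCF: {rec.chrom} appears twice")
                seen_chroms.append(rec.chrom)
                last_pos = 0
            if rec.pos < last_pos:
                raise ValueError(
                    f"unsorted VCF at {rec.chrom}:{rec.pos} (after {last_pos})"
                )
            last_pos = rec.pos

            alts = rec.alts or ()
            alt = alts[0] if alts else ""
            ref = rec.ref or ""
            is_snp = (
                len(alts) == 1
                and len(ref) == 1
                and len(alt) == 1
                and ref in _BASES
                and alt in _BASES
            )
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    parent_F_gt=_classify_gt(rec.samples[parent_F].get("GT")),
                    parent_N_gt=_classify_gt(rec.samples[parent_N].get("GT")),
                    pool_F_ad=_parse_ad(rec.samples[pool_F].get("AD")),
                    pool_N_ad=_parse_ad(rec.samples[pool_N].get("AD")),
                    is_snp=is_snp,
                    multiallelic=len(alts) > 1,
                )
            )
    return records


def _informative(rec: VariantRecord) -> bool:
    gts = {rec.parent_F_gt, rec.parent_N_gt}
    return gts == {HOM_REF, HOM_ALT}


def filter_variants(
    records: Iterable[VariantRecord], criteria: FilterCriteria | None = None
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the informative-marker rules; return kept records and a tally.

    Each rejected record is tallied under the first rule it fails, so
    ``kept + sum(tally.values()) == input``. Filters never raise on data
    content; a missing or zero-depth pool fails the depth rule.
    """
    criteria = criteria or FilterCriteria()
    kept: list[VariantRecord] = []
    tally = {"not_biallelic_snp": 0, "uninformative_parents": 0, "pool_depth": 0}
    for rec in records:
        if criteria.require_snp and (not rec.is_snp or rec.multiallelic):
            tally["not_biallelic_snp"] += 1
            continue
        if criteria.require_informative_parents and not _informative(rec):
            tally["uninformative_parents"] += 1
            continue
        depth_ok = True
        for ad in (rec.pool_F_ad, rec.pool_N_ad):
            d = 0 if ad is None else ad[0] + ad[1]
            if d == 0 or not (criteria.min_pool_depth <= d <= criteria.max_pool_depth):
                depth_ok = False
                break
        if not depth_ok:
            tally["pool_depth"] += 1
            continue
        kept.append(rec)
    return kept, tally


def polarize(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Orient every site so the "A" allele is the fruiting parent's allele.

    Pool AD pairs become (non-A, A): where the fruiting parent is homozygous
    for the ALT allele the VCF (ref, alt) order already has A second and the
    pair is untouched; where it is homozygous REF the pair is swapped.
    Idempotent: an already-oriented record passes through unchanged.
    """
    out: list[VariantRecord] = []
    for rec in records:
        if rec.oriented:
            out.append(rec)
            continue
        if rec.parent_F_gt == HOM_ALT and rec.parent_N_gt == HOM_REF:
            out.append(replace(rec, oriented=True, a_is_alt=True))
        elif rec.parent_F_gt == HOM_REF and rec.parent_N_gt == HOM_ALT:
            swap = lambda ad: None if ad is None else (ad[1], ad[0])  # noqa: E731
            out.append(
                replace(
                    rec,
                    pool_F_ad=swap(rec.pool_F_ad),
                    pool_N_ad=swap(rec.pool_N_ad),
                    oriented=True,
                    a_is_alt=False,
                )
            )
        else:
            raise ValueError(
                f"cannot polarize {rec.chrom}:{rec.pos}: parents "
                f"{rec.parent_F_gt}/{rec.parent_N_gt} are not opposite homozygotes"
            )
    return out


def prepare_variants(
    vcf_path: str | Path,
    parent_F: str,
    parent_N: str,
    pool_F: str,
    pool_N: str,
    criteria: FilterCriteria | None = None,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """read -> filter -> polarize in one call; returns oriented records + tally."""
    records = read_variants(vcf_path, parent_F, parent_N, pool_F, pool_N)
    kept, tally = filter_variants(records, criteria)
    return polarize(kept), tally
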