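"""QTL interval calling and candidate-gene / coding-variant annotation.

Smoothed statistic tracks plus null thresholds become per-method significant
regions (maximal above-threshold marker runs); the genomic intersection of the
four methods' regions is the consensus QTL interval. Genes overlapping a
consensus interval are pulled from the GFF3 annotation, variants are assigned
to gene features, coding changes are classified by codon translation, and
candidates are ranked by association (with optional conserved-domain evidence
as an input annotation, mirroring how a CDD lookup is used in practice).

All external coordinates are 1-based closed (VCF/GFF convention); BED export
converts to 0-based half-open in one place (:func:`region_to_bed_fields`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .bsa_statistics import SmoothedTrack
from .variant_io import VariantRecord

METHODS = ("delta_snp_index", "ed", "g", "fisher")

CODING_EFFECTS = frozenset({"missense", "nonsense", "start_loss"})


# ---------------------------------------------------------------------------
# regions and consensus intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignificantRegion:
    """A contiguous above-threshold run of markers for one method (1-based closed)."""

    chrom: str
    start: int
    end: int
    method: str
    peak_pos: int
    peak_value: float
    n_sites: int


@dataclass(frozen=True)
class QtlInterval:
    """A consensus interval supported by >= consensus_level methods."""

    chrom: str
    start: int
    end: int
    supporting_methods: frozenset[str]
    member_regions: tuple[SignificantRegion, ...] = ()


def call_regions(
    track: SmoothedTrack,
    threshold: float,
    max_gap: int = 1_000_000,
    method: str = "",
) -> list[SignificantRegion]:
    """Maximal runs of significant sites, merging runs <= max_gap bp apart.

    A site is significant when its (smoothed) value >= threshold — ties count.
    Region span is [first site pos, last site pos]; the peak is the member
    site with the largest value.
    """
    regions: list[SignificantRegion] = []
    sig = track.values >= threshold
    n = len(sig)
    i = 0
    runs: list[tuple[str, int, int]] = []  # (chrom, start_idx, end_idx) inclusive
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and track.chroms[j + 1] == track.chroms[i]:
            j += 1
        runs.append((track.chroms[i], i, j))
        i = j + 1
    # merge runs on the same scaffold separated by <= max_gap bp
    merged: list[tuple[str, int, int]] = []
    for chrom, a, b in runs:
        if (
            merged
            and merged[-1][0] == chrom
            and track.positions[a] - track.positions[merged[-1][2]] <= max_gap
        ):
            merged[-1] = (chrom, merged[-1][1], b)
        else:
            merged.append((chrom, a, b))
    for chrom, a, b in merged:
        idx = np.arange(a, b + 1)
        member = idx[sig[a : b + 1]]
        peak = member[np.argmax(track.values[member])]
        regions.append(
            SignificantRegion(
                chrom=str(chrom),
                start=int(track.positions[a]),
                end=int(track.positions[b]),
                method=method or track.statistic,
                peak_pos=int(track.positions[peak]),
                peak_value=float(track.values[peak]),
                n_sites=int(member.size),
            )
        )
    return regions


def consensus_intervals(
    regions_by_method: Mapping[str, Sequence[SignificantRegion]],
    consensus_level: int | None = None,
) -> list[QtlInterval]:
    """Maximal genomic intervals covered by >= consensus_level methods.

    With the default level (all methods) this is the exact set intersection of
    the per-method region footprints; any method with no overlapping region
    empties the consensus.
    """
    n_methods = len(regions_by_method)
    if consensus_level is None:
        consensus_level = n_methods
    if not (1 <= consensus_level <= n_methods):
        raise ValueError(
            f"consensus_level {consensus_level} outside [1, {n_methods}]"
        )
    # sweep-line over half-open coordinates, one +-1 event pair per merged
    # per-method interval so overlapping regions of one method count once
    chroms = sorted(
        {r.chrom for regs in regions_by_method.values() for r in regs}
    )
    out: list[QtlInterval] = []
    for chrom in chroms:
        events: list[tuple[int, int]] = []
        for method, regs in regions_by_method.items():
            ivals = sorted(
                (r.start, r.end + 1) for r in regs if r.chrom == chrom
            )
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                events.append((s, +1))
                events.append((e, -1))
        events.sort()
        depth = 0
        seg_start: int | None = None
        pieces: list[tuple[int, int]] = []
        for pos, delta in events:
            prev = depth
            depth += delta
            if prev < consensus_level <= depth:
                seg_start = pos
            elif prev >= consensus_level > depth:
                pieces.append((seg_start, pos))  # type: ignore[arg-type]
                seg_start = None
        # merge adjacent pieces (can only touch, not overlap)
        squashed: list[list[int]] = []
        for s, e in pieces:
            if squashed and s <= squashed[-1][1]:
                squashed[-1][1] = max(squashed[-1][1], e)
            else:
                squashed.append([s, e])
        for s, e in squashed:
            start, end = s, e - 1
            supporting = frozenset(
                m
                for m, regs in regions_by_method.items()
                if any(
                    r.chrom == chrom and r.start <= end and r.end >= start
                    for r in regs
                )
            )
            members = tuple(
                r
                for regs in regions_by_method.values()
                for r in regs
                if r.chrom == chrom and r.start <= end and r.end >= start
            )
            out.append(
                QtlInterval(
                    chrom=chrom,
                    start=start,
                    end=end,
                    supporting_methods=supporting,
                    member_regions=members,
                )
            )
    return out


def region_to_bed_fields(chrom: str, start: int, end: int) -> tuple[str, int, int]:
    """1-based closed genomic interval -> BED (0-based half-open) fields."""
    if start < 1 or end < start:
        raise ValueError(f"bad interval {chrom}:{start}-{end}")
    return chrom, start - 1, end


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one gene (1-based closed genomic coordinates).

    ``exons`` and ``cds`` are tuples of (start, end) / (start, end, phase) in
    ascending genomic order; ``strand`` is '+' or '-'.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int, int], ...]
    name: str = ""
    flags: tuple[str, ...] = field(default=())

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)


def read_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 file into GeneModels."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        cds = []
        for child in db.children(gene, featuretype="exon", order_by="start"):
            exons.append((child.start, child.end))
        for child in db.children(gene, featuretype="CDS", order_by="start"):
            phase = int(child.frame) if child.frame not in (None, ".") else 0
            cds.append((child.start, child.end, phase))
        name = gene.attributes.get("Name", [gene.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=tuple(exons),
                cds=tuple(cds),
                name=name,
            )
        )
    return genes


def genes_in_interval(
    genes: Sequence[GeneModel],
    interval: tuple[str, int, int],
    known_chroms: Iterable[str] | None = None,
) -> list[GeneModel]:
    """Genes whose span overlaps the (chrom, start, end) interval by >= 1 bp.

    ``known_chroms`` (e.g. FASTA scaffold names) enables the unknown-scaffold
    check; without it any scaffold is accepted and a gene desert yields [].
    """
    chrom, start, end = interval
    if known_chroms is not None and chrom not in set(known_chroms):
        raise ValueError(f"unknown scaffold {chrom!r}")
    hits = [
        g
        for g in genes
        if g.chrom == chrom and g.start <= end and g.end >= start
    ]
    return sorted(hits, key=lambda g: (g.start, g.end))


# ---------------------------------------------------------------------------
# variant-to-feature assignment and effect classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureAssignment:
    variant: VariantRecord
    gene_id: str | None
    feature: str  # 'CDS' | 'exon' | 'intron' | 'intergenic'
    cds_pos: int | None  # 1-based offset within the spliced CDS


def _cds_position(gene: GeneModel, pos: int) -> int | None:
    """1-based CDS-relative offset of a genomic position, or None outside CDS."""
    if gene.strand == "+":
        cum = 0
        for s, e, _ in gene.cds:
            if s <= pos <= e:
                return cum + (pos - s) + 1
            cum += e - s + 1
    else:
        cum = 0
        for s, e, _ in reversed(gene.cds):
            if s <= pos <= e:
                return cum + (e - pos) + 1
            cum += e - s + 1
    return None


def variants_in_genes(
    variants: Sequence[VariantRecord], genes: Sequence[GeneModel]
) -> list[FeatureAssignment]:
    """Assign each variant to the gene feature it falls in.

    A variant inside a gene span is 'CDS' (with its spliced-CDS offset) when it
    hits a CDS interval, 'exon' when it hits a non-coding exon stretch, else
    'intron'; outside every gene span it is 'intergenic'. Genes whose total
    CDS length is not a codon multiple are flagged with a warning.
    """
    for g in genes:
        if g.cds and g.cds_length % 3 != 0:
            warnings.warn(
                f"gene {g.gene_id}: CDS length {g.cds_length} not divisible by 3",
                stacklevel=2,
            )
    out: list[FeatureAssignment] = []
    for v in variants:
        assigned = False
        for g in genes:
            if g.chrom != v.chrom or not (g.start <= v.pos <= g.end):
                continue
            cds_pos = _cds_position(g, v.pos)
            if cds_pos is not None:
                out.append(FeatureAssignment(v, g.gene_id, "CDS", cds_pos))
            elif any(s <= v.pos <= e for s, e in g.exons):
                out.append(FeatureAssignment(v, g.gene_id, "exon", None))
            else:
                out.append(FeatureAssignment(v, g.gene_id, "intron", None))
            assigned = True
            break
        if not assigned:
            out.append(FeatureAssignment(v, None, "intergenic", None))
    return out


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def spliced_cds(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Extract the spliced CDS sequence of a gene in transcript orientation."""
    seq = genome[gene.chrom]
    parts = [seq[s - 1 : e] for s, e, _ in gene.cds]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
    phase = gene.cds[0][2] if gene.strand == "+" else gene.cds[-1][2]
    return cds[phase:]


def translate_cds(cds_seq: str) -> str:
    """Translate a complete CDS with the standard code, excluding the stop.

    Raises when the length is not a codon multiple or an internal stop codon
    is present (the codon index is named); warns when the sequence does not
    begin with ATG.
    """
    cds_seq = cds_seq.upper()
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"CDS length {len(cds_seq)} not divisible by 3")
    if not cds_seq.startswith("ATG"):
        warnings.warn("CDS does not begin with ATG", stacklevel=2)
    protein = str(Seq(cds_seq).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop at codon {protein.index('*') + 1}")
    return protein


@dataclass(frozen=True)
class EffectCall:
    """Coding consequence of one SNP within a gene's CDS."""

    effect: str  # 'synonymous' | 'missense' | 'nonsense' | 'start_loss' | 'other'
    codon_number: int
    ref_aa: str
    alt_aa: str
    cds_pos: int
    gene_id: str


def classify_effect(
    variant: VariantRecord, gene: GeneModel, genome: Mapping[str, str]
) -> EffectCall:
    """Classify a CDS SNP by mutating its codon and translating both versions.

    Exons are spliced in transcript order (reverse-complemented on the minus
    strand); CDS position 121 is codon 41 position 1. The VCF REF base must
    match the FASTA base at the site.
    """
    seq = genome[variant.chrom]
    genome_base = seq[variant.pos - 1].upper()
    if genome_base != variant.ref.upper():
        raise ValueError(
            f"REF mismatch at {variant.chrom}:{variant.pos}: "
            f"VCF {variant.ref} vs FASTA {genome_base}"
        )
    cds_pos = _cds_position(gene, variant.pos)
    if cds_pos is None:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} is outside the CDS of "
            f"{gene.gene_id}"
        )
    cds = spliced_cds(gene, genome)
    ref_base = variant.ref.upper()
    alt_base = variant.alt.upper()
    if gene.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    if cds[cds_pos - 1] != ref_base:
        raise ValueError(
            f"CDS/genome inconsistency for {gene.gene_id} at CDS position {cds_pos}"
        )
    codon_number = (cds_pos - 1) // 3 + 1
    within = (cds_pos - 1) % 3
    codon = cds[3 * (codon_number - 1) : 3 * codon_number]
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate(table=1))
    alt_aa = str(Seq(alt_codon).translate(table=1))
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    elif codon_number == 1 and ref_aa == "M":
        effect = "start_loss"
    elif ref_aa == "*":
        effect = "other"  # stop loss
    else:
        effect = "missense"
    return EffectCall(
        effect=effect,
        codon_number=codon_number,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        cds_pos=cds_pos,
        gene_id=gene.gene_id,
    )


# ---------------------------------------------------------------------------
# candidate ranking and per-strain concordance
# ---------------------------------------------------------------------------


def candidate_filter(
    annotated: Sequence[tuple[VariantRecord, EffectCall]],
    domains: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Rank protein-changing, fully parent/pool-concordant variants.

    Keeps variants that (a) are missense/nonsense/start-loss, (b) come from
    opposite-homozygous parents (guaranteed for polarized records), and
    (c) have each pool's SNP-index on the expected side of 1/2 (A-index > 1/2
    in the fruiting pool, < 1/2 in the non-fruiting pool). Ranking is by
    conserved-domain membership when a ``{gene_id: [(aa_start, aa_end), ...]}``
    annotation is supplied — association alone cannot separate perfectly
    linked coding variants — then by |delta(SNP-index)| and Fisher evidence.
    """
    from .bsa_statistics import fisher_two_tailed_batch, snp_index

    rows = []
    for variant, effect in annotated:
        if effect.effect not in CODING_EFFECTS:
            continue
        if not variant.oriented:
            raise ValueError("candidate_filter requires polarized records")
        idx_F = snp_index(variant.pool_F_ad)
        idx_N = snp_index(variant.pool_N_ad)
        if not (idx_F > 0.5 and idx_N < 0.5):
            continue
        in_domain = False
        if domains and effect.gene_id in domains:
            in_domain = any(
                lo <= effect.codon_number <= hi
                for lo, hi in domains[effect.gene_id]
            )
        rows.append(
            {
                "chrom": variant.chrom,
                "pos": variant.pos,
                "ref": variant.ref,
                "alt": variant.alt,
                "gene_id": effect.gene_id,
                "effect": effect.effect,
                "codon_number": effect.codon_number,
                "aa_change": f"{effect.ref_aa}{effect.codon_number}{effect.alt_aa}",
                "snp_index_F": idx_F,
                "snp_index_N": idx_N,
                "delta_snp_index": idx_F - idx_N,
                "in_domain": in_domain,
                "a_F": variant.pool_F_ad[1],
                "d_F": sum(variant.pool_F_ad),
                "a_N": variant.pool_N_ad[1],
                "d_N": sum(variant.pool_N_ad),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "chrom", "pos", "ref", "alt", "gene_id", "effect",
                "codon_number", "aa_change", "snp_index_F", "snp_index_N",
                "delta_snp_index", "in_domain", "neg_log10_fisher_p", "rank",
            ]
        )
    df = pd.DataFrame(rows)
    p = fisher_two_tailed_batch(
        df["a_F"].to_numpy(), df["d_F"].to_numpy(),
        df["a_N"].to_numpy(), df["d_N"].to_numpy(),
    )
    df["neg_log10_fisher_p"] = -np.log10(p)
    df["abs_delta"] = df["delta_snp_index"].abs()
    df = df.sort_values(
        ["in_domain", "abs_delta", "neg_log10_fisher_p", "chrom", "pos"],
        ascending=[False, False, False, True, True],
        kind="mergesort",
    ).drop(columns=["abs_delta", "a_F", "d_F", "a_N", "d_N"])
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def genotype_concordance(
    genotypes: Mapping[str, str], phenotypes: Mapping[str, str]
) -> tuple[float, pd.DataFrame]:
    """Fraction of strains whose allele matches the phenotype-expected parent.

    ``genotypes`` maps strain id -> parental-origin allele ('F' fruiting-parent
    or 'N'); ``phenotypes`` maps strain id -> 'fruiting'/'non_fruiting'. A
    strain carrying the fruiting-parent allele is expected to fruit. Returns
    the concordant fraction and the 2x2 allele-by-phenotype table.
    """
    g_ids = set(genotypes)
    p_ids = set(phenotypes)
    if g_ids != p_ids:
        missing = sorted(g_ids ^ p_ids)
        raise ValueError(f"strains present in only one input: {missing}")
    if not g_ids:
        raise ValueError("no strains")
    table = pd.DataFrame(
        0,
        index=pd.Index(["F", "N"], name="allele"),
        columns=pd.Index(["fruiting", "non_fruiting"], name="phenotype"),
    )
    concordant = 0
    for strain in genotypes:
        allele = genotypes[strain]
        pheno = phenotypes[strain]
        if allele not in ("F", "N") or pheno not in ("fruiting", "non_fruiting"):
            raise ValueError(f"bad labels for strain {strain}: {allele}/{pheno}")
        table.loc[allele, pheno] += 1
        if (allele == "F") == (pheno == "fruiting"):
            concordant += 1
    return concordant / len(genotypes), table
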