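"""Synthetic haploid-cross dataset generator for pooled trait mapping.

Emulates the study design the pipeline targets: two fully homozygous
monokaryotic parents differing in a single fully penetrant fruiting locus, a
segregating population of haploid (monokaryotic) F1 strains produced by
simulated meioses, two phenotype bulks, and pooled short-read allele depths at
a genome-wide SNP marker set. Defaults reproduce the study scale: 156 progeny,
bulks of 24 strains, 7021 biallelic SNP markers, ~68.8x mean pool depth, on a
stand-in genome of 10 scaffolds x 3.5 Mb (the real assembly geometry is not
public; only the scale matters for the statistics).

The causal locus is implanted as a real coding variant: a multi-exon gene is
written into the genome around the causal position so that the causal SNP is a
T->G missense change at CDS position 121 (codon 41, Ser->Ala) of a 1710 bp CDS
— a 569-residue protein — with a conserved-domain annotation spanning the
mutated codon, plus four flanking genes tiling the surrounding ~10 kb. All
emitted files (VCF 4.2, GFF3, FASTA, TSV) are plain text and byte-reproducible
from the seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qtl_mapping import GeneModel

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic cross and sequencing model.

    Defaults are the study conditions: 156 haploid progeny, two bulks of 24,
    7021 markers, 68.8x expected pool depth. ``recomb_rate`` is crossovers per
    Mb per meiosis (0.3 ~ a 30 cM/Mb basidiomycete map); ``seq_error`` is a
    per-read allele-flip probability; ``penetrance`` is the probability a
    fruiting-allele carrier fruits; ``misclass_rate`` flips the recorded
    phenotype label.
    """

    n_scaffolds: int = 10
    scaffold_lengths: tuple[int, ...] = (3_500_000,) * 10
    n_markers: int = 7021
    n_progeny: int = 156
    pool_size: int = 24
    mean_depth: float = 68.8
    seq_error: float = 0.001
    recomb_rate: float = 0.3
    causal_locus: tuple[str, int] = ("scaffold5", 1_750_000)
    penetrance: float = 1.0
    misclass_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or len(self.scaffold_lengths) != self.n_scaffolds:
            raise ValueError("scaffold_lengths must have n_scaffolds entries")
        if any(length < 1 for length in self.scaffold_lengths):
            raise ValueError("scaffold lengths must be positive")
        if self.n_markers < 0 or self.n_progeny < 1 or self.pool_size < 0:
            raise ValueError("counts must be non-negative (n_progeny >= 1)")
        if 2 * self.pool_size > self.n_progeny:
            raise ValueError("need 2*pool_size <= n_progeny")
        if self.n_markers > sum(self.scaffold_lengths):
            raise ValueError("more markers than representable genome positions")
        if not (0.0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must lie in [0, 0.5)")
        for name, p in (("penetrance", self.penetrance),
                        ("misclass_rate", self.misclass_rate)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_depth <= 0 or self.recomb_rate < 0:
            raise ValueError("mean_depth must be > 0 and recomb_rate >= 0")
        chrom, pos = self.causal_locus
        names = self.scaffold_names
        if chrom not in names:
            raise ValueError(f"causal scaffold {chrom!r} not among {names}")
        if not (1 <= pos <= self.scaffold_lengths[names.index(chrom)]):
            raise ValueError("causal position outside its scaffold")

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaffold{i + 1}" for i in range(self.n_scaffolds)]

    def scaffold_length(self, chrom: str) -> int:
        return self.scaffold_lengths[self.scaffold_names.index(chrom)]


def sim_config_to_yaml(config: SimConfig) -> str:
    d = {
        "n_scaffolds": config.n_scaffolds,
        "scaffold_lengths": list(config.scaffold_lengths),
        "n_markers": config.n_markers,
        "n_progeny": config.n_progeny,
        "pool_size": config.pool_size,
        "mean_depth": config.mean_depth,
        "seq_error": config.seq_error,
        "recomb_rate": config.recomb_rate,
        "causal_locus": list(config.causal_locus),
        "penetrance": config.penetrance,
        "misclass_rate": config.misclass_rate,
        "seed": config.seed,
    }
    return yaml.safe_dump(d, sort_keys=False)


def load_sim_config(path: str | Path) -> SimConfig:
    """Build a SimConfig from a YAML file; absent keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "scaffold_lengths" in kwargs:
        kwargs["scaffold_lengths"] = tuple(kwargs["scaffold_lengths"])
    if "causal_locus" in kwargs:
        chrom, pos = kwargs["causal_locus"]
        kwargs["causal_locus"] = (str(chrom), int(pos))
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# genome and gene implantation
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Causal gene architecture: 7 coding exons (1710 bp CDS incl. stop -> 569 aa),
# 6 introns, 2193 bp span; CDS position 121 (codon 41, forced TCT) sits in the
# third exon, 280 bp downstream of the gene start.
_CAUSAL_EXONS = (60, 50, 300, 400, 400, 300, 200)
_CAUSAL_INTRONS = (80, 80, 80, 81, 81, 81)
_CAUSAL_CDS_OFFSET_IN_GENE = 280  # genomic offset of CDS position 121
CAUSAL_CDS_POS = 121
CAUSAL_CODON = 41
CAUSAL_DOMAIN = (30, 80)  # conserved-domain codon range on the causal gene

# Flanking genes: (genomic start offset from the causal position, strand,
# coding-exon lengths, intron lengths) tiling ~10 kb around the locus.
_FLANK_GENES = (
    (-1806, "-", (300, 399), (671,)),
    (2003, "+", (450, 600), (473,)),
    (3624, "-", (240, 300, 300), (271, 271)),
    (6024, "+", (300, 300), (901,)),
)


def _random_cds_codons(
    n_codons: int, rng: np.random.Generator, special: Mapping[int, str] | None = None
) -> str:
    """ATG + random non-stop codons + TAA, with 1-based codon overrides."""
    codons = ["ATG"]
    codons += list(rng.choice(_NONSTOP_CODONS, size=n_codons - 2))
    codons.append("TAA")
    for number, codon in (special or {}).items():
        if not (1 < number < n_codons) or codon in _STOPS:
            raise ValueError(f"bad codon override {number}:{codon}")
        codons[number - 1] = codon
    return "".join(codons)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


def _build_gene(
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    exon_cds_lengths: Sequence[int],
    intron_lengths: Sequence[int],
    rng: np.random.Generator,
    special_codons: Mapping[int, str] | None = None,
) -> tuple[GeneModel, str]:
    """Design a gene and its genomic sequence; coding-only exons, valid CDS."""
    total = sum(exon_cds_lengths)
    if total % 3 != 0 or len(intron_lengths) != len(exon_cds_lengths) - 1:
        raise ValueError("bad gene architecture")
    cds_seq = _random_cds_codons(total // 3, rng, special_codons)

    # split the CDS into transcript-order exon pieces
    pieces = []
    off = 0
    for length in exon_cds_lengths:
        pieces.append(cds_seq[off : off + length])
        off += length
    phases = []
    cum = 0
    for length in exon_cds_lengths:
        phases.append((3 - cum % 3) % 3)
        cum += length
    if strand == "-":
        genomic_pieces = [p.translate(_COMPLEMENT)[::-1] for p in reversed(pieces)]
        genomic_lengths = list(reversed(exon_cds_lengths))
        genomic_phases = list(reversed(phases))
        genomic_introns = list(reversed(intron_lengths))
    else:
        genomic_pieces = pieces
        genomic_lengths = list(exon_cds_lengths)
        genomic_phases = phases
        genomic_introns = list(intron_lengths)

    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int, int]] = []
    pos = start
    for i, (piece, length) in enumerate(zip(genomic_pieces, genomic_lengths)):
        exons.append((pos, pos + length - 1))
        cds.append((pos, pos + length - 1, genomic_phases[i]))
        parts.append(piece)
        pos += length
        if i < len(genomic_introns):
            ilen = genomic_introns[i]
            parts.append("GT" + _random_seq(ilen - 4, rng) + "AG")
            pos += ilen
    gene_seq = "".join(parts)
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        start=start,
        end=start + len(gene_seq) - 1,
        strand=strand,
        exons=tuple(exons),
        cds=tuple(cds),
        name=gene_id,
    )
    return model, gene_seq


def generate_genome(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel], dict[str, list[tuple[int, int]]]]:
    """Random scaffolds with the causal and flanking genes implanted.

    Returns (genome, gene models in genomic order, conserved-domain annotation
    mapping gene id -> [(aa_start, aa_end)]).
    """
    base_lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    raw: dict[str, bytearray] = {}
    for name, length in zip(config.scaffold_names, config.scaffold_lengths):
        arr = base_lookup[rng.integers(0, 4, size=length)]
        raw[name] = bytearray(arr.tobytes())

    chrom, causal_pos = config.causal_locus
    specs = [
        (
            causal_pos - _CAUSAL_CDS_OFFSET_IN_GENE,
            "+",
            _CAUSAL_EXONS,
            _CAUSAL_INTRONS,
            {CAUSAL_CODON: "TCT"},
        )
    ] + [
        (causal_pos + off, strand, exons, introns, None)
        for off, strand, exons, introns in _FLANK_GENES
    ]
    genes: list[GeneModel] = []
    causal_gene_id = ""
    for start, strand, exons, introns, special in sorted(specs):
        if start < 1:
            raise ValueError("causal locus too close to the scaffold start")
        gid = f"simgene_{len(genes) + 1}"
        model, seq = _build_gene(gid, chrom, start, strand, exons, introns, rng, special)
        if model.end > config.scaffold_length(chrom):
            raise ValueError("causal locus too close to the scaffold end")
        raw[chrom][start - 1 : start - 1 + len(seq)] = seq.encode("ascii")
        genes.append(model)
        if special:
            causal_gene_id = gid
    genome = {name: raw[name].decode("ascii") for name in raw}
    assert genome[chrom][causal_pos - 1] == "T"  # codon 41 = TCT by construction
    domains = {causal_gene_id: [CAUSAL_DOMAIN]}
    return genome, genes, domains


# ---------------------------------------------------------------------------
# markers and parents
# ---------------------------------------------------------------------------


def generate_parents(
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    genome: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Marker table plus the two opposite-constant parental haplotypes.

    Markers are placed uniformly at random genome-wide (one forced at the
    causal position when any markers fall on its scaffold), REF taken from the
    genome, ALT a different random base — causal ALT forced to G so the causal
    change is the designed T->G missense. Alleles are coded 0 = REF, 1 = ALT;
    the fruiting parent carries ALT everywhere (all-1), the non-fruiting
    parent REF everywhere (all-0), so every marker is fully informative.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if genome is None:
        genome, _, _ = generate_genome(config, rng)

    names = config.scaffold_names
    lengths = np.asarray(config.scaffold_lengths, dtype=float)
    if config.n_markers == 0:
        markers = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "is_causal"]
        ).astype({"pos": np.int64, "is_causal": bool})
        return markers, np.zeros(0, np.uint8), np.zeros(0, np.uint8)

    counts = rng.multinomial(config.n_markers, lengths / lengths.sum())
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for name, count, length in zip(names, counts, config.scaffold_lengths):
        if count > length:
            raise ValueError(f"more markers than positions on {name}")
        pos = np.sort(rng.choice(length, size=count, replace=False) + 1)
        chroms.extend([name] * count)
        positions.append(pos)
    pos_all = np.concatenate(positions)
    markers = pd.DataFrame({"chrom": chroms, "pos": pos_all.astype(np.int64)})

    # force a marker at the causal position (nearest marker on its scaffold is
    # moved there), so the causal locus is genotyped
    causal_chrom, causal_pos = config.causal_locus
    on_chrom = markers.index[markers["chrom"] == causal_chrom]
    if len(on_chrom):
        exact = markers.loc[on_chrom, "pos"] == causal_pos
        if not exact.any():
            nearest = (markers.loc[on_chrom, "pos"] - causal_pos).abs().idxmin()
            markers.loc[nearest, "pos"] = causal_pos
        markers = markers.sort_values(["chrom", "pos"], key=_scaffold_sort_key(names))
        markers = markers.reset_index(drop=True)

    ref = [genome[c][p - 1] for c, p in zip(markers["chrom"], markers["pos"])]
    others = {b: [x for x in _BASES if x != b] for b in _BASES}
    alt = [others[b][i] for b, i in zip(ref, rng.integers(0, 3, size=len(ref)))]
    markers["ref"] = ref
    markers["alt"] = alt
    is_causal = (markers["chrom"] == causal_chrom) & (markers["pos"] == causal_pos)
    if is_causal.any():
        ci = int(np.flatnonzero(is_causal)[0])
        if markers.loc[ci, "ref"] == "T":
            markers.loc[ci, "alt"] = "G"
    markers["is_causal"] = is_causal.to_numpy()

    n = len(markers)
    hap_F = np.ones(n, dtype=np.uint8)  # fruiting parent: all ALT
    hap_N = np.zeros(n, dtype=np.uint8)  # non-fruiting parent: all REF
    return markers, hap_F, hap_N


def _scaffold_sort_key(names: Sequence[str]):
    order = {name: i for i, name in enumerate(names)}

    def key(col: pd.Series) -> pd.Series:
        if col.name == "chrom":
            return col.map(order)
        return col

    return key


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def origin_from_crossovers(
    positions: np.ndarray, crossovers: Sequence[float], start_parent: int
) -> np.ndarray:
    """Parental origin (0/1) at each marker given crossover breakpoints.

    The origin alternates at every crossover position; markers exactly at a
    breakpoint take the downstream (switched) origin.
    """
    cx = np.sort(np.asarray(crossovers, dtype=float))
    flips = np.searchsorted(cx, np.asarray(positions, dtype=float), side="left")
    return ((start_parent + flips) % 2).astype(np.uint8)


def _scaffold_blocks(
    markers: pd.DataFrame, config: SimConfig
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """(marker indices, positions, scaffold length) per scaffold, cached shape."""
    pos = markers["pos"].to_numpy()
    return [
        (np.asarray(idx), pos[np.asarray(idx)], config.scaffold_length(str(chrom)))
        for chrom, idx in markers.groupby("chrom", sort=False).indices.items()
    ]


def simulate_meiosis(
    markers: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    _blocks: list[tuple[np.ndarray, np.ndarray, int]] | None = None,
) -> np.ndarray:
    """One haploid recombinant: parental-origin vector over all markers.

    Per scaffold the crossover count is Poisson(recomb_rate x length in Mb),
    breakpoints are uniform, and the starting parent is a fair coin — a
    no-interference (Haldane) model. Origin 1 = fruiting parent.
    """
    origin = np.empty(len(markers), dtype=np.uint8)
    for idx, pos, length in _blocks or _scaffold_blocks(markers, config):
        n_cx = rng.poisson(config.recomb_rate * length / 1e6)
        cx = rng.uniform(0.0, length, size=n_cx)
        start = int(rng.integers(0, 2))
        origin[idx] = origin_from_crossovers(pos, cx, start)
    return origin


def simulate_progeny(
    markers: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """n_progeny independent meioses -> origin matrix (progeny x markers)."""
    blocks = _scaffold_blocks(markers, config)
    return np.vstack(
        [
            simulate_meiosis(markers, config, rng, _blocks=blocks)
            for _ in range(config.n_progeny)
        ]
    )


# ---------------------------------------------------------------------------
# phenotypes and pools
# ---------------------------------------------------------------------------

FRUITING = "fruiting"
NON_FRUITING = "non_fruiting"


def causal_marker_index(markers: pd.DataFrame, config: SimConfig) -> int:
    """Index of the marker nearest the causal locus (same scaffold)."""
    chrom, pos = config.causal_locus
    on_chrom = markers.index[markers["chrom"] == chrom]
    if not len(on_chrom):
        raise ValueError(f"no markers on causal scaffold {chrom!r}")
    return int((markers.loc[on_chrom, "pos"] - pos).abs().idxmin())


def assign_phenotypes(
    origins: np.ndarray,
    markers: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotype labels from the causal-marker origin.

    Carriers of the fruiting-parent allele fruit with probability
    ``penetrance``; non-carriers never fruit; each recorded label then flips
    with probability ``misclass_rate``.
    """
    ci = causal_marker_index(markers, config)
    carrier = origins[:, ci] == 1
    n = origins.shape[0]
    fruits = carrier & (rng.random(n) < config.penetrance)
    flip = rng.random(n) < config.misclass_rate
    fruits = fruits ^ flip
    return np.where(fruits, FRUITING, NON_FRUITING)


def build_pools(
    phenotypes: np.ndarray, pool_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample pool_size strain indices per phenotype class, without replacement."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    idx_F = np.flatnonzero(phenotypes == FRUITING)
    idx_N = np.flatnonzero(phenotypes == NON_FRUITING)
    for name, idx in ((FRUITING, idx_F), (NON_FRUITING, idx_N)):
        if len(idx) < pool_size:
            raise ValueError(
                f"cannot bulk {pool_size} strains: only {len(idx)} {name} strains"
            )
    return (
        np.sort(rng.choice(idx_F, size=pool_size, replace=False)),
        np.sort(rng.choice(idx_N, size=pool_size, replace=False)),
    )


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------


def simulate_pool_reads(
    bulk_alleles: Sequence[int], config: SimConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """(ref, alt) read counts at one marker for one bulk.

    The true pool ALT frequency is the carrier fraction; depth is
    Poisson(mean_depth) and each read flips allele with probability
    ``seq_error``.
    """
    alleles = np.asarray(bulk_alleles)
    if alleles.size == 0:
        raise ValueError("empty bulk")
    p = float(alleles.mean())
    e = config.seq_error
    depth = int(rng.poisson(config.mean_depth))
    alt = int(rng.binomial(depth, p * (1 - e) + (1 - p) * e)) if depth else 0
    return depth - alt, alt


def simulate_pool_depths(
    origins: np.ndarray,
    pool_idx: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """(markers x 2) array of (ref, alt) read counts for one bulk, all markers."""
    p = origins[pool_idx].mean(axis=0)
    e = config.seq_error
    depth = rng.poisson(config.mean_depth, size=p.size)
    alt = rng.binomial(depth, p * (1 - e) + (1 - p) * e)
    return np.stack([depth - alt, alt], axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# whole simulation and file emission
# ---------------------------------------------------------------------------

PARENT_F, PARENT_N = "parent_F", "parent_N"
POOL_F, POOL_N = "pool_F", "pool_N"


@dataclass
class Simulation:
    """A complete synthetic cross: genome, population, bulks and pool depths."""

    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    domains: dict[str, list[tuple[int, int]]]
    markers: pd.DataFrame
    hap_F: np.ndarray
    hap_N: np.ndarray
    origins: np.ndarray  # progeny x markers, 1 = fruiting-parent origin
    strain_ids: list[str]
    phenotypes: np.ndarray
    pool_F_idx: np.ndarray
    pool_N_idx: np.ndarray
    pool_F_ad: np.ndarray  # markers x (ref, alt)
    pool_N_ad: np.ndarray
    causal_index: int

    @property
    def causal_gene(self) -> GeneModel:
        gid = next(iter(self.domains))
        return next(g for g in self.genes if g.gene_id == gid)


def run_simulation(config: SimConfig | None = None, seed: int | None = None) -> Simulation:
    """Generate a full synthetic dataset; ``seed`` overrides ``config.seed``."""
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    genome, genes, domains = generate_genome(config, rng)
    markers, hap_F, hap_N = generate_parents(config, rng, genome)
    origins = simulate_progeny(markers, config, rng)
    phenotypes = assign_phenotypes(origins, markers, config, rng)
    pool_F_idx, pool_N_idx = build_pools(phenotypes, config.pool_size, rng)
    pool_F_ad = simulate_pool_depths(origins, pool_F_idx, config, rng)
    pool_N_ad = simulate_pool_depths(origins, pool_N_idx, config, rng)
    width = len(str(config.n_progeny))
    return Simulation(
        config=config,
        genome=genome,
        genes=genes,
        domains=domains,
        markers=markers,
        hap_F=hap_F,
        hap_N=hap_N,
        origins=origins,
        strain_ids=[f"strain_{i + 1:0{width}d}" for i in range(config.n_progeny)],
        phenotypes=phenotypes,
        pool_F_idx=pool_F_idx,
        pool_N_idx=pool_N_idx,
        pool_F_ad=pool_F_ad,
        pool_N_ad=pool_N_ad,
        causal_index=causal_marker_index(markers, config),
    )


def to_variant_records(sim: Simulation):
    """The simulation's sites as VCF-convention variant records (unoriented).

    Equivalent to emitting the VCF and reading it back: parent genotypes are
    hom-alt (fruiting) / hom-ref (non-fruiting), pool AD pairs in (ref, alt)
    order.
    """
    from .variant_io import HOM_ALT, HOM_REF, VariantRecord

    adF, adN = sim.pool_F_ad, sim.pool_N_ad
    return [
        VariantRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            parent_F_gt=HOM_ALT,
            parent_N_gt=HOM_REF,
            pool_F_ad=(int(adF[i, 0]), int(adF[i, 1])),
            pool_N_ad=(int(adN[i, 0]), int(adN[i, 1])),
            is_snp=True,
        )
        for i, row in enumerate(sim.markers.itertuples(index=False))
    ]


def _vcf_text(sim: Simulation) -> str:
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=bsamap-simulate\n")
    for name, length in zip(sim.config.scaffold_names, sim.config.scaffold_lengths):
        buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths (ref,alt)">\n'
    )
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{PARENT_F}\t{PARENT_N}\t{POOL_F}\t{POOL_N}\n"
    )
    adF, adN = sim.pool_F_ad, sim.pool_N_ad
    for i, row in enumerate(sim.markers.itertuples(index=False)):
        rF, aF = int(adF[i, 0]), int(adF[i, 1])
        rN, aN = int(adN[i, 0]), int(adN[i, 1])
        buf.write(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
            f"GT:AD:DP\t1|1:.:.\t0|0:.:.\t"
            f"./.:{rF},{aF}:{rF + aF}\t./.:{rN},{aN}:{rN + aN}\n"
        )
    return buf.getvalue()


def _gff_text(sim: Simulation) -> str:
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for name, length in zip(sim.config.scaffold_names, sim.config.scaffold_lengths):
        buf.write(f"##sequence-region {name} 1 {length}\n")
    src = "bsamap_sim"
    for g in sorted(sim.genes, key=lambda g: (g.chrom, g.start)):
        buf.write(
            f"{g.chrom}\t{src}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};Name={g.name}\n"
        )
        mrna = f"{g.gene_id}.t1"
        buf.write(
            f"{g.chrom}\t{src}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}\n"
        )
        for j, (s, e) in enumerate(g.exons, 1):
            buf.write(
                f"{g.chrom}\t{src}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna}.exon{j};Parent={mrna}\n"
            )
        for j, (s, e, phase) in enumerate(g.cds, 1):
            buf.write(
                f"{g.chrom}\t{src}\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                f"ID={mrna}.cds{j};Parent={mrna}\n"
            )
    return buf.getvalue()


def emit_dataset(sim: Simulation, outdir: str | Path) -> dict[str, Path]:
    """Write VCF/GFF3/FASTA/TSV files; returns the path of each artifact.

    Output is byte-deterministic given the simulation (no timestamps); the
    VCF round-trips exactly through :func:`bsamap.variant_io.read_variants`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "variants.vcf",
        "gff": outdir / "annotation.gff3",
        "fasta": outdir / "genome.fa",
        "phenotypes": outdir / "phenotypes.tsv",
        "domains": outdir / "domains.tsv",
    }

    def _write(path: Path, text: str) -> None:
        try:
            path.write_text(text)
        except OSError as exc:  # pragma: no cover
            raise OSError(f"cannot write {path}: {exc}") from exc

    _write(paths["vcf"], _vcf_text(sim))
    _write(paths["gff"], _gff_text(sim))
    records = [
        SeqRecord(Seq(sim.genome[name]), id=name, description="")
        for name in sim.config.scaffold_names
    ]
    with open(paths["fasta"], "w") as fh:
        SeqIO.write(records, fh, "fasta")
    pheno = "strain_id\tphenotype\n" + "".join(
        f"{sid}\t{ph}\n" for sid, ph in zip(sim.strain_ids, sim.phenotypes)
    )
    _write(paths["phenotypes"], pheno)
    dom = "gene_id\taa_start\taa_end\n" + "".join(
        f"{gid}\t{lo}\t{hi}\n"
        for gid, ranges in sim.domains.items()
        for lo, hi in ranges
    )
    _write(paths["domains"], dom)
    return paths
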