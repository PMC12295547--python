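# Methods

## The mapping model

`bsamap` maps a fully penetrant binary trait segregating 1:1 in a haploid
(monokaryotic) F1 population derived from two homozygous parents. The central
object is the four-sample VCF: two parents typed by genotype, two phenotype
bulks typed by allele depth (AD). Sites are reduced to informative markers —
biallelic SNPs at which the parents are homozygous for opposite alleles and
both pools fall inside a depth window — and polarized so that "allele A" is
the fruiting parent's allele at every site. Polarization fixes the sign of
Δ(SNP-index): at the causal locus the fruiting bulk is fixed for A and the
non-fruiting bulk for the alternative, so Δ → +1, while an unlinked marker has
E[Δ] = 0.

Five statistics are computed per site from the 2×2 pool × allele read-count
table: SNP-index per pool, Δ(SNP-index), Euclidean distance between the pools'
allele-frequency vectors (ED = √2·|Δ| for biallelic sites), the
likelihood-ratio G statistic, and the exact two-tailed Fisher p. The Fisher
test uses the point-probability rule (sum of all hypergeometric outcomes at
fixed margins whose probability does not exceed the observed one), computed
from log-factorial tables with a 1e-9 relative guard so exact ties are always
included; the unit tests verify exact agreement with integer-arithmetic
enumeration on every 2×2 table with margins ≤ 20. G follows the standard
convention: empty cells contribute zero, no continuity correction; the scalar
entry point rejects degenerate tables (a zero row or column sum) while the
vectorized pipeline path scores them 0, since a table with an empty margin
carries no evidence of association.

## The haploid null and significance thresholds

Because every strain in a bulk contributes one chromosome set, the unlinked
null for a bulk of n strains is: carrier count ~ Binomial(n, ½), true pool
frequency p = count/n (granularity 1/n), depth ~ Poisson(mean depth), A reads
~ Binomial(depth, p). This is deliberately *not* the diploid QTL-seq null —
with n = 24 the haploid null is substantially wider, and using a diploid null
here would overcall significance. Cutoffs per statistic are the empirical 99th
percentile over ≥100,000 simulated null sites (|Δ|, ED⁴, G, −log₁₀ p); a site
exactly at a cutoff counts as significant. Calibration is checked by applying
thresholds to a fresh null draw: each statistic flags 1% ± binomial/quantile
noise. Zero-depth null draws (vanishingly rare at realistic depths) are
floored at one read; p-values are floored at 1e-300 before taking logs.

## Smoothing, regions, consensus

All four tracks are smoothed per scaffold with a tricube kernel,
w = (1 − (d/h)³)³ within ±h, default h = 1 Mb (a "uniform" kernel is
available). One coherent smoothing convention is used for all four methods
rather than four method-specific ones; every choice is a config knob. A site
always carries its own full weight, so isolated sites keep their raw values,
and smoothing never crosses scaffold boundaries. Thresholds are estimated on
*unsmoothed* null sites, which makes them conservative when applied to
smoothed tracks — acceptable here because the target is a single
fully-penetrant locus whose signal dwarfs the threshold.

Significant regions are maximal runs of above-threshold markers, merging runs
separated by at most `max_gap` bp (default: the smoothing bandwidth, so a
marker desert narrower than the kernel cannot split a QTL). Region bounds are
the outermost significant marker positions — marker-supported and
reproducible, with no threshold-crossing interpolation. The consensus QTL is
the exact genomic intersection of the four methods' region footprints
(sweep-line over per-method merged intervals; verified against a per-base-pair
oracle in tests). A lower consensus level (≥k of 4) is configurable.
Externally all coordinates are 1-based closed (VCF/GFF convention); BED
exports convert to 0-based half-open in a single tested helper.

## Candidate annotation and ranking

Genes overlapping a consensus interval by ≥1 bp are read from GFF3
(gene/mRNA/exon/CDS with phase; minus-strand genes fully supported). Variants
are assigned to CDS/exon/intron/intergenic; CDS SNPs are classified by
splicing the CDS in transcript order, mutating the codon and translating both
versions (CDS position 121 = codon 41, position 1). The candidate filter keeps
protein-changing variants (missense/nonsense/start-loss) whose pools are
concordant with the parents (A-index > ½ in the fruiting pool, < ½ in the
non-fruiting pool), and ranks by conserved-domain membership (when supplied),
then |Δ(SNP-index)|, then Fisher evidence.

Conserved-domain evidence is an *input annotation* (a gene → codon-range
table), not a computation: in practice it comes from an external database
lookup. It matters because association cannot distinguish perfectly linked
coding variants — two SNPs a few kb apart in one bulk pair of 24 strains are
almost always inherited together, so their Δ values are identical up to
sequencing noise. Domain membership is the principled tie-break, and it is
exactly how such candidates are triaged in practice.

`genotype_concordance` supports the per-strain validation step: given a
per-strain genotype call at one site and the phenotype table, it reports the
fraction of strains carrying the phenotype-expected parental allele plus the
2×2 table.

## The synthetic cross generator

The generator emulates the study design end to end; its defaults are the
study conditions:

| parameter | default | meaning |
|---|---|---|
| genome | 10 scaffolds × 3.5 Mb | stand-in geometry at a realistic agaric genome scale (~35 Mb); the real assembly is not modelled |
| n_markers | 7021 | informative SNPs placed uniformly at random, one forced at the causal position |
| n_progeny | 156 | haploid F1 strains |
| pool_size | 24 | strains per phenotype bulk |
| mean_depth | 68.8× | Poisson per site per pool (shotgun coverage variance) |
| seq_error | 0.001 | per-read allele flip, post-filter Illumina scale |
| recomb_rate | 0.3 crossovers/Mb | ≈30 cM/Mb, total map ~1050 cM, in line with published basidiomycete linkage maps |
| penetrance | 1.0 | P(carrier fruits); the misclass_rate knob (default 0) additionally flips recorded labels, for stress-testing phenotype scoring |

Meioses follow a no-interference (Haldane) model: per scaffold, crossover
count ~ Poisson(rate × length), uniform breakpoints, fair starting parent.
Interference is irrelevant to single-locus mapping power at this scale. The
causal locus is implanted as a real coding change: a 7-exon gene (2193 bp
span, 1710 bp CDS → 569-aa protein) is written into the genome so that the
causal SNP is a T→G missense at CDS position 121 (codon 41 TCT→GCT, Ser→Ala),
with a conserved-domain annotation covering codons 30–80 and four flanking
multi-exon genes tiling ~10 kb around it. Emitted files (VCF 4.2 with GT for
parents and AD/DP for pools, GFF3, 60-column FASTA, phenotype and domain TSVs)
are plain text, byte-reproducible from the seed, and round-trip exactly
through the package's readers.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: alignment and variant-calling artifacts (mapping bias,
paralogy, indel shadows), depth autocorrelation along the genome, marker
ascertainment bias, segregation distortion, polygenic or environment-dependent
penetrance, and real gene architecture beyond the implanted models. The
pipeline starts from a VCF by design; upstream read processing is out of
scope.

## Numerical and design choices

- Polarized pool AD pairs are stored (non-A, A) so the SNP-index is always the
  second-slot fraction; polarization swaps pairs only where the fruiting
  parent is homozygous reference, preserves total depth, and is idempotent.
- Sites with a zero-depth pool are dropped (SNP-index undefined) and tallied;
  every filter rejection is tallied under the first rule it fails, and
  kept + Σ tally = input always.
- Filter defaults: biallelic SNPs only (indels excluded from association;
  admit them by disabling `require_snp`), opposite-homozygous parents, pool
  depth in [10, 206] (~3× the expected 68.8×). There is no published numeric
  "high-quality" definition to match, so all thresholds are exposed.
- Phased (`0|0`) and unphased (`0/0`) genotypes are treated identically —
  phase is meaningless for homozygous haploid-derived calls.
- ED is raised to the 4th power before smoothing (the usual peak-sharpening
  convention in the ED lineage); the power is configurable.
- Fisher significance is thresholded on −log₁₀(p) against the simulated null
  quantile rather than a Bonferroni bound, keeping all four methods on the
  same simulation-calibrated footing.
- Determinism: one seed drives genome, meiosis, phenotypes, pools, read
  sampling and the null simulation; identical config + seed yields
  byte-identical files and reports.

## Problem sizes used in the shipped checks

The test suite exercises most behaviour on a scaled-down cross (two 300 kb
scaffolds, 240 markers, 60 progeny, bulks of 12 at 40×) that preserves the
full design's architecture, and runs the full-scale design (156 progeny,
bulks of 24, 7021 markers, 68.8×) for the calibration and recovery checks:
type-I control uses 100,000 training + 100,000 evaluation null sites, and
parameter recovery uses 50 independent full-scale simulations, in which the
four-method consensus must contain the causal locus and rank the causal
missense variant first in ≥95% of runs. `scripts/acceptance.py` re-runs these
same computations from scratch.

## Known limitations

- The consensus interval width is governed by recombination around the locus
  and the smoothing bandwidth; with the default 1 Mb kernel the interval is
  intentionally conservative (hundreds of kb to Mb at the simulated scale).
  Narrower localization requires reducing the bandwidth once a single clean
  peak is established.
- The null simulation conditions on the nominal pool size and mean depth; it
  does not model overdispersed coverage or unequal bulk sizes.
- `classify_effect` handles single-nucleotide substitutions within annotated
  CDS; indel consequences and splice-site disruption are not modelled.
- With penetrance < 1 or phenotype misclassification, bulk purity drops and
  power falls; the generator exposes both knobs but the default acceptance
  checks run the clean design.
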