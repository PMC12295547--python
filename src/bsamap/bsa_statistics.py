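"""Per-site pooled association statistics, kernel smoothing, null thresholds.

Five statistics are computed at every polarized site from the two pools' read
counts of the fruiting-parent allele (A) versus the other allele:

* SNP-index per pool: fraction of reads carrying A;
* delta(SNP-index): fruiting-pool index minus non-fruiting-pool index, in
  [-1, 1], near +1 at a fully penetrant causal locus;
* Euclidean distance ED = sqrt(sum_alleles (f_F - f_N)^2) = sqrt(2)*|delta| for
  a biallelic site, raised to a configurable power (default 4) to sharpen
  peaks before smoothing;
* G statistic: likelihood-ratio statistic of the 2x2 pool-by-allele read-count
  table, G = 2 * sum n*ln(n/e) over non-empty cells;
* two-tailed Fisher exact p of the same table (sum of hypergeometric outcomes
  no more probable than the observed one at fixed margins).

Tracks are smoothed along each scaffold with a tricube kernel, and 99%
significance cutoffs are drawn from a null simulation matched to the haploid
cross: each pool's carrier count is Binomial(pool_size, 1/2) — a monokaryotic
bulk samples one chromosome set per strain, so allele-frequency granularity is
1/pool_size, coarser than the diploid QTL-seq null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .variant_io import VariantRecord

# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------


def snp_index(ad: Sequence[int]) -> float:
    """Fraction of reads carrying the designated allele, from an AD pair.

    The pair is (other count, designated count); on polarized records the
    designated allele is A, the fruiting parent's allele.
    """
    other, des = int(ad[0]), int(ad[1])
    total = other + des
    if total < 1:
        raise ValueError("SNP-index undefined at zero depth")
    return des / total


def delta_snp_index(index_F: float, index_N: float) -> float:
    """Difference of pool SNP-indices (fruiting minus non-fruiting)."""
    return index_F - index_N


def euclidean_distance(
    freq_F: Sequence[float], freq_N: Sequence[float]
) -> float:
    """Euclidean distance between the pools' allele-frequency vectors.

    Each vector must sum to 1. For a biallelic site this equals
    sqrt(2)*|freq difference|, with maximum sqrt(2) at fixation for opposite
    alleles.
    """
    f = np.asarray(freq_F, dtype=float)
    g = np.asarray(freq_N, dtype=float)
    if f.shape != g.shape:
        raise ValueError("frequency vectors differ in length")
    for v in (f, g):
        if not math.isclose(float(v.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("allele frequencies must sum to 1")
    return float(np.sqrt(np.sum((f - g) ** 2)))


def g_statistic(table: Sequence[Sequence[float]]) -> float:
    """Log-likelihood-ratio G of a 2x2 pool-by-allele count table.

    ``G = 2 * sum n*ln(n/e)`` with ``e = row_total*col_total/grand_total``;
    empty cells contribute zero and no continuity correction is applied. A
    zero row or column sum makes the table degenerate and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValueError("degenerate table: zero row or column sum")
    total = t.sum()
    expected = np.outer(rows, cols) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / expected), 0.0)
    return float(max(2.0 * terms.sum(), 0.0))


def _g_statistic_array(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Vectorized G over tables [[a, b], [c, d]]; degenerate tables yield 0."""
    t = np.stack([a, b, c, d], axis=-1).astype(float)
    total = t.sum(axis=-1)
    r1 = a + b
    r2 = c + d
    c1 = a + c
    c2 = b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.stack([r1 * c1, r1 * c2, r2 * c1, r2 * c2], axis=-1) / total[..., None]
        terms = np.where(t > 0, t * np.log(t / e), 0.0)
    g = 2.0 * terms.sum(axis=-1)
    return np.where(np.isfinite(g), np.maximum(g, 0.0), 0.0)


# ---------------------------------------------------------------------------
# Fisher exact test (two-tailed, point-probability rule)
# ---------------------------------------------------------------------------

_LOG_FACT = gammaln(np.arange(2, dtype=float) + 1.0)


def _log_fact(n_max: int) -> np.ndarray:
    global _LOG_FACT
    if n_max >= _LOG_FACT.size:
        _LOG_FACT = gammaln(np.arange(n_max + 1, dtype=float) + 1.0)
    return _LOG_FACT


def fisher_two_tailed_batch(
    k1: np.ndarray, n1: np.ndarray, k2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Two-tailed Fisher exact p for tables [[k1, n1-k1], [k2, n2-k2]].

    Sums every hypergeometric outcome (at fixed margins) whose point
    probability does not exceed the observed one, with a 1e-9 relative guard
    so exact probability ties are always included. Fully vectorized; rows with
    an all-zero table raise.
    """
    k1 = np.asarray(k1, dtype=np.int64)
    n1 = np.asarray(n1, dtype=np.int64)
    k2 = np.asarray(k2, dtype=np.int64)
    n2 = np.asarray(n2, dtype=np.int64)
    if np.any((k1 < 0) | (k2 < 0) | (k1 > n1) | (k2 > n2)):
        raise ValueError("counts must satisfy 0 <= k <= n per pool")
    N = n1 + n2
    if np.any(N == 0):
        raise ValueError("all-zero table")
    K = k1 + k2
    lf = _log_fact(int(N.max()))

    lo = np.maximum(0, K - n2)
    hi = np.minimum(n1, K)
    width = int((hi - lo).max()) + 1

    # bound the support matrix to ~32 MB per chunk
    chunk = max(1, 4_000_000 // width)
    if k1.size > chunk:
        return np.concatenate(
            [
                fisher_two_tailed_batch(
                    k1[i : i + chunk], n1[i : i + chunk],
                    k2[i : i + chunk], n2[i : i + chunk],
                )
                for i in range(0, k1.size, chunk)
            ]
        )
    ks = lo[:, None] + np.arange(width)[None, :]
    valid = ks <= hi[:, None]
    ksv = np.where(valid, ks, lo[:, None])  # safe index

    def logpmf(k):
        return (
            lf[n1[:, None]]
            - lf[k]
            - lf[n1[:, None] - k]
            + lf[n2[:, None]]
            - lf[K[:, None] - k]
            - lf[n2[:, None] - K[:, None] + k]
            - (lf[N[:, None]] - lf[K[:, None]] - lf[N[:, None] - K[:, None]])
        )

    lp = logpmf(ksv)
    lp_obs = logpmf(k1[:, None])
    include = valid & (lp <= lp_obs + 1e-9)
    p = np.where(include, np.exp(lp), 0.0).sum(axis=1)
    return np.minimum(p, 1.0)


def fisher_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Exact two-tailed Fisher p of one 2x2 count table."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative integer 2x2 table")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    (a, b), (c, d) = t
    return float(
        fisher_two_tailed_batch(
            np.array([a]), np.array([a + b]), np.array([c]), np.array([c + d])
        )[0]
    )


# ---------------------------------------------------------------------------
# site-stats table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteStats:
    """The five association statistics at one polarized site."""

    chrom: str
    pos: int
    snp_index_F: float
    snp_index_N: float
    delta_snp_index: float
    ed: float
    ed_pow: float
    g: float
    fisher_p: float


def compute_site_stats(
    records: Sequence[VariantRecord], ed_power: float = 4.0
) -> pd.DataFrame:
    """Per-site statistics table for polarized records, in input order.

    Columns: chrom, pos, ref, alt, a_F/b_F/a_N/b_N (A and non-A read counts),
    snp_index_F/N, delta_snp_index, ed, ed_pow, g, fisher_p,
    neg_log10_fisher_p. Requires every record oriented with both pools
    covered (the depth filter guarantees this upstream).
    """
    if any(not r.oriented for r in records):
        raise ValueError("records must be polarized before computing statistics")
    if not records:
        return pd.DataFrame(
            columns=[
                "chrom", "pos", "ref", "alt", "a_F", "b_F", "a_N", "b_N",
                "snp_index_F", "snp_index_N", "delta_snp_index",
                "ed", "ed_pow", "g", "fisher_p", "neg_log10_fisher_p",
            ]
        )
    aF = np.array([r.pool_F_ad[1] for r in records], dtype=np.int64)
    bF = np.array([r.pool_F_ad[0] for r in records], dtype=np.int64)
    aN = np.array([r.pool_N_ad[1] for r in records], dtype=np.int64)
    bN = np.array([r.pool_N_ad[0] for r in records], dtype=np.int64)
    dF = aF + bF
    dN = aN + bN
    if np.any(dF == 0) or np.any(dN == 0):
        raise ValueError("zero-depth pool at a retained site")
    idxF = aF / dF
    idxN = aN / dN
    delta = idxF - idxN
    ed = np.sqrt(2.0) * np.abs(delta)
    g = _g_statistic_array(aF, bF, aN, bN)
    p = fisher_two_tailed_batch(aF, dF, aN, dN)
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "a_F": aF,
            "b_F": bF,
            "a_N": aN,
            "b_N": bN,
            "snp_index_F": idxF,
            "snp_index_N": idxN,
            "delta_snp_index": delta,
            "ed": ed,
            "ed_pow": ed**ed_power,
            "g": g,
            "fisher_p": p,
            "neg_log10_fisher_p": -np.log10(np.maximum(p, 1e-300)),
        }
    )


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothedTrack:
    """A per-site smoothed statistic track, sorted by (chrom, pos)."""

    chroms: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    bandwidth: float
    kernel: str
    statistic: str = ""


def smooth_track(
    chroms: Sequence[str],
    positions: Sequence[int],
    values: Sequence[float],
    bandwidth: float,
    kernel: str = "tricube",
    statistic: str = "",
) -> SmoothedTrack:
    """Kernel-smooth a statistic along the genome, never mixing scaffolds.

    The smoothed value at site i is ``sum(w_j * v_j) / sum(w_j)`` over sites j
    on the same scaffold within +-bandwidth bp, with tricube weights
    ``w = (1 - (d/bandwidth)^3)^3`` (or constant weights for
    ``kernel="uniform"``). A site always includes itself with full weight, so
    an isolated site keeps its raw value. Input must be sorted by scaffold
    block and position.
    """
    chroms = np.asarray(chroms, dtype=object)
    pos = np.asarray(positions, dtype=np.int64)
    vals = np.asarray(values, dtype=float)
    if not (chroms.shape == pos.shape == vals.shape):
        raise ValueError("chroms, positions and values must align")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if kernel not in ("tricube", "uniform"):
        raise ValueError(f"unknown kernel {kernel!r}")

    out = np.empty_like(vals)
    seen: set[str] = set()
    i = 0
    n = len(pos)
    while i < n:
        chrom = chroms[i]
        if chrom in seen:
            raise ValueError(f"unsorted track: scaffold {chrom} appears twice")
        seen.add(chrom)
        j = i
        while j < n and chroms[j] == chrom:
            j += 1
        p = pos[i:j]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"unsorted track positions on {chrom}")
        v = vals[i:j]
        lo = np.searchsorted(p, p - bandwidth, side="left")
        hi = np.searchsorted(p, p + bandwidth, side="right")
        sm = np.empty_like(v)
        for k in range(len(p)):
            d = np.abs(p[lo[k] : hi[k]] - p[k]) / bandwidth
            if kernel == "tricube":
                w = (1.0 - d**3) ** 3
            else:
                w = np.ones_like(d)
            sm[k] = np.dot(w, v[lo[k] : hi[k]]) / w.sum()
        out[i:j] = sm
        i = j
    return SmoothedTrack(
        chroms=chroms,
        positions=pos,
        values=out,
        bandwidth=float(bandwidth),
        kernel=kernel,
        statistic=statistic,
    )


# ---------------------------------------------------------------------------
# null-model significance thresholds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NullThresholds:
    """Upper-quantile cutoffs per statistic from an unlinked-site simulation.

    ``fisher`` is on the -log10(p) scale; ``delta_snp_index`` on |delta|;
    ``ed`` on ED^ed_power. A site exactly at a cutoff counts as significant.
    """

    delta_snp_index: float
    ed: float
    g: float
    fisher: float
    n_null_sites: int
    pool_size: int
    mean_depth: float
    quantile: float
    ed_power: float

    def as_dict(self) -> dict[str, float]:
        return {
            "delta_snp_index": self.delta_snp_index,
            "ed": self.ed,
            "g": self.g,
            "fisher": self.fisher,
        }


def simulate_null_sites(
    pool_size: int,
    mean_depth: float,
    n_sites: int,
    rng: np.random.Generator,
    ed_power: float = 4.0,
) -> pd.DataFrame:
    """Simulate unlinked null sites for the haploid cross and score them.

    Per pool independently: carrier count ~ Binomial(pool_size, 1/2), true
    pool frequency p = count/pool_size, depth ~ Poisson(mean_depth) (floored
    at 1 read), A reads ~ Binomial(depth, p). Returns abs_delta, ed_pow, g and
    neg_log10_fisher_p per site.
    """
    if pool_size < 1 or mean_depth <= 0 or n_sites < 1:
        raise ValueError("pool_size, mean_depth and n_sites must be positive")
    pF = rng.binomial(pool_size, 0.5, size=n_sites) / pool_size
    pN = rng.binomial(pool_size, 0.5, size=n_sites) / pool_size
    dF = np.maximum(rng.poisson(mean_depth, size=n_sites), 1)
    dN = np.maximum(rng.poisson(mean_depth, size=n_sites), 1)
    aF = rng.binomial(dF, pF)
    aN = rng.binomial(dN, pN)
    delta = aF / dF - aN / dN
    ed = np.sqrt(2.0) * np.abs(delta)
    g = _g_statistic_array(aF, dF - aF, aN, dN - aN)
    p = fisher_two_tailed_batch(aF, dF, aN, dN)
    return pd.DataFrame(
        {
            "abs_delta": np.abs(delta),
            "ed_pow": ed**ed_power,
            "g": g,
            "neg_log10_fisher_p": -np.log10(np.maximum(p, 1e-300)),
        }
    )


def null_thresholds(
    pool_size: int,
    mean_depth: float,
    n_null_sites: int = 100_000,
    quantile: float = 0.99,
    ed_power: float = 4.0,
    rng: np.random.Generator | int | None = None,
) -> NullThresholds:
    """Significance cutoffs at the given upper quantile of the simulated null.

    The null matches the study design (haploid bulks, Poisson depth) but not
    linkage to any locus, so at the 0.99 quantile ~1% of genuinely unlinked
    sites exceed each cutoff. At least 10,000 sites are recommended for a
    stable 99th percentile.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    null = simulate_null_sites(pool_size, mean_depth, n_null_sites, rng, ed_power)
    q = lambda col: float(np.quantile(null[col].to_numpy(), quantile))  # noqa: E731
    return NullThresholds(
        delta_snp_index=q("abs_delta"),
        ed=q("ed_pow"),
        g=q("g"),
        fisher=q("neg_log10_fisher_p"),
        n_null_sites=n_null_sites,
        pool_size=pool_size,
        mean_depth=float(mean_depth),
        quantile=quantile,
        ed_power=ed_power,
    )
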