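"""Segregation-ratio statistics for a haploid mapping population.

A cross between two homozygous monokaryotic parents that differ at a single
fully penetrant locus segregates 1:1 for the trait among basidiospore-derived
progeny. These helpers test observed phenotype counts against any small-integer
expected ratio (1:1, 3:1, ...) with a goodness-of-fit chi-square, and tabulate
phenotype classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SegregationTest:
    """Result of a chi-square goodness-of-fit test against an expected ratio."""

    observed: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    expected: tuple[float, ...]
    chi_square: float
    df: int
    p_value: float


def segregation_chi_square(
    observed: Sequence[int],
    ratio: Sequence[int] = (1, 1),
    continuity_correction: bool = False,
) -> SegregationTest:
    """Chi-square goodness-of-fit of observed class counts to a small-integer ratio.

    Parameters
    ----------
    observed
        Counts per phenotype class (>= 2 classes, total > 0).
    ratio
        Expected segregation ratio, one integer per class (e.g. ``(1, 1)`` or
        ``(3, 1)``).
    continuity_correction
        Apply the Yates correction ``(|O-E| - 0.5)^2 / E``. Off by default: the
        uncorrected statistic is the conventional one for segregation tests.

    Returns
    -------
    SegregationTest
        With ``chi_square``, ``df = classes - 1`` and the upper-tail p-value.
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need at least two phenotype classes")
    if rat.shape != obs.shape:
        raise ValueError(
            f"ratio has {rat.size} classes but observed has {obs.size}"
        )
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("observed counts must be non-negative with positive total")
    if np.any(rat <= 0):
        raise ValueError("expected ratio entries must be positive")

    expected = obs.sum() * rat / rat.sum()
    if continuity_correction:
        dev = np.abs(obs - expected) - 0.5
        dev = np.maximum(dev, 0.0)
        chi2 = float(np.sum(dev**2 / expected))
    else:
        chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationTest(
        observed=tuple(int(x) for x in obs),
        expected_ratio=tuple(int(x) for x in rat),
        expected=tuple(float(x) for x in expected),
        chi_square=chi2,
        df=df,
        p_value=p,
    )


def trait_tally(
    phenotypes: Sequence[str] | pd.Series | Mapping[str, int],
    vocabulary: Sequence[str] = ("fruiting", "non_fruiting"),
) -> pd.DataFrame:
    """Count phenotype classes and report percentages to one decimal.

    ``phenotypes`` is either an iterable of per-strain labels or a mapping of
    label -> count. Labels outside ``vocabulary`` raise with the offenders
    listed.
    """
    if isinstance(phenotypes, Mapping):
        counts = {str(k): int(v) for k, v in phenotypes.items()}
    else:
        ser = pd.Series(list(phenotypes), dtype=object)
        if ser.empty:
            raise ValueError("empty phenotype table")
        counts = ser.value_counts().to_dict()

    unknown = sorted(set(counts) - set(vocabulary))
    if unknown:
        raise ValueError(f"unknown phenotype labels: {unknown}")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty phenotype table")

    rows = []
    for label in vocabulary:
        n = counts.get(label, 0)
        rows.append(
            {"phenotype": label, "count": n, "percent": round(100.0 * n / total, 1)}
        )
    return pd.DataFrame(rows)
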