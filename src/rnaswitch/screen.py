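"""Scoring of sort-seq reporter screens and the mutagenesis switch score.

Variants sorted into 8 expression bins (two replicates) are normalized
by median-of-ratios across samples.  A variant's functional effect is a
one-way chi-squared test of its bin distribution against uniformity.
A candidate switch, represented by its four conformation-locking
variants, is scored by how concordantly the same-conformation mutant
pairs behave versus the opposite-conformation pairs:

    score = mean(corr(A,B), corr(C,D)) - mean(corr(A,C), corr(A,D))

on the 16-element vectors of normalized bin counts (8 bins x 2
replicates).  Scores above mean + 1 sample s.d. are called significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import ContractViolation

N_BINS = 8


@dataclass
class ScreenCounts:
    """Long-format read counts: variant x bin (1-8) x replicate."""

    table: pd.DataFrame  # columns: variant, bin, replicate, count
    material: str = "RNA"

    def __post_init__(self) -> None:
        req = {"variant", "bin", "replicate", "count"}
        missing = req - set(self.table.columns)
        if missing:
            raise ContractViolation(f"counts table missing columns {sorted(missing)}")
        bins = set(self.table["bin"].unique())
        if not bins <= set(range(1, N_BINS + 1)):
            raise ContractViolation(
                f"bin labels must be 1..{N_BINS}, got {sorted(bins)}"
            )
        counts = self.table["count"]
        if (counts < 0).any() or not np.allclose(counts, counts.round()):
            raise ContractViolation("counts must be nonnegative integers")

    def matrix(self) -> pd.DataFrame:
        """variants x samples matrix; sample = (bin, replicate)."""
        m = self.table.pivot_table(
            index="variant",
            columns=["bin", "replicate"],
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        return m.sort_index(axis=1)


@dataclass
class NormalizedCounts:
    size_factors: pd.Series  # per (bin, replicate) sample
    normalized: pd.DataFrame  # variants x samples

    def variant_vector(self, variant) -> np.ndarray:
        """16-vector of normalized counts: bins 1-8 of rep 1, then rep 2."""
        row = self.normalized.loc[variant]
        reps = sorted({rep for _, rep in self.normalized.columns})
        return np.concatenate(
            [
                [row.get((b, rep), 0.0) for b in range(1, N_BINS + 1)]
                for rep in reps
            ]
        )

    def bin_distribution(self, variant, replicate) -> np.ndarray:
        """The variant's 8-bin distribution for one replicate, summing to 1."""
        row = self.normalized.loc[variant]
        v = np.array([row.get((b, replicate), 0.0) for b in range(1, N_BINS + 1)])
        total = v.sum()
        if total <= 0:
            raise ContractViolation(
                f"variant {variant!r} has zero total in replicate {replicate}"
            )
        return v / total


@dataclass
class VariantScore:
    variant: object
    correlations: tuple  # (same_1, same_2, opposite_1, opposite_2); None = undefined
    score: float  # NaN when any correlation is undefined
    significant: bool = False


def normalize_median_of_ratios(counts: ScreenCounts) -> NormalizedCounts:
    """Median-of-ratios (DESeq-style) size factors across all samples.

    The reference per variant is the geometric mean of its counts over
    samples; variants with a zero in any sample are excluded from the
    reference set.  Each sample's size factor is the median of its
    count/reference ratios; normalized counts are count/size_factor.
    """
    m = counts.matrix()
    if m.shape[1] < 2:
        raise ContractViolation("need >= 2 samples to normalize")
    arr = m.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ContractViolation(
            "un-normalizable input: no variant has nonzero counts in every sample"
        )
    ref = np.exp(np.log(arr[all_nonzero]).mean(axis=1))
    ratios = arr[all_nonzero] / ref[:, None]
    sf = np.median(ratios, axis=0)
    size_factors = pd.Series(sf, index=m.columns)
    normalized = m / sf
    return NormalizedCounts(size_factors=size_factors, normalized=normalized)


def functional_effect_test(nc: NormalizedCounts, variant) -> tuple:
    """Chi-squared test of the variant's bin distribution vs uniform.

    Replicates are summed, normalized counts rounded back to integers;
    df = 7.  Returns (chi2, p, direction) where direction is the sign of
    the read-weighted mean bin relative to the uniform midpoint.
    """
    row = nc.normalized.loc[variant]
    bins = np.zeros(N_BINS)
    for (b, rep), v in row.items():
        bins[b - 1] += v
    bins = np.round(bins)
    total = bins.sum()
    if total <= 0:
        raise ContractViolation(f"variant {variant!r} has zero total count")
    chi2, p = stats.chisquare(bins)
    mean_bin = float(np.dot(np.arange(1, N_BINS + 1), bins) / total)
    midpoint = (1 + N_BINS) / 2
    direction = int(np.sign(mean_bin - midpoint))
    return float(chi2), float(p), direction


def _pearson(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def mutagenesis_score(
    nc: NormalizedCounts, a, b, c, d, variant=None, symmetrized: bool = False
) -> VariantScore:
    """Concordance score of a candidate switch from its A-D variants.

    Same-conformation correlations pair A with B and C with D; opposite
    correlations pair A with C and A with D, exactly as the score is
    defined.  The optional symmetrized mode adds B-C and B-D to the
    opposite term.
    """
    va, vb, vc, vd = (nc.variant_vector(v) for v in (a, b, c, d))
    same = (_pearson(va, vb), _pearson(vc, vd))
    if symmetrized:
        opp_pairs = [(va, vc), (va, vd), (vb, vc), (vb, vd)]
    else:
        opp_pairs = [(va, vc), (va, vd)]
    opposite = tuple(_pearson(x, y) for x, y in opp_pairs)
    cors = same + opposite
    if any(x is None for x in cors):
        score = float("nan")
    else:
        score = float(np.mean(same) - np.mean(opposite))
    return VariantScore(
        variant=variant if variant is not None else a,
        correlations=cors,
        score=score,
    )


def call_significant_switches(scores: list) -> list:
    """Flag scores strictly above mean + 1 sample (n-1) standard deviation.

    Accepts VariantScore objects or bare floats; returns parallel bools.
    Non-finite scores are never flagged and are excluded from the
    threshold computation.
    """
    vals = np.array(
        [s.score if isinstance(s, VariantScore) else float(s) for s in scores]
    )
    finite = vals[np.isfinite(vals)]
    if len(finite) < 2:
        raise ContractViolation("need >= 2 finite scores to set a threshold")
    threshold = float(finite.mean()) + float(finite.std(ddof=1))
    flags = [bool(np.isfinite(v) and v > threshold) for v in vals]
    for s, f in zip(scores, flags):
        if isinstance(s, VariantScore):
            s.significant = f
    return flags
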