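"""Chemical-probing signal processing and the probing support test.

Mutational-profiling counts become per-position rates, rates are
boxplot-normalized (top decile of positions flagged as outliers, signal
scaled by the mean of the next decile), region accessibilities are
summarized over informative residues (A/C for DMS chemistry), and
normalized reactivities can be fed back into ensemble sampling as
pseudo-energy restraints to ask whether in vivo data support the two
in-silico conformations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    ConflictingStemPair,
    ContractViolation,
    ReactivityRestraints,
    RnaSequence,
    Stem,
)


@dataclass
class MutationRateProfile:
    """Per-position mutation counts and read coverage."""

    counts: np.ndarray
    coverage: np.ndarray
    min_coverage: int = 100

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.counts.shape != self.coverage.shape:
            raise ContractViolation("counts and coverage shapes differ")
        if np.any(self.counts < 0) or np.any(self.coverage < 0):
            raise ContractViolation("negative counts or coverage")
        if np.any(self.counts > self.coverage):
            raise ContractViolation("mutation count exceeds coverage")

    @property
    def rates(self) -> np.ndarray:
        """count/coverage, NaN where coverage is below the minimum."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.counts / self.coverage
        r[self.coverage < self.min_coverage] = np.nan
        return r

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class NormalizedReactivity:
    values: np.ndarray  # normalized reactivity, NaN = undefined
    outlier_flags: np.ndarray  # bool
    scale_factor: float


def boxplot_normalize(profile) -> NormalizedReactivity:
    """Boxplot normalization with the top decile treated as outliers.

    The highest ceil(0.10 * n_defined) rates are flagged as outliers
    (ties broken by position index); the scale factor is the mean of the
    next decile of rates (the 80th-90th percentile band); all defined
    values are divided by the scale factor and outliers are capped at
    the largest non-outlier normalized value.
    """
    if isinstance(profile, MutationRateProfile):
        raw = profile.rates
    else:
        raw = np.asarray(profile, dtype=float)
    n = len(raw)
    defined = np.flatnonzero(~np.isnan(raw))
    if len(defined) < 10:
        raise ContractViolation(
            f"need >= 10 defined positions for boxplot normalization, "
            f"got {len(defined)}"
        )
    # sort defined positions by descending rate, ties by ascending index
    order = sorted(defined, key=lambda i: (-raw[i], i))
    n_out = math.ceil(0.10 * len(defined))
    outliers = order[:n_out]
    band = order[n_out : n_out + math.ceil(0.10 * len(defined))]
    scale = float(np.mean([raw[i] for i in band]))
    if scale <= 0:
        raise ContractViolation("degenerate profile: normalization band is all zero")
    values = raw / scale
    flags = np.zeros(n, dtype=bool)
    flags[outliers] = True
    non_outlier_max = max(
        (values[i] for i in order[n_out:]), default=float("nan")
    )
    for i in outliers:
        values[i] = non_outlier_max
    return NormalizedReactivity(values=values, outlier_flags=flags, scale_factor=scale)


@dataclass
class RegionAccessibility:
    region: tuple  # (start, end) 0-based half-open
    value: Optional[float]  # None when no informative position


def region_accessibility(
    nr: NormalizedReactivity,
    seq: RnaSequence,
    region: tuple,
    ac_only: bool = True,
) -> RegionAccessibility:
    """Mean normalized reactivity over a region's informative positions."""
    start, end = region
    if not (0 <= start < end <= len(seq)):
        raise ContractViolation(f"region {region} outside sequence of {len(seq)} nt")
    vals = []
    for i in range(start, end):
        if ac_only and seq.residues[i] not in ("A", "C"):
            continue
        v = nr.values[i]
        if not np.isnan(v):
            vals.append(v)
    if not vals:
        return RegionAccessibility(region=region, value=None)
    return RegionAccessibility(region=region, value=float(np.mean(vals)))


def restraints_from_normalized(
    nr: NormalizedReactivity,
    seq: RnaSequence,
    slope_m: float = 1.8,
    intercept_b: float = -0.6,
    ac_only: bool = True,
) -> ReactivityRestraints:
    """Package normalized reactivities as sampling restraints.

    With DMS chemistry only A/C positions are informative; others are
    marked missing so they contribute no restraint.
    """
    values = []
    for i, v in enumerate(nr.values):
        if np.isnan(v) or (ac_only and seq.residues[i] not in ("A", "C")):
            values.append(None)
        else:
            values.append(max(float(v), 0.0))
    return ReactivityRestraints(values=values, slope_m=slope_m, intercept_b=intercept_b)


def _stem_jaccard(a: Stem, b: Stem) -> float:
    pa, pb = set(a.pairs), set(b.pairs)
    return len(pa & pb) / len(pa | pb)


def _pairs_match(
    cand: ConflictingStemPair, ref: ConflictingStemPair, jaccard: float
) -> bool:
    direct = min(
        _stem_jaccard(cand.stem1, ref.stem1), _stem_jaccard(cand.stem2, ref.stem2)
    )
    swapped = min(
        _stem_jaccard(cand.stem1, ref.stem2), _stem_jaccard(cand.stem2, ref.stem1)
    )
    return max(direct, swapped) >= jaccard


def probing_support_test(
    seq: RnaSequence,
    insilico_pair: ConflictingStemPair,
    restraints: ReactivityRestraints,
    config=None,
    backend=None,
    seed: Optional[int] = None,
) -> bool:
    """Do probing data support the two in-silico conformations?

    The switch prediction is re-run with reactivity restraints applied
    to sampling; the data are supportive iff a stem pair matching the
    in-silico pair (per-stem base-pair Jaccard >= the configured
    threshold, stem order free) appears among the top T ranked
    conflicting stem pairs.
    """
    from .config import RunConfig
    from .conflict import rank_switches

    cfg = config or RunConfig()
    if len(restraints) != len(seq):
        raise ContractViolation("restraints not aligned to sequence")
    ranked = rank_switches(
        seq, config=cfg, restraints=restraints, backend=backend, seed=seed
    )
    for cand in ranked[: cfg.support_top_t]:
        if _pairs_match(cand, insilico_pair, cfg.support_jaccard):
            return True
    return False
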