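"""Synthetic data generators: every pipeline stage testable offline.

The central construct is a designed bistable sequence: a middle "box"
complementary both to a 5' box and to a 3' box, so the molecule folds
into one of two mutually exclusive stems (the three-box competition of
a classic switch).  On the exact backend the ground truth — both stems,
their exact occupancies, every conformation — is computable in closed
form.  Around it: mixture reactivity profiles emulating population-
averaged chemical probing, labeled feature datasets for the classifier,
and multinomial sort-seq screen counts with designed-in true switches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .backends import ExactToyBackend
from .core import (
    ContractViolation,
    RnaSequence,
    SecondaryStructure,
    Stem,
    reverse_complement,
)
from .reactivity import MutationRateProfile
from .screen import N_BINS, ScreenCounts

#: DMS-like mutation rates: accessible A/C vs paired / uninformative
UNPAIRED_RATE = 0.05
PAIRED_RATE = 0.005


@dataclass
class BistableFixture:
    sequence: RnaSequence
    stem1: Stem
    stem2: Stem
    fractions: tuple  # exact Boltzmann fraction of folds in each conformation


def exact_conformation_fractions(
    seq: RnaSequence, stem1: Stem, stem2: Stem, backend: Optional[ExactToyBackend] = None
) -> tuple:
    """Exact Boltzmann probability that a fold sides with stem 1 vs stem 2.

    A fold is assigned to the conformation whose stem contributes more
    of its pairs; ties (including the empty structure) count for
    neither.  Computed by exhaustive enumeration on the toy backend.
    """
    be = backend or ExactToyBackend()
    p1 = p2 = 0.0
    s1, s2 = set(stem1.pairs), set(stem2.pairs)
    for structure, prob in be.enumerate_structures(seq):
        c1 = len(s1 & structure.pairs)
        c2 = len(s2 & structure.pairs)
        if c1 > c2:
            p1 += prob
        elif c2 > c1:
            p2 += prob
    return p1, p2


def make_bistable_sequence(
    stem_len: int = 7,
    linker_len: int = 3,
    seed: int = 0,
    balance: tuple = (0.35, 0.65),
    probing_informative: bool = False,
) -> BistableFixture:
    """A three-box bistable sequence with known ground-truth stems.

    Layout: rc(box) + A-linker + box + A-linker + rc(box).  The central
    box pairs either 5' (stem 1) or 3' (stem 2).  The box is a capped
    homopolymer block over {G, C} — e.g. GCCCCCG — chosen (cap letter by
    seed) because the block structure suppresses shifted pairing
    registers and flank-flank pairing, while the all-A linkers cannot
    pair with the G/C boxes at all.  The construction is verified: the
    exact Boltzmann fractions of folds siding with each stem (computed
    by exhaustive enumeration on the toy backend) must both fall within
    *balance*, else the parameters are rejected as infeasible.

    ``probing_informative`` forces the orientation with C-rich flanks:
    DMS chemistry reads A/C only, and the two conformations differ in
    which flank pairs the central box, so a probing experiment can
    support (or refute) the conformations only when the flanks carry
    informative residues; with the opposite orientation the differing
    strands are all-G and invisible to the reagent by construction.
    """
    if stem_len < 4:
        raise ContractViolation("stem_len must be >= 4 to pass the stem filter")
    if linker_len < 3:
        raise ContractViolation("linker_len must be >= 3 (hairpin loop minimum)")
    L, k = stem_len, linker_len
    total = 3 * L + 2 * k
    backend = ExactToyBackend()
    if total > backend.length_cap:
        raise ContractViolation(
            f"infeasible: {total} nt exceeds the exact backend cap "
            f"{backend.length_cap}"
        )
    rng = np.random.default_rng(seed)
    if probing_informative:
        cap, block = ("C", "G")  # box G-block -> flanks C-rich (DMS-visible)
    else:
        cap, block = ("G", "C") if rng.integers(2) == 0 else ("C", "G")
    box = cap + block * (L - 2) + cap
    s = L + k  # start of the central box
    stem1 = Stem(((0, L - 1), (s, s + L - 1)))
    stem2 = Stem(((s, s + L - 1), (2 * s, 2 * s + L - 1)))
    residues = (
        reverse_complement(box) + "A" * k + box + "A" * k + reverse_complement(box)
    )
    seq = RnaSequence(id=f"bistable_L{L}k{k}s{seed}", residues=residues)
    f1, f2 = exact_conformation_fractions(seq, stem1, stem2, backend)
    if not (balance[0] <= f1 <= balance[1] and balance[0] <= f2 <= balance[1]):
        raise ContractViolation(
            f"infeasible parameters: stem_len={L}, linker_len={k} gives "
            f"unbalanced conformation fractions ({f1:.3f}, {f2:.3f})"
        )
    return BistableFixture(sequence=seq, stem1=stem1, stem2=stem2, fractions=(f1, f2))


def recovers_designed(pair, fixture: BistableFixture) -> bool:
    """Does a predicted stem pair recover the fixture's designed switch?

    Under the toy energy model the rarely-formed outermost pairs of each
    designed stem fall below the ensemble-frequency floor (arm-split
    states carry the same pair count as pure conformations, so boundary
    pairs are genuinely infrequent); the prediction therefore recovers
    the cores of the two designed stems.  Recovery = each predicted stem's
    pairs are a subset of a distinct designed stem's pairs.
    """
    if pair is None:
        return False
    p1, p2 = set(pair.stem1.pairs), set(pair.stem2.pairs)
    d1, d2 = set(fixture.stem1.pairs), set(fixture.stem2.pairs)
    return (p1 <= d1 and p2 <= d2) or (p1 <= d2 and p2 <= d1)


def simulate_reactivity_mixture(
    seq: RnaSequence,
    conf1: SecondaryStructure,
    conf2: SecondaryStructure,
    proportion: float,
    noise_sd: float = 0.1,
    depth: int = 10_000,
    seed: int = 0,
) -> MutationRateProfile:
    """Population-averaged probing profile of a two-conformation mixture.

    Expected rate per position: proportion * rate(conf1) +
    (1 - proportion) * rate(conf2), where an unpaired A/C reacts at
    UNPAIRED_RATE, everything else sits at the PAIRED_RATE baseline.
    Rates get lognormal position noise and binomial sampling at *depth*.
    """
    if not 0 <= proportion <= 1:
        raise ContractViolation("proportion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(seq)
    unpaired1 = np.ones(n, dtype=bool)
    unpaired2 = np.ones(n, dtype=bool)
    for i, j in conf1.pairs:
        unpaired1[[i, j]] = False
    for i, j in conf2.pairs:
        unpaired2[[i, j]] = False
    informative = np.array([c in "AC" for c in seq.residues])

    def pos_rate(unp):
        return np.where(unp & informative, UNPAIRED_RATE, PAIRED_RATE)

    expected = proportion * pos_rate(unpaired1) + (1 - proportion) * pos_rate(
        unpaired2
    )
    if noise_sd > 0:
        expected = expected * np.exp(
            rng.normal(0.0, noise_sd, size=n) - noise_sd**2 / 2
        )
    expected = np.clip(expected, 0.0, 1.0)
    counts = rng.binomial(depth, expected)
    return MutationRateProfile(
        counts=counts.astype(float), coverage=np.full(n, float(depth))
    )


def _bin_profile(mode: float, width: float = 1.2) -> np.ndarray:
    """Unimodal 8-bin probability profile: a discretized Gaussian.

    Sort-seq fluorescence is roughly log-normal, so the bin-occupancy
    profile of one variant is a truncated Gaussian over the bin axis.
    """
    bins = np.arange(N_BINS, dtype=float)
    p = np.exp(-((bins - mode) ** 2) / (2 * width**2))
    return p / p.sum()


def simulate_screen_counts(
    n_variants: int = 200,
    effect_size: float = 1.0,
    depth: int = 5000,
    seed: int = 0,
    frac_true: float = 0.05,
    n_replicates: int = 2,
    profile_width: float = 1.2,
    mode_center: float = 3.5,
    mode_sd: float = 0.3,
):
    """Multinomial sort-seq counts for candidate-switch quartets A-D.

    A fraction *frac_true* of candidates are true switches: their A/B
    variants' bin-distribution mode is shifted by -effect_size bins and
    C/D by +effect_size relative to the candidate's base mode; the rest
    share one mode across all four variants.  Per (variant, replicate)
    totals equal *depth*.

    Non-switch base modes scatter tightly (sd *mode_sd*) around the
    library's central expression *mode_center*: reporter libraries are
    dominated by members with near-median output, and median-of-ratios
    normalization divides out exactly that consensus profile — a variant
    shaped like the consensus normalizes to a flat, uninformative
    vector, so the concordance score can only see shifts AWAY from the
    consensus.  Returns (ScreenCounts, truth), truth: candidate -> bool.
    """
    if depth < N_BINS:
        raise ContractViolation("depth must be >= number of bins")
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    n_true = int(round(frac_true * n_variants))
    for v in range(n_variants):
        is_true = v < n_true
        cand = f"cand{v:04d}"
        truth[cand] = is_true
        base_mode = rng.normal(mode_center, mode_sd)
        for cls in "ABCD":
            if is_true:
                mode = base_mode - effect_size if cls in "AB" else base_mode + effect_size
            else:
                mode = base_mode
            profile = _bin_profile(mode, profile_width)
            for rep in range(1, n_replicates + 1):
                counts = rng.multinomial(depth, profile)
                for b in range(N_BINS):
                    rows.append(
                        {
                            "variant": f"{cand}_{cls}",
                            "bin": b + 1,
                            "replicate": rep,
                            "count": int(counts[b]),
                        }
                    )
    table = pd.DataFrame(rows)
    return ScreenCounts(table=table), truth


#: construction groups for the labeled dataset: (stem_len, linker_len)
FAMILY_GEOMETRIES = [(6, 3), (6, 4), (6, 5), (7, 3), (7, 4)]


def make_labeled_dataset(
    n_per_class: int = 100,
    n_families: int = 5,
    seed: int = 0,
    config=None,
) -> list:
    """Labeled feature examples: bistable fixtures vs their dinucleotide shuffles.

    Positives are designed bistable sequences; negatives are their
    dinucleotide-preserving shuffles.  Both go through the *real*
    feature pipeline (ensemble -> conflict detection -> conformations ->
    barrier) on the exact backend.  Family labels follow the
    construction geometry (stem length, linker length), giving LOFO
    cross-validation genuinely disjoint groups.
    """
    from .classifier import LabeledExample, dinucleotide_shuffle
    from .config import RunConfig
    from .conformations import features_for_sequence

    if n_per_class < 10:
        raise ContractViolation("need >= 10 examples per class")
    if not 2 <= n_families <= len(FAMILY_GEOMETRIES):
        raise ContractViolation(
            f"n_families must be in [2, {len(FAMILY_GEOMETRIES)}]"
        )
    cfg = config or RunConfig()
    backend = ExactToyBackend()
    per_family = [
        n_per_class // n_families + (1 if f < n_per_class % n_families else 0)
        for f in range(n_families)
    ]
    examples = []
    for f in range(n_families):
        stem_len, linker_len = FAMILY_GEOMETRIES[f]
        family = f"L{stem_len}k{linker_len}"
        for k in range(per_family[f]):
            fixture_seed = seed * 100_003 + f * 1009 + k
            fx = make_bistable_sequence(
                stem_len=stem_len, linker_len=linker_len, seed=fixture_seed
            )
            _, feats = features_for_sequence(
                fx.sequence, config=cfg, backend=backend, seed=fixture_seed
            )
            examples.append(
                LabeledExample(features=feats, label=1, family=family)
            )
            shuf = dinucleotide_shuffle(fx.sequence, seed=fixture_seed + 1)
            _, sfeats = features_for_sequence(
                shuf, config=cfg, backend=backend, seed=fixture_seed + 2
            )
            examples.append(
                LabeledExample(features=sfeats, label=0, family=family)
            )
    return examples
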