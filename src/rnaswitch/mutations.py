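"""Design of conformation-locking mutations for a candidate switch.

For a switch with conflicting stems 1 and 2, four variants are built:

A  strengthen stem 1 (rewrite both its arms, keeping complementarity,
   so that stem 2 can no longer form)          -> locks conformation 1
B  weaken stem 2 (rewrite one of its arms, leaving stem 1 untouched)
                                               -> locks conformation 1
C  strengthen stem 2                           -> locks conformation 2
D  weaken stem 1                               -> locks conformation 2

Candidates are filtered (rival stem must not re-form more than a
fraction of its pairs; the edit must not create long complementary runs
with the rest of the sequence), ranked by how little they change the
mononucleotide composition, and verified by re-sampling the mutant's
Boltzmann ensemble to confirm the shift toward the target conformation.
All edits are same-length replacements, so stem coordinates are
unchanged in the mutant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    CANONICAL_PAIRS,
    ContractViolation,
    RnaSequence,
    Stem,
    reverse_complement,
)

BASES = "ACGU"


class MutationDesignError(RuntimeError):
    """No candidate survives the filters (or verification) for a class."""


@dataclass
class MutantVariant:
    variant_class: str  # A, B, C or D
    sequence: RnaSequence
    edited_intervals: list  # [(start, end)] 0-based inclusive
    composition_distance: int
    shift_stats: Optional[tuple] = None  # (target_frac, rival_frac)
    verified: bool = False

    @property
    def label(self) -> str:
        """offset-REPLACEMENT naming, e.g. 77-GA for an edit of GA at offset 77."""
        parts = []
        for a, b in self.edited_intervals:
            parts.append(f"{a}-{self.sequence.residues[a:b + 1]}")
        return "_".join(parts)


@dataclass
class MutationSet:
    reference: RnaSequence
    variants: dict  # class letter -> MutantVariant

    def __post_init__(self) -> None:
        if sorted(self.variants) != ["A", "B", "C", "D"]:
            raise ContractViolation(
                f"mutation set must have classes A-D exactly once, "
                f"got {sorted(self.variants)}"
            )


def composition_distance(a: str, b: str) -> int:
    """L1 distance between mononucleotide count vectors."""
    return sum(abs(a.count(c) - b.count(c)) for c in BASES)


def reformable_pairs(residues: str, stem: Stem) -> int:
    """How many of the stem's original pairings are canonical in *residues*."""
    count = 0
    for i, j in stem.pairs:
        if (residues[i], residues[j]) in CANONICAL_PAIRS:
            count += 1
    return count


def _pairable(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def max_complement_run(residues: str, edited_intervals: list) -> int:
    """Longest antiparallel pairable run between edited and unedited parts.

    A run of length L is positions (a+t, b-t), t = 0..L-1, each a
    canonical pair (AU/GC/GU), where one strand of the run intersects an
    edited interval and the other strand is disjoint from every edited
    interval.  The intended pairing between two co-edited stem arms is
    deliberately not penalized.  Scans each anti-diagonal once: within a
    maximal stretch where pairing holds and one strand is edit-free, the
    whole stretch qualifies as soon as the other strand touches an edit.
    """
    n = len(residues)
    edited = np.zeros(n, dtype=bool)
    for a, b in edited_intervals:
        edited[a : b + 1] = True
    best = 0
    for diag in range(1, 2 * n - 2):  # diag = i + j
        lo = max(0, diag - n + 1)
        hi = (diag - 1) // 2  # ensure i < j
        # two orientations: edit on left strand / edit on right strand
        for want_edit_left in (True, False):
            run = 0
            has_edit = False
            for i in range(lo, hi + 1):
                j = diag - i
                clean = (not edited[j]) if want_edit_left else (not edited[i])
                if _pairable(residues[i], residues[j]) and clean:
                    run += 1
                    has_edit |= bool(edited[i] if want_edit_left else edited[j])
                    if has_edit and run > best:
                        best = run
                else:
                    run = 0
                    has_edit = False
    return best


def _interval_residues(residues: str, interval: tuple) -> str:
    return residues[interval[0] : interval[1] + 1]


def _replace(residues: str, interval: tuple, repl: str) -> str:
    a, b = interval
    return residues[:a] + repl + residues[b + 1 :]


def _enumerate_replacements(length: int, config, rng: np.random.Generator):
    """All 4^length strings when small, else a seeded random sample."""
    if length <= config.exhaustive_interval_cap:
        for tup in itertools.product(BASES, repeat=length):
            yield "".join(tup)
    else:
        seen = set()
        budget = config.random_candidate_budget
        for _ in range(budget):
            cand = "".join(BASES[k] for k in rng.integers(0, 4, size=length))
            if cand not in seen:
                seen.add(cand)
                yield cand


def _intervals_overlap(a: tuple, b: tuple) -> bool:
    return not (a[1] < b[0] or b[1] < a[0])


def _materialize(
    seq: RnaSequence,
    candidates: list,  # (mutated_residues, edited_intervals)
    predicate,
    variant_class: str,
    max_candidates: Optional[int],
) -> list:
    """Apply filters lazily over rank-ordered candidates."""
    out = []
    for mutated, intervals in candidates:
        if not predicate(mutated, intervals):
            continue
        out.append(
            MutantVariant(
                variant_class=variant_class,
                sequence=RnaSequence(id=f"{seq.id}_{variant_class}", residues=mutated),
                edited_intervals=list(intervals),
                composition_distance=composition_distance(seq.residues, mutated),
            )
        )
        if max_candidates is not None and len(out) >= max_candidates:
            break
    return out


def design_strengthen_variants(
    seq: RnaSequence,
    keep_stem: Stem,
    kill_stem: Stem,
    config=None,
    variant_class: str = "A",
    seed: int = 0,
    max_candidates: Optional[int] = None,
) -> list:
    """Rewrite keep_stem's 5' arm (3' arm gets the reverse complement).

    Filters: the rival stem must not be able to re-form more than
    ``refold_fraction`` of its original pairs, and the edit must not
    create a complementary run longer than ``complement_run_threshold``
    with unedited sequence.  Survivors come sorted by ascending
    composition distance (ties by mutant sequence); *max_candidates*
    truncates the list without changing its order.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    five, three = keep_stem.intervals
    max_refold = cfg.refold_fraction * kill_stem.length

    cands = []
    for repl in _enumerate_replacements(keep_stem.length, cfg, rng):
        mutated = _replace(seq.residues, five, repl)
        mutated = _replace(mutated, three, reverse_complement(repl))
        cands.append((mutated, (five, three)))
    cands.sort(key=lambda t: (composition_distance(seq.residues, t[0]), t[0]))

    def ok(mutated: str, intervals) -> bool:
        if reformable_pairs(mutated, kill_stem) > max_refold:
            return False
        return (
            max_complement_run(mutated, list(intervals))
            <= cfg.complement_run_threshold
        )

    return _materialize(seq, cands, ok, variant_class, max_candidates)


def design_weaken_variants(
    seq: RnaSequence,
    keep_stem: Stem,
    kill_stem: Stem,
    config=None,
    variant_class: str = "B",
    seed: int = 0,
    max_candidates: Optional[int] = None,
) -> list:
    """Rewrite one arm of kill_stem at a time, leaving keep_stem untouched."""
    from .config import RunConfig

    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    max_refold = cfg.refold_fraction * kill_stem.length

    cands = []
    for interval in kill_stem.intervals:
        if any(_intervals_overlap(interval, kiv) for kiv in keep_stem.intervals):
            continue  # filter (i): keep_stem must stay unchanged
        for repl in _enumerate_replacements(interval[1] - interval[0] + 1, cfg, rng):
            cands.append((_replace(seq.residues, interval, repl), (interval,)))
    cands.sort(key=lambda t: (composition_distance(seq.residues, t[0]), t[0]))

    def ok(mutated: str, intervals) -> bool:
        if reformable_pairs(mutated, keep_stem) != keep_stem.length:
            return False  # keep_stem pairing must be fully preserved
        if reformable_pairs(mutated, kill_stem) > max_refold:
            return False
        return (
            max_complement_run(mutated, list(intervals))
            <= cfg.complement_run_threshold
        )

    return _materialize(seq, cands, ok, variant_class, max_candidates)


def _interval_contacts(structure, stem: Stem) -> int:
    """Pairs of the fold connecting the stem's two arm intervals (any register)."""
    (u, v), (x, y) = stem.intervals
    return sum(1 for i, j in structure.pairs if u <= i <= v and x <= j <= y)


def conformation_fractions(
    structures: list,
    stem_a: Stem,
    stem_b: Stem,
    mode: str = "conformation_share",
    presence_frac: float = 0.8,
) -> tuple:
    """Fraction of the ensemble siding with each of two competing stems.

    Each fold is assigned to the stem whose two arm intervals it
    connects with more base pairs — any pairing register between the
    arms counts as that conformation; ties count for neither.
    ``conformation_share`` (default) returns the two conformations'
    shares of the assigned folds (summing to 1 when any fold takes
    either conformation); ``interval_contact`` returns the absolute
    ensemble fractions instead.

    ``pair_mean``: per-stem mean, over its exact pairs, of their fold
    frequency.  ``fold_membership``: per-stem fraction of folds
    containing at least ``presence_frac`` of its exact pairs.  These two
    treat each stem independently.
    """
    n = len(structures)
    if mode in ("conformation_share", "interval_contact"):
        fa = fb = 0
        for s in structures:
            ca = _interval_contacts(s, stem_a)
            cb = _interval_contacts(s, stem_b)
            if ca > cb:
                fa += 1
            elif cb > ca:
                fb += 1
        if mode == "conformation_share":
            # shares of the two-state equilibrium: how the folds that take
            # either conformation split between them
            total = fa + fb
            if total == 0:
                return 0.0, 0.0
            return fa / total, fb / total
        return fa / n, fb / n
    if mode == "pair_mean":
        return tuple(
            sum(len(set(stem.pairs) & s.pairs) for s in structures)
            / (n * stem.length)
            for stem in (stem_a, stem_b)
        )
    if mode == "fold_membership":
        return tuple(
            sum(
                1
                for s in structures
                if len(set(stem.pairs) & s.pairs) >= presence_frac * stem.length
            )
            / n
            for stem in (stem_a, stem_b)
        )
    raise ContractViolation(f"unknown stem fraction mode {mode!r}")


def verify_conformational_shift(
    mutant: RnaSequence,
    target_stem: Stem,
    rival_stem: Stem,
    backend=None,
    n: int = 1000,
    seed: int = 0,
    config=None,
) -> tuple:
    """Sample the mutant's ensemble; return (target_frac, rival_frac, shifted).

    "Heavily shifted" means the target conformation holds at least
    ``shift_target_min`` of the ensemble while the rival holds at most
    ``shift_rival_max``.  Coordinates need no remapping: all edits are
    same-length replacements.
    """
    from .backends import ExactToyBackend
    from .config import RunConfig

    cfg = config or RunConfig()
    if backend is None:
        backend = ExactToyBackend()
    structures = backend.sample(mutant, n, seed=seed)
    tf, rf = conformation_fractions(
        structures,
        target_stem,
        rival_stem,
        mode=cfg.stem_fraction_mode,
        presence_frac=cfg.stem_presence_frac,
    )
    shifted = tf >= cfg.shift_target_min and rf <= cfg.shift_rival_max
    return tf, rf, shifted


def design_mutation_set(
    seq: RnaSequence,
    pair,
    config=None,
    backend=None,
    seed: int = 0,
) -> MutationSet:
    """One verified conformation-locking variant per class A-D."""
    from .config import RunConfig

    cfg = config or RunConfig()
    s1, s2 = pair.stem1, pair.stem2
    plans = {
        "A": ("strengthen", s1, s2),  # lock conformation 1
        "B": ("weaken", s1, s2),
        "C": ("strengthen", s2, s1),  # lock conformation 2
        "D": ("weaken", s2, s1),
    }
    variants = {}
    failing = []
    for cls in "ABCD":
        kind, keep, kill = plans[cls]
        design = (
            design_strengthen_variants if kind == "strengthen" else design_weaken_variants
        )
        candidates = design(
            seq, keep, kill, config=cfg, variant_class=cls, seed=seed,
            max_candidates=cfg.max_verify_candidates,
        )
        chosen = None
        for k, cand in enumerate(candidates):
            tf, rf, ok = verify_conformational_shift(
                cand.sequence,
                target_stem=keep,
                rival_stem=kill,
                backend=backend,
                n=cfg.n_samples,
                seed=seed + k,
                config=cfg,
            )
            if ok:
                cand.shift_stats = (tf, rf)
                cand.verified = True
                chosen = cand
                break
        if chosen is None:
            failing.append(cls)
        else:
            variants[cls] = chosen
    if failing:
        raise MutationDesignError(
            f"partial mutation set: no verified candidate for class(es) "
            f"{','.join(failing)}"
        )
    return MutationSet(reference=seq, variants=variants)
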