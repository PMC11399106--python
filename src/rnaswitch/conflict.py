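"""Detection of mutually exclusive stem pairs from a fold ensemble.

The core idea: represent each base pair seen in the ensemble as a binary
presence vector over the N sampled folds, compute pairwise mutual
information between these vectors, and look for pairs of stems whose
constituent base pairs carry high total mutual information — those are
the alternative helices of a bi-stable switch.

Pipeline: frequency filter -> MI table -> K row-sums -> U*MAX(K)
threshold -> stem assembly from adjacent pairs -> conflicting-stem-pair
ranking by mean K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    ConflictingStemPair,
    ContractViolation,
    FoldEnsemble,
    ReactivityRestraints,
    RnaSequence,
    Stem,
)


@dataclass
class BasePairPresence:
    pair: tuple
    presence: np.ndarray  # uint8 vector of length N
    frequency: float


@dataclass
class MutualInformationTable:
    pairs: list  # list of (i, j)
    mi: np.ndarray  # M x M, bits, zero diagonal
    k_sums: np.ndarray  # length M, row sums excluding the diagonal


def collect_base_pairs(
    ensemble: FoldEnsemble, f_min: float = 0.05, f_max: float = 0.95
) -> list:
    """Base pairs with ensemble frequency in [f_min, f_max].

    Pairs present in (almost) every fold or (almost) no fold carry no
    information about alternative conformations and are dropped.
    """
    if not 0 <= f_min < f_max <= 1:
        raise ContractViolation(f"need 0 <= f_min < f_max <= 1, got {f_min}, {f_max}")
    n = ensemble.n
    index: dict = {}
    for k, structure in enumerate(ensemble.structures):
        for pair in structure.pairs:
            vec = index.get(pair)
            if vec is None:
                vec = np.zeros(n, dtype=np.uint8)
                index[pair] = vec
            vec[k] = 1
    out = []
    for pair in sorted(index):
        vec = index[pair]
        freq = float(vec.mean())
        if f_min <= freq <= f_max:
            out.append(BasePairPresence(pair=pair, presence=vec, frequency=freq))
    return out


def mutual_information(p: np.ndarray, q: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two binary vectors."""
    p = np.asarray(p, dtype=np.uint8)
    q = np.asarray(q, dtype=np.uint8)
    if p.shape != q.shape or p.ndim != 1 or p.size < 1:
        raise ContractViolation("mutual_information needs equal-length 1-D vectors")
    n = p.size
    n11 = int(np.sum((p == 1) & (q == 1)))
    n10 = int(np.sum((p == 1) & (q == 0)))
    n01 = int(np.sum((p == 0) & (q == 1)))
    n00 = n - n11 - n10 - n01
    total = 0.0
    for nij, ni, nj in (
        (n00, n00 + n01, n00 + n10),
        (n01, n00 + n01, n01 + n11),
        (n10, n10 + n11, n00 + n10),
        (n11, n10 + n11, n01 + n11),
    ):
        if nij > 0:
            total += (nij / n) * np.log2(nij * n / (ni * nj))
    return max(total, 0.0)


def mi_table(presences: list) -> MutualInformationTable:
    """All-against-all MI of the presence vectors, vectorized over joint counts."""
    if not presences:
        raise ContractViolation("no base pairs to analyze")
    P = np.stack([bp.presence for bp in presences]).astype(np.float64)  # M x N
    m, n = P.shape
    n11 = P @ P.T
    ones = P.sum(axis=1)  # marginal counts
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = n - n11 - n10 - n01

    def term(nij, ni, nj):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (nij / n) * np.log2(nij * n / (ni * nj))
        return np.where(nij > 0, t, 0.0)

    mi = (
        term(n00, n00 + n01, n00 + n10)
        + term(n01, n00 + n01, n01 + n11)
        + term(n10, n10 + n11, n00 + n10)
        + term(n11, n10 + n11, n01 + n11)
    )
    mi = np.maximum(mi, 0.0)
    np.fill_diagonal(mi, 0.0)
    mi = (mi + mi.T) / 2.0  # symmetrize away float noise
    k_sums = mi.sum(axis=1)
    return MutualInformationTable(
        pairs=[bp.pair for bp in presences], mi=mi, k_sums=k_sums
    )


def select_conflicting_base_pairs(
    table: MutualInformationTable, U: float = 0.5
) -> list:
    """Indices of base pairs with K >= U * max(K)."""
    if len(table.pairs) < 1:
        raise ContractViolation("empty MI table")
    if not 0 < U <= 1:
        raise ContractViolation(f"U must be in (0, 1], got {U}")
    kmax = float(table.k_sums.max())
    return [a for a in range(len(table.pairs)) if table.k_sums[a] >= U * kmax]


def assemble_stems(conflicting_pairs: list, min_len: int = 3) -> list:
    """Merge adjacent base pairs into maximal stems; keep length > min_len.

    Pairs (a, b) and (c, d) are adjacent when (a, b) == (c-1, d+1) or
    (c+1, d-1): stacked in the same helix.
    """
    pset = set(conflicting_pairs)
    stems = []
    for i, j in sorted(pset):
        if (i - 1, j + 1) in pset:
            continue  # not the outermost pair of its run
        length = 1
        while (i + length, j - length) in pset:
            length += 1
        stems.append(Stem(((i, i + length - 1), (j - length + 1, j))))
    return [s for s in stems if s.length > min_len]


def _interval_overlap(a: tuple, b: tuple) -> int:
    """Overlap length of two 0-based inclusive intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def stems_conflict(s1: Stem, s2: Stem, overlap_threshold: int = 3) -> int:
    """Largest overlap between any arm of s1 and any arm of s2.

    The stems conflict when this exceeds overlap_threshold (strict).
    """
    best = 0
    for a in s1.intervals:
        for b in s2.intervals:
            best = max(best, _interval_overlap(a, b))
    return best


def find_conflicting_pairs(
    stems: list,
    k_by_pair: dict,
    overlap_threshold: int = 3,
) -> list:
    """All conflicting stem pairs ranked by mean K over both stems' pairs.

    Ties are broken lexicographically by (u of stem1, x of stem1,
    u of stem2) with stem1 being the 5'-most stem of the two.
    """
    results = []
    for a in range(len(stems)):
        for b in range(a + 1, len(stems)):
            s1, s2 = stems[a], stems[b]
            if s1.intervals > s2.intervals:
                s1, s2 = s2, s1
            overlap = stems_conflict(s1, s2, overlap_threshold)
            if overlap <= overlap_threshold:
                continue
            ks = [k_by_pair[p] for p in s1.pairs + s2.pairs if p in k_by_pair]
            if not ks:
                continue
            score = float(np.mean(ks))
            results.append(ConflictingStemPair(s1, s2, score, overlap))
    results.sort(
        key=lambda cp: (
            -cp.score,
            cp.stem1.intervals[0][0],
            cp.stem1.intervals[1][0],
            cp.stem2.intervals[0][0],
        )
    )
    return results


def rank_switches(
    seq: RnaSequence,
    config=None,
    restraints: Optional[ReactivityRestraints] = None,
    backend=None,
    ensemble: Optional[FoldEnsemble] = None,
    seed: Optional[int] = None,
) -> list:
    """Full conflict-detection pipeline; all surviving stem pairs, ranked."""
    from .config import RunConfig
    from .backends import sample_ensemble, get_backend

    cfg = config or RunConfig()
    if ensemble is None:
        if backend is None:
            backend = get_backend(cfg.backend)
        ensemble = sample_ensemble(
            seq,
            n_samples=cfg.n_samples,
            restraints=restraints,
            seed=cfg.sampler_seed if seed is None else seed,
            backend=backend,
        )
    presences = collect_base_pairs(ensemble, cfg.f_min, cfg.f_max)
    if not presences:
        return []
    table = mi_table(presences)
    keep = select_conflicting_base_pairs(table, cfg.mi_threshold_u)
    conflicting = [table.pairs[a] for a in keep]
    k_by_pair = {table.pairs[a]: float(table.k_sums[a]) for a in keep}
    stems = assemble_stems(conflicting, cfg.min_stem_len)
    return find_conflicting_pairs(stems, k_by_pair, cfg.overlap_threshold)


def predict_switch(
    seq: RnaSequence,
    config=None,
    restraints: Optional[ReactivityRestraints] = None,
    backend=None,
    ensemble: Optional[FoldEnsemble] = None,
    seed: Optional[int] = None,
) -> Optional[ConflictingStemPair]:
    """The highest-scoring conflicting stem pair, or None if no switch found."""
    ranked = rank_switches(
        seq,
        config=config,
        restraints=restraints,
        backend=backend,
        ensemble=ensemble,
        seed=seed,
    )
    return ranked[0] if ranked else None
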