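"""The two conformations of a candidate switch and the barrier between them.

Each conflicting stem is forced in turn as a folding constraint, and the
corresponding conformation is predicted by maximum-expected-accuracy
(MEA) dynamic programming over the ensemble's base-pair frequencies:
maximize sum over paired (i,j) of 2*gamma*p(i,j) plus sum over unpaired
i of q(i), q(i) = 1 - sum_j p(i,j).  Accuracy, not energy, is the
objective.

The activation barrier of the conf1 -> conf2 transition is estimated by
a beam search over single base-pair additions/removals; the result is
an upper bound on the true minimal barrier.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import (
    BarrierEstimate,
    ConflictingStemPair,
    ConformationPair,
    ContractViolation,
    FoldEnsemble,
    RnaSequence,
    SecondaryStructure,
    Stem,
    SwitchFeatures,
    MIN_HAIRPIN_LOOP,
)

FORCE_BONUS = 1.0e6  # reward per forced pair in the MEA objective


def pair_frequencies(ensemble: FoldEnsemble) -> np.ndarray:
    """Ensemble frequency of every base pair as an n x n upper matrix."""
    n = len(ensemble.sequence)
    p = np.zeros((n, n), dtype=float)
    for structure in ensemble.structures:
        for i, j in structure.pairs:
            p[i, j] += 1.0
    p /= ensemble.n
    return p


def _crosses_or_clashes(i: int, j: int, forced: tuple) -> bool:
    for a, b in forced:
        if (i, j) == (a, b):
            continue
        if i in (a, b) or j in (a, b):
            return True
        if (a < i < b < j) or (i < a < j < b):
            return True
    return False


def mea_structure(
    seq: RnaSequence,
    p: np.ndarray,
    forced_stem: Optional[Stem] = None,
    gamma: float = 1.0,
) -> SecondaryStructure:
    """MEA structure given pair probabilities, with a stem optionally forced.

    Forced pairs receive a large score bonus (guaranteeing inclusion);
    pairs crossing or sharing an endpoint with a forced pair are
    forbidden.
    """
    n = len(seq)
    forced = forced_stem.pairs if forced_stem is not None else ()
    for i, j in forced:
        if not seq.can_pair(i, j):
            raise ContractViolation(
                f"infeasible constraints: forced pair {(i, j)} is not canonical"
            )
    SecondaryStructure.from_pairs(forced).validate(seq)  # crossing check

    q = np.clip(1.0 - (p.sum(axis=1) + p.sum(axis=0)), 0.0, None)
    s = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            if not seq.can_pair(i, j):
                continue
            if _crosses_or_clashes(i, j, forced):
                continue
            s[i, j] = 2.0 * gamma * p[i, j]
    for i, j in forced:
        s[i, j] += FORCE_BONUS

    M = np.zeros((n + 1, n + 1), dtype=float)  # M[i][j] over i..j-1 half-open
    choice = {}

    def mval(i, j):  # inclusive interval i..j, empty -> 0
        return M[i][j + 1] if j >= i else 0.0

    for span in range(0, n):
        for i in range(0, n - span):
            j = i + span
            best = mval(i + 1, j) + q[i]
            bk = ("unpaired",)
            for k in range(i + 1, j + 1):
                if s[i, k] == -np.inf:
                    continue
                v = s[i, k] + mval(i + 1, k - 1) + mval(k + 1, j)
                if v > best + 1e-12:
                    best = v
                    bk = ("pair", k)
            M[i][j + 1] = best
            choice[(i, j)] = bk

    pairs = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i > j:
            continue
        c = choice[(i, j)]
        if c[0] == "unpaired":
            stack.append((i + 1, j))
        else:
            k = c[1]
            pairs.append((i, k))
            stack.append((i + 1, k - 1))
            stack.append((k + 1, j))
    return SecondaryStructure.from_pairs(pairs)


def predict_conformations(
    seq: RnaSequence,
    pair: ConflictingStemPair,
    ensemble: FoldEnsemble,
    backend=None,
    gamma: float = 1.0,
) -> ConformationPair:
    """MEA conformations with each conflicting stem forced in turn."""
    from .backends import ExactToyBackend

    if backend is None:
        backend = ExactToyBackend()
    p = pair_frequencies(ensemble)
    conf1 = mea_structure(seq, p, forced_stem=pair.stem1, gamma=gamma)
    conf2 = mea_structure(seq, p, forced_stem=pair.stem2, gamma=gamma)
    for stem, conf in ((pair.stem1, conf1), (pair.stem2, conf2)):
        missing = set(stem.pairs) - set(conf.pairs)
        if missing:
            raise ContractViolation(f"forced pairs {missing} missing from conformation")
    return ConformationPair(
        conf1=conf1,
        conf2=conf2,
        e1=backend.evaluate_energy(seq, conf1),
        e2=backend.evaluate_energy(seq, conf2),
        constraint_stems=(pair.stem1, pair.stem2),
    )


def _structure_key(pairs: frozenset) -> tuple:
    return tuple(sorted(pairs))


def _legal_addition(pairs: frozenset, i: int, j: int) -> bool:
    for a, b in pairs:
        if i in (a, b) or j in (a, b):
            return False
        if (a < i < b < j) or (i < a < j < b):
            return False
    return True


def estimate_barrier(
    seq: RnaSequence,
    conf1: SecondaryStructure,
    conf2: SecondaryStructure,
    backend=None,
    beam_width: int = 50,
    keep_path: bool = True,
) -> BarrierEstimate:
    """Beam-search estimate of the refolding barrier conf1 -> conf2.

    Moves remove a pair not in conf2 or add a compatible pair of conf2;
    every path therefore has exactly |conf1 ^ conf2| steps.  The barrier
    is max path energy minus E(conf1); the beam keeps the *beam_width*
    states with the lowest running maximum, so the result upper-bounds
    the true minimal direct-path barrier (and equals it when the beam is
    wide enough to be exhaustive).
    """
    from .backends import ExactToyBackend

    if backend is None:
        backend = ExactToyBackend()
    conf1.validate(seq)
    conf2.validate(seq)

    def energy(pairs: frozenset) -> float:
        return backend.evaluate_energy(seq, SecondaryStructure(pairs))

    start, goal = conf1.pairs, conf2.pairs
    e_start = energy(start)
    if start == goal:
        return BarrierEstimate(0.0, path=[conf1] if keep_path else None)

    # state: (max_energy_so_far, current_energy, pairs, path)
    beam = [(e_start, e_start, start, [start] if keep_path else None)]
    visited = {_structure_key(start): e_start}
    goal_best = None
    nsteps = len(start ^ goal)
    for _ in range(nsteps):
        candidates = []
        for mx, e, pairs, path in beam:
            for pq in pairs - goal:
                nxt = pairs - {pq}
                candidates.append((mx, e, pairs, path, nxt))
            for pq in goal - pairs:
                if _legal_addition(pairs, *pq):
                    nxt = pairs | {pq}
                    candidates.append((mx, e, pairs, path, nxt))
        nxt_beam = []
        for mx, e, pairs, path, nxt in candidates:
            en = energy(nxt)
            nmx = max(mx, en)
            key = _structure_key(nxt)
            if key in visited and visited[key] <= nmx:
                continue
            visited[key] = nmx
            npath = path + [nxt] if keep_path else None
            nxt_beam.append((nmx, en, nxt, npath))
        nxt_beam.sort(key=lambda t: (t[0], t[1], _structure_key(t[2])))
        beam = nxt_beam[:beam_width]
        for mx, e, pairs, path in beam:
            if pairs == goal and (goal_best is None or mx < goal_best[0]):
                goal_best = (mx, path)
        if not beam:
            break
    if goal_best is None:  # beam lost the goal; fall back to naive path
        order = sorted(start - goal) + sorted(goal - start)
        pairs = set(start)
        mx = e_start
        path = [frozenset(pairs)] if keep_path else None
        for pq in order:
            if pq in pairs:
                pairs.discard(pq)
            elif _legal_addition(frozenset(pairs), *pq):
                pairs.add(pq)
            mx = max(mx, energy(frozenset(pairs)))
            if keep_path:
                path.append(frozenset(pairs))
        goal_best = (mx, path)
    barrier = max(0.0, goal_best[0] - e_start)
    path_structs = (
        [SecondaryStructure(p) for p in goal_best[1]] if keep_path else None
    )
    return BarrierEstimate(barrier, path=path_structs)


def compute_switch_features(
    cp: ConformationPair, be: BarrierEstimate
) -> SwitchFeatures:
    """(mean folding energy of the two conformations, activation energy)."""
    return SwitchFeatures(
        mean_fold_energy=(cp.e1 + cp.e2) / 2.0,
        activation_energy=be.activation_energy,
    )


def features_for_sequence(
    seq: RnaSequence,
    config=None,
    backend=None,
    seed: Optional[int] = None,
    restraints=None,
):
    """End-to-end: predict switch, conformations, barrier, features.

    Returns (ConflictingStemPair or None, SwitchFeatures).  Sequences
    with no detected stem pair get the trivial features (0, 0): no
    alternative structure, no stability, no barrier.
    """
    from .config import RunConfig
    from .conflict import predict_switch
    from .backends import get_backend, sample_ensemble

    cfg = config or RunConfig()
    if backend is None:
        backend = get_backend(cfg.backend)
    ens = sample_ensemble(
        seq,
        n_samples=cfg.n_samples,
        restraints=restraints,
        seed=cfg.sampler_seed if seed is None else seed,
        backend=backend,
    )
    pair = predict_switch(seq, config=cfg, ensemble=ens)
    if pair is None:
        return None, SwitchFeatures(0.0, 0.0)
    cp = predict_conformations(seq, pair, ens, backend=backend, gamma=cfg.mea_gamma)
    be = estimate_barrier(
        seq, cp.conf1, cp.conf2, backend=backend, beam_width=cfg.beam_width,
        keep_path=False,
    )
    return pair, compute_switch_features(cp, be)
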