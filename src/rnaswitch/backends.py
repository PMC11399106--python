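"""Folding backends: Boltzmann sampling, energy evaluation, pseudo-energies.

Two implementations of one contract:

``ExactToyBackend``
    A self-contained backend with an additive energy model of
    -1.0 kcal/mol per canonical pair at kT = 0.6163 kcal/mol (~310 K).
    It computes the partition function exactly by dynamic programming,
    draws i.i.d. structures by stochastic traceback, enumerates all
    structures of short sequences with their exact Boltzmann
    probabilities, and computes exact base-pair probabilities by an
    inside-outside recursion.  Everything downstream of sampling is
    therefore testable against closed forms.

``ViennaBackend``
    A thin adapter over the ViennaRNA nearest-neighbor thermodynamics
    engine (stochastic backtracking from the partition function,
    structure free-energy evaluation, Deigan-style reactivity
    pseudo-energies).

Reactivity restraints enter as per-position pairing penalties
``m*ln(r+1) + b`` and are applied at the sampling step only; energy
evaluation always reports the unrestrained value.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .core import (
    BackendCapacityError,
    ContractViolation,
    FoldEnsemble,
    ReactivityRestraints,
    RnaSequence,
    SecondaryStructure,
    MIN_HAIRPIN_LOOP,
)

DEFAULT_KT = 0.6163  # kcal/mol, ~310 K
DEFAULT_PAIR_ENERGY = -1.0  # kcal/mol per canonical pair (toy model)
DEFAULT_LENGTH_CAP = 30


def reactivity_to_pseudoenergy(restraints: ReactivityRestraints) -> np.ndarray:
    """Per-position pairing penalty in kcal/mol: m*ln(r+1)+b, missing -> 0."""
    pen = np.zeros(len(restraints), dtype=float)
    for i, r in enumerate(restraints.values):
        if r is None:
            continue
        if r < 0:
            raise ContractViolation(f"negative reactivity at position {i}")
        pen[i] = restraints.slope_m * math.log(r + 1.0) + restraints.intercept_b
    return pen


class ExactToyBackend:
    """Exact Boltzmann backend with E = -1 kcal/mol per canonical pair."""

    name = "exact"

    def __init__(
        self,
        kT: float = DEFAULT_KT,
        pair_energy: float = DEFAULT_PAIR_ENERGY,
        length_cap: int = DEFAULT_LENGTH_CAP,
    ) -> None:
        self.kT = kT
        self.pair_energy = pair_energy
        self.length_cap = length_cap

    # -- energy model -------------------------------------------------

    def evaluate_energy(self, seq: RnaSequence, structure: SecondaryStructure) -> float:
        structure.validate(seq)
        return self.pair_energy * len(structure.pairs)

    def _weights(
        self, seq: RnaSequence, restraints: Optional[ReactivityRestraints]
    ) -> np.ndarray:
        """Boltzmann weight per admissible pair, 0 where pairing is illegal."""
        n = len(seq)
        pen = (
            reactivity_to_pseudoenergy(restraints)
            if restraints is not None
            else np.zeros(n)
        )
        if restraints is not None and len(restraints) != n:
            raise ContractViolation(
                f"restraints length {len(restraints)} != sequence length {n}"
            )
        w = np.zeros((n, n), dtype=float)
        for i in range(n):
            for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
                if seq.can_pair(i, j):
                    e = self.pair_energy + pen[i] + pen[j]
                    w[i, j] = math.exp(-e / self.kT)
        return w

    def _check_cap(self, seq: RnaSequence) -> None:
        if len(seq) > self.length_cap:
            raise BackendCapacityError(
                f"backend capacity: sequence {seq.id!r} has {len(seq)} nt, "
                f"exact backend cap is {self.length_cap}"
            )

    def _inside(self, w: np.ndarray) -> np.ndarray:
        """Z[i,j] = partition function of the subsequence i..j (inclusive)."""
        n = w.shape[0]
        Z = np.ones((n + 1, n + 1), dtype=float)  # Z[i, j+1] convention inside
        # use explicit (i, j) inclusive table padded so empty intervals are 1
        z = np.ones((n, n), dtype=float)
        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                total = z[i, j - 1] if j - 1 >= i else 1.0
                for k in range(i, j):
                    if w[k, j] > 0.0:
                        left = z[i, k - 1] if k - 1 >= i else 1.0
                        inner = z[k + 1, j - 1] if k + 1 <= j - 1 else 1.0
                        total += left * w[k, j] * inner
                z[i, j] = total
        return z

    def partition_function(
        self, seq: RnaSequence, restraints: Optional[ReactivityRestraints] = None
    ) -> float:
        self._check_cap(seq)
        w = self._weights(seq, restraints)
        z = self._inside(w)
        return float(z[0, len(seq) - 1]) if len(seq) > 1 else 1.0

    # -- sampling -----------------------------------------------------

    def sample(
        self,
        seq: RnaSequence,
        n_samples: int,
        restraints: Optional[ReactivityRestraints] = None,
        seed: int = 0,
    ) -> list:
        """Draw n i.i.d. structures from the exact Boltzmann distribution."""
        self._check_cap(seq)
        if n_samples < 1:
            raise ContractViolation("n_samples must be >= 1")
        n = len(seq)
        w = self._weights(seq, restraints)
        z = self._inside(w) if n > 1 else np.ones((1, 1))
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_samples):
            pairs = []
            stack = [(0, n - 1)]
            while stack:
                i, j = stack.pop()
                if i >= j:
                    continue
                ztot = z[i, j]
                # choose: j unpaired, or j paired with some k in [i, j)
                u = rng.random() * ztot
                acc = z[i, j - 1] if j - 1 >= i else 1.0
                if u < acc:
                    stack.append((i, j - 1))
                    continue
                chosen = None
                for k in range(i, j):
                    if w[k, j] == 0.0:
                        continue
                    left = z[i, k - 1] if k - 1 >= i else 1.0
                    inner = z[k + 1, j - 1] if k + 1 <= j - 1 else 1.0
                    acc += left * w[k, j] * inner
                    if u < acc:
                        chosen = k
                        break
                if chosen is None:  # numerical edge: fall back to last legal k
                    chosen = max(k for k in range(i, j) if w[k, j] > 0.0)
                pairs.append((chosen, j))
                stack.append((i, chosen - 1))
                stack.append((chosen + 1, j - 1))
            out.append(SecondaryStructure.from_pairs(pairs))
        return out

    # -- exact quantities (oracle surface) ----------------------------

    def enumerate_structures(
        self, seq: RnaSequence, restraints: Optional[ReactivityRestraints] = None
    ) -> list:
        """All valid structures with exact Boltzmann probabilities.

        Returns a list of (SecondaryStructure, probability); probabilities
        sum to 1.
        """
        self._check_cap(seq)
        n = len(seq)
        w = self._weights(seq, restraints)

        memo: dict = {}

        def enum(i: int, j: int) -> list:
            """List of (pairs tuple, weight) for subsequence i..j."""
            if i >= j:
                return [((), 1.0)]
            key = (i, j)
            if key in memo:
                return memo[key]
            res = [(p, wt) for p, wt in enum(i, j - 1)]
            for k in range(i, j):
                if w[k, j] == 0.0:
                    continue
                for pl, wl in enum(i, k - 1):
                    for pi, wi in enum(k + 1, j - 1):
                        res.append((pl + pi + ((k, j),), wl * w[k, j] * wi))
            memo[key] = res
            return res

        raw = enum(0, n - 1)
        total = sum(wt for _, wt in raw)
        return [
            (SecondaryStructure.from_pairs(p), wt / total)
            for p, wt in sorted(raw, key=lambda t: sorted(t[0]))
        ]

    def pair_probabilities(
        self, seq: RnaSequence, restraints: Optional[ReactivityRestraints] = None
    ) -> np.ndarray:
        """Exact base-pair probability matrix via inside-outside recursion."""
        self._check_cap(seq)
        n = len(seq)
        w = self._weights(seq, restraints)
        z = self._inside(w)

        def zin(i: int, j: int) -> float:
            return z[i, j] if i <= j else 1.0

        # O[i, j]: partition over everything outside i..j given (i, j) paired
        O = np.zeros((n, n), dtype=float)
        spans = sorted(
            ((i, j) for i in range(n) for j in range(i + 1, n) if w[i, j] > 0.0),
            key=lambda ij: ij[0] - ij[1],  # decreasing span first
        )
        for i, j in spans:
            val = zin(0, i - 1) * zin(j + 1, n - 1)
            for p in range(0, i):
                for q in range(j + 1, n):
                    if w[p, q] > 0.0:
                        val += w[p, q] * O[p, q] * zin(p + 1, i - 1) * zin(j + 1, q - 1)
            O[i, j] = val
        ztot = zin(0, n - 1)
        P = np.zeros((n, n), dtype=float)
        for i, j in spans:
            P[i, j] = w[i, j] * O[i, j] * zin(i + 1, j - 1) / ztot
        return P


class ViennaBackend:
    """Adapter over the ViennaRNA engine (nearest-neighbor thermodynamics).

    Sampling uses stochastic backtracking from the partition function;
    reactivity restraints are passed through as Deigan-style pseudo-free
    energies with the configured slope/intercept.
    """

    name = "vienna"

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "configuration error: ViennaRNA python bindings not available"
            ) from exc
        self._RNA = __import__("RNA")

    def _fold_compound(
        self, seq: RnaSequence, restraints: Optional[ReactivityRestraints]
    ):
        RNA = self._RNA
        md = RNA.md()
        md.uniq_ML = 1
        fc = RNA.fold_compound(seq.residues, md)
        if restraints is not None:
            if len(restraints) != len(seq):
                raise ContractViolation(
                    f"restraints length {len(restraints)} != sequence length "
                    f"{len(seq)}"
                )
            # ViennaRNA wants a 1-based list; negative marks missing data
            vals = [0.0] + [
                (-999.0 if v is None else float(v)) for v in restraints.values
            ]
            fc.sc_add_SHAPE_deigan(
                vals, restraints.slope_m, restraints.intercept_b
            )
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        fc.pf()
        return fc

    def sample(
        self,
        seq: RnaSequence,
        n_samples: int,
        restraints: Optional[ReactivityRestraints] = None,
        seed: int = 0,
    ) -> list:
        if n_samples < 1:
            raise ContractViolation("n_samples must be >= 1")
        fc = self._fold_compound(seq, restraints)
        self._RNA.init_rand(int(seed))
        dbs = fc.pbacktrack(int(n_samples))
        return [parse_dotbracket(db) for db in dbs]

    def evaluate_energy(self, seq: RnaSequence, structure: SecondaryStructure) -> float:
        structure.validate(seq)
        RNA = self._RNA
        fc = RNA.fold_compound(seq.residues)
        return float(fc.eval_structure(dotbracket(structure, len(seq))))


def dotbracket(structure: SecondaryStructure, n: int) -> str:
    """Render a structure as a dot-bracket string of length n."""
    chars = ["."] * n
    for i, j in structure.pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def parse_dotbracket(db: str) -> SecondaryStructure:
    stack = []
    pairs = []
    for idx, c in enumerate(db):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ContractViolation(f"unbalanced dot-bracket at column {idx}")
            pairs.append((stack.pop(), idx))
        elif c != ".":
            raise ContractViolation(f"bad dot-bracket character {c!r} at {idx}")
    if stack:
        raise ContractViolation("unbalanced dot-bracket: unclosed '('")
    return SecondaryStructure.from_pairs(pairs)


_BACKENDS = {"exact": ExactToyBackend, "vienna": ViennaBackend}


def get_backend(name: str, **kwargs):
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"configuration error: unknown backend {name!r}; "
            f"choose from {sorted(_BACKENDS)}"
        ) from None
    return cls(**kwargs)


def sample_ensemble(
    seq: RnaSequence,
    n_samples: int = 1000,
    restraints: Optional[ReactivityRestraints] = None,
    seed: int = 0,
    backend=None,
) -> FoldEnsemble:
    """Draw a Boltzmann ensemble of *n_samples* structures for *seq*.

    The same (sequence, n, restraints, seed, backend) always yields a
    bit-identical ensemble.  Energies are the backend's unrestrained
    free energies for each sampled structure.
    """
    if backend is None:
        backend = ExactToyBackend()
    structures = backend.sample(seq, n_samples, restraints=restraints, seed=seed)
    energies = [backend.evaluate_energy(seq, s) for s in structures]
    return FoldEnsemble(
        sequence=seq, structures=structures, energies=energies, sampler_seed=seed
    )
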