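"""Core domain objects shared by every stage of the switch-discovery pipeline.

The pipeline operates on RNA sequences, pseudoknot-free secondary
structures, Boltzmann-sampled structure ensembles, and the stem /
stem-pair objects that describe a candidate bi-stable switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

ALPHABET = frozenset("ACGU")
#: canonical base pairs (Watson-Crick plus wobble)
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
#: minimum number of unpaired nucleotides enclosed by a hairpin
MIN_HAIRPIN_LOOP = 3

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class ContractViolation(ValueError):
    """An input object breaks one of the documented invariants."""


class BackendCapacityError(RuntimeError):
    """Sequence exceeds what the configured folding backend can handle."""


def reverse_complement(residues: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(residues))


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U}.

    DNA input is accepted via :meth:`from_string`, which maps T to U.
    Ambiguity codes are rejected by default, or mapped to ``N`` (forced
    unpaired in every backend) when ``ambiguous_as_unpaired`` is set.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ContractViolation(f"sequence {self.id!r}: empty sequence")
        bad = set(self.residues) - ALPHABET - {"N"}
        if bad:
            raise ContractViolation(
                f"sequence {self.id!r}: non-ACGU residues {sorted(bad)}"
            )

    @classmethod
    def from_string(
        cls, id: str, raw: str, ambiguous_as_unpaired: bool = False
    ) -> "RnaSequence":
        s = raw.strip().upper().replace("T", "U")
        if ambiguous_as_unpaired:
            s = "".join(c if c in ALPHABET else "N" for c in s)
        return cls(id=id, residues=s)

    def __len__(self) -> int:
        return len(self.residues)

    def can_pair(self, i: int, j: int) -> bool:
        """Whether positions i < j may form a canonical pair with a legal loop."""
        if j - i < MIN_HAIRPIN_LOOP + 1:
            return False
        return (self.residues[i], self.residues[j]) in CANONICAL_PAIRS


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs, 0-based, i < j in every pair."""

    pairs: frozenset = frozenset()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "SecondaryStructure":
        return cls(frozenset((int(i), int(j)) for i, j in pairs))

    def validate(self, seq: RnaSequence) -> None:
        """Raise ContractViolation unless every invariant holds for *seq*."""
        n = len(seq)
        seen: set = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ContractViolation(f"pair {(i, j)} out of range for n={n}")
            if j - i < MIN_HAIRPIN_LOOP + 1:
                raise ContractViolation(f"pair {(i, j)} closes a loop shorter than 3")
            if not seq.can_pair(i, j):
                raise ContractViolation(
                    f"pair {(i, j)} is non-canonical: "
                    f"{seq.residues[i]}-{seq.residues[j]}"
                )
            for k in (i, j):
                if k in seen:
                    raise ContractViolation(f"position {k} paired twice")
                seen.add(k)
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            ia, ja = plist[a]
            for b in range(a + 1, len(plist)):
                ib, jb = plist[b]
                if ia < ib < ja < jb:
                    raise ContractViolation(
                        f"crossing pairs {(ia, ja)} and {(ib, jb)}"
                    )

    def partner_array(self, n: int) -> list:
        """Partner index per position, -1 when unpaired."""
        partner = [-1] * n
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        return partner

    def paired_positions(self) -> frozenset:
        return frozenset(k for ij in self.pairs for k in ij)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class FoldEnsemble:
    """A Boltzmann sample of N structures for one sequence."""

    sequence: RnaSequence
    structures: list
    energies: Optional[list] = None
    sampler_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.structures) < 1:
            raise ContractViolation("ensemble must contain at least one structure")
        if self.energies is not None and len(self.energies) != len(self.structures):
            raise ContractViolation("energies do not align 1:1 with structures")

    @property
    def n(self) -> int:
        return len(self.structures)


@dataclass
class ReactivityRestraints:
    """Per-position chemical reactivities plus the pseudo-energy parameters.

    ``values[i]`` is a nonnegative reactivity or None (missing = no
    restraint).  The pseudo-energy applied to a paired position i is
    ``slope_m * ln(values[i] + 1) + intercept_b`` kcal/mol.
    """

    values: list
    slope_m: float = 1.8
    intercept_b: float = -0.6

    def __post_init__(self) -> None:
        for i, v in enumerate(self.values):
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ContractViolation(
                    f"reactivity at position {i} is negative or non-finite: {v}"
                )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Stem:
    """A helix: a run of stacked base pairs (u+t, y-t), t = 0..length-1.

    Stored as the interval pair ((u, v), (x, y)), 0-based inclusive,
    with v - u == y - x and u <= v < x <= y.
    """

    intervals: tuple  # ((u, v), (x, y))

    def __post_init__(self) -> None:
        (u, v), (x, y) = self.intervals
        if not (u <= v < x <= y):
            raise ContractViolation(f"malformed stem intervals {self.intervals}")
        if v - u != y - x:
            raise ContractViolation(f"unequal stem arms {self.intervals}")

    @property
    def length(self) -> int:
        (u, v), _ = self.intervals
        return v - u + 1

    @property
    def pairs(self) -> tuple:
        (u, v), (x, y) = self.intervals
        return tuple((u + t, y - t) for t in range(self.length))

    def positions(self) -> frozenset:
        (u, v), (x, y) = self.intervals
        return frozenset(range(u, v + 1)) | frozenset(range(x, y + 1))


@dataclass
class ConflictingStemPair:
    """Two mutually exclusive stems: the core object of a switch prediction."""

    stem1: Stem
    stem2: Stem
    score: float
    overlap_len: int

    def as_dict(self) -> dict:
        return {
            "stem1": [list(self.stem1.intervals[0]), list(self.stem1.intervals[1])],
            "stem2": [list(self.stem2.intervals[0]), list(self.stem2.intervals[1])],
            "score": self.score,
            "overlap_len": self.overlap_len,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConflictingStemPair":
        mk = lambda iv: Stem(((iv[0][0], iv[0][1]), (iv[1][0], iv[1][1])))
        return cls(
            stem1=mk(d["stem1"]),
            stem2=mk(d["stem2"]),
            score=float(d["score"]),
            overlap_len=int(d["overlap_len"]),
        )


@dataclass
class ConformationPair:
    """The two predicted conformations of a candidate switch."""

    conf1: SecondaryStructure
    conf2: SecondaryStructure
    e1: float
    e2: float
    constraint_stems: tuple  # (Stem, Stem)


@dataclass
class BarrierEstimate:
    """Upper-bound estimate of the refolding activation barrier (kcal/mol)."""

    activation_energy: float
    path: Optional[list] = None
    method: str = "beam"


@dataclass(frozen=True)
class SwitchFeatures:
    """The two classifier features of a candidate switch."""

    mean_fold_energy: float
    activation_energy: float

    def as_vector(self) -> tuple:
        return (self.mean_fold_energy, self.activation_energy)
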