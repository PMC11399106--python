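"""Two-feature switch classifier, LOFO evaluation, and long-sequence scanning.

The classifier is a literal least-squares fit of the binary label
(real switch vs shuffled counterpart) on (mean folding energy,
activation energy).  Scores are only ever used for ranking and ROC
curves, where any monotone link gives identical results, so the linear
probability model is adequate for the task.

Negatives are dinucleotide-preserving shuffles (Altschul-Erickson
Eulerian-walk shuffle), evaluation is leave-one-family-out, and long
sequences are scanned as overlapping fragments (default 186 nt with
93 nt overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from .core import ContractViolation, RnaSequence, SwitchFeatures


@dataclass(frozen=True)
class LabeledExample:
    features: SwitchFeatures
    label: int  # 1 = real switch, 0 = shuffled
    family: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ContractViolation(f"label must be 0/1, got {self.label}")
        if not self.family:
            raise ContractViolation("family must be nonempty")


@dataclass
class SwitchClassifier:
    intercept: float
    w_energy: float
    w_barrier: float

    def score(self, features: SwitchFeatures) -> float:
        return (
            self.intercept
            + self.w_energy * features.mean_fold_energy
            + self.w_barrier * features.activation_energy
        )

    def as_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "w_energy": self.w_energy,
            "w_barrier": self.w_barrier,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SwitchClassifier":
        return cls(
            intercept=float(d["intercept"]),
            w_energy=float(d["w_energy"]),
            w_barrier=float(d["w_barrier"]),
        )


@dataclass
class RocResult:
    auc: Optional[float]  # None when undefined (single-class family)
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class Fragment:
    parent_id: str
    start: int  # 0-based half-open
    end: int
    sequence: RnaSequence


def dinucleotide_shuffle(seq: RnaSequence, seed: int = 0) -> RnaSequence:
    """Uniform random shuffle preserving exact dinucleotide counts.

    Altschul-Erickson: pick, for each residue type except the terminal
    one, a random outgoing edge whose choices form an arborescence into
    the terminal residue (sampled by Wilson's loop-erased random walk),
    shuffle all remaining edges, and walk the Eulerian path.  The first
    and last residues are preserved.
    """
    s = seq.residues
    if len(s) < 2:
        return RnaSequence(id=f"{seq.id}_shuf", residues=s)
    rng = np.random.default_rng(seed)
    edges: dict = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = sorted(edges)  # vertices with out-edges

    # Wilson's algorithm: random arborescence of last-edges rooted at `last`
    def random_step(v: str) -> str:
        outs = edges[v]
        return outs[rng.integers(len(outs))]

    in_tree = {last}
    last_edge: dict = {}
    for v in vertices:
        if v in in_tree:
            continue
        walk = [v]
        pos = {v: 0}
        cur = v
        while cur not in in_tree:
            nxt = random_step(cur)
            if nxt in pos:  # erase the loop
                walk = walk[: pos[nxt] + 1]
                pos = {u: k for k, u in enumerate(walk)}
            else:
                walk.append(nxt)
                pos[nxt] = len(walk) - 1
            cur = walk[-1]
        for a, b in zip(walk, walk[1:]):
            last_edge[a] = b
            in_tree.add(a)

    out_lists: dict = {}
    for v in vertices:
        outs = list(edges[v])
        if v in last_edge:
            outs.remove(last_edge[v])
        perm = rng.permutation(len(outs))
        shuffled = [outs[k] for k in perm]
        if v in last_edge:
            shuffled.append(last_edge[v])
        out_lists[v] = shuffled

    result = [s[0]]
    counters = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = out_lists[cur][counters[cur]]
        counters[cur] += 1
        result.append(nxt)
        cur = nxt
    return RnaSequence(id=f"{seq.id}_shuf", residues="".join(result))


def fit_switch_classifier(examples: list) -> SwitchClassifier:
    """OLS of the binary label on the two switch features."""
    labels = {e.label for e in examples}
    if labels != {0, 1}:
        raise ContractViolation("training set must contain both classes")
    X = np.array(
        [[1.0, e.features.mean_fold_energy, e.features.activation_energy]
         for e in examples]
    )
    y = np.array([float(e.label) for e in examples])
    if np.linalg.matrix_rank(X) < 3:
        raise ContractViolation("degenerate input: singular design matrix")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return SwitchClassifier(
        intercept=float(coef[0]), w_energy=float(coef[1]), w_barrier=float(coef[2])
    )


def roc_auc(scores, labels) -> RocResult:
    """AUC = Mann-Whitney U / (n_pos * n_neg), ties at half credit."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        return RocResult(auc=None, n_pos=n_pos, n_neg=n_neg)
    return RocResult(
        auc=float(roc_auc_score(labels, scores)), n_pos=n_pos, n_neg=n_neg
    )


def evaluate_lofo(examples: list) -> dict:
    """Leave-one-family-out ROC: family -> RocResult."""
    families = sorted({e.family for e in examples})
    if len(families) < 2:
        raise ContractViolation("LOFO needs at least 2 families")
    out = {}
    for fam in families:
        train = [e for e in examples if e.family != fam]
        test = [e for e in examples if e.family == fam]
        model = fit_switch_classifier(train)
        scores = [model.score(e.features) for e in test]
        labels = [e.label for e in test]
        out[fam] = roc_auc(scores, labels)
    return out


def fragment_sequences(
    seqs: list, frag_len: int = 186, overlap: int = 93
) -> list:
    """Overlapping windows over each sequence.

    Windows start at 0 with stride frag_len - overlap; when the final
    stride leaves a remainder, a last full-length window anchored at the
    3' end is added so every nucleotide is covered.  Sequences shorter
    than frag_len yield a single whole-sequence fragment.
    """
    if not frag_len > overlap >= 0:
        raise ContractViolation("need frag_len > overlap >= 0")
    stride = frag_len - overlap
    out = []
    for seq in seqs:
        n = len(seq)
        if n <= frag_len:
            out.append(Fragment(seq.id, 0, n, seq))
            continue
        starts = list(range(0, n - frag_len + 1, stride))
        tail = n - frag_len
        if starts[-1] != tail:
            starts.append(tail)
        for st in starts:
            sub = RnaSequence(
                id=f"{seq.id}:{st}-{st + frag_len}",
                residues=seq.residues[st : st + frag_len],
            )
            out.append(Fragment(seq.id, st, st + frag_len, sub))
    return out


@dataclass
class RankedFragment:
    fragment: Fragment
    score: float
    stem_pair: object  # ConflictingStemPair
    features: SwitchFeatures


def rank_fragments(
    fragments: list,
    model: SwitchClassifier,
    config=None,
    top_k: Optional[int] = None,
    backend=None,
    seed: Optional[int] = None,
) -> list:
    """Score every fragment through the full pipeline; top_k by score.

    Fragments in which no conflicting stem pair is detected are
    excluded.  Ties break by (parent_id, start).
    """
    from .conformations import features_for_sequence

    if top_k is not None and top_k <= 0:
        raise ContractViolation(f"top_k must be positive, got {top_k}")
    scored = []
    for frag in fragments:
        pair, feats = features_for_sequence(
            frag.sequence, config=config, backend=backend, seed=seed
        )
        if pair is None:
            continue
        scored.append(
            RankedFragment(
                fragment=frag,
                score=model.score(feats),
                stem_pair=pair,
                features=feats,
            )
        )
    scored.sort(key=lambda r: (-r.score, r.fragment.parent_id, r.fragment.start))
    return scored if top_k is None else scored[:top_k]
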