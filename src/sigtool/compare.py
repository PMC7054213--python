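"""Signature comparison: cosine similarity, optimal matching, set separation.

The separation of a signature set is summarised by the distribution of
pairwise cosine similarities between its profiles: the lower the median,
the more distinguishable the signatures are, and the less attribution can
"bleed" between them.  Two sets are compared signature-to-signature by a
globally optimal one-to-one assignment (Hungarian algorithm on cosine
similarities), and two separation distributions by a rank-based
two-sample shift test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import mannwhitneyu

from .extraction import SignatureSet


def cosine(u, v) -> float:
    """Cosine similarity of two nonnegative vectors (in [0, 1], scale invariant)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class SignatureMatch:
    pairs: list[tuple[str, str, float]]  # (name in A, name in B, cosine)
    unmatched_a: list[str]
    unmatched_b: list[str]
    total_cosine: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["a", "b", "cosine"])


def match_signatures(A: SignatureSet, B: SignatureSet) -> SignatureMatch:
    """One-to-one assignment between two signature sets maximising total cosine.

    Rectangular inputs are allowed; the surplus signatures of the larger
    set are left unassigned.  Ties are broken deterministically by index
    order (the assignment solver is deterministic on the cost matrix).
    """
    if A.schema.name != B.schema.name:
        raise ValueError(
            f"schema mismatch: {A.schema.name} vs {B.schema.name}"
        )
    Wa, Wb = A.W, B.W
    sim = np.zeros((Wa.shape[1], Wb.shape[1]))
    for i in range(Wa.shape[1]):
        for j in range(Wb.shape[1]):
            sim[i, j] = cosine(Wa[:, i], Wb[:, j])
    rows, cols = linear_sum_assignment(-sim)
    pairs = [(A.names[i], B.names[j], float(sim[i, j])) for i, j in zip(rows, cols)]
    pairs.sort(key=lambda p: A.names.index(p[0]))
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    return SignatureMatch(
        pairs=pairs,
        unmatched_a=[n for n in A.names if n not in matched_a],
        unmatched_b=[n for n in B.names if n not in matched_b],
        total_cosine=float(sim[rows, cols].sum()),
    )


@dataclass
class SetSeparation:
    pairwise: pd.Series  # indexed by (name_i, name_j) pairs
    median: float


def set_separation(S: SignatureSet) -> SetSeparation:
    """All C(n, 2) pairwise cosines within a set, plus their median."""
    if len(S) < 2:
        raise ValueError("set separation needs at least 2 signatures")
    W = S.W
    vals = {}
    for i, j in combinations(range(len(S)), 2):
        vals[(S.names[i], S.names[j])] = cosine(W[:, i], W[:, j])
    series = pd.Series(vals)
    return SetSeparation(pairwise=series, median=float(series.median()))


def separation_shift_test(
    sims_a, sims_b, method: str = "mannwhitney", n_permutations: int = 10_000, seed: int = 0
) -> float:
    """Two-sided p-value for a location shift between two cosine distributions.

    Default is the Mann-Whitney U test (normal approximation with tie
    correction); ``method="permutation"`` runs a seeded permutation test on
    the difference of means instead.
    """
    a = np.asarray(sims_a, dtype=float).ravel()
    b = np.asarray(sims_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both similarity lists must be nonempty")
    if method == "mannwhitney":
        return float(
            mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    if method == "permutation":
        rng = np.random.default_rng(seed)
        observed = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            if abs(pooled[: a.size].mean() - pooled[a.size :].mean()) >= observed:
                hits += 1
        return (hits + 1) / (n_permutations + 1)
    raise ValueError("method must be 'mannwhitney' or 'permutation'")
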