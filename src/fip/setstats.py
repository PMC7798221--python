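"""Compound-set comparison statistics: Jaccard overlap between InChIKey
sets and exhaustive-sample average pairwise Tanimoto similarity."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .featurize import FeatureVector, FingerprintSpec, stack_vectors


class SetStatsError(ValueError):
    pass


@dataclass(frozen=True)
class OverlapReport:
    """Exact set overlap between two deduplicated compound collections."""

    size_a: int
    size_b: int
    intersection: int
    jaccard: float


@dataclass(frozen=True)
class TanimotoSummary:
    """Mean Tanimoto over all unordered pairs of a random sample.

    n_pairs is always n_sampled * (n_sampled - 1) / 2 — the enumeration
    is exhaustive over the sample. rng_name records the generator so runs
    are repeatable from (rng_name, seed).
    """

    n_sampled: int
    n_pairs: int
    mean_tc: float
    seed: int
    spec: FingerprintSpec
    rng_name: str = "numpy.random.Generator(PCG64)"


def jaccard_overlap(keys_a: Iterable[str], keys_b: Iterable[str]) -> OverlapReport:
    """J(A, B) = |A ∩ B| / |A ∪ B| over InChIKey sets."""
    a, b = set(keys_a), set(keys_b)
    if not a and not b:
        raise SetStatsError("both key sets are empty")
    inter = len(a & b)
    union = len(a) + len(b) - inter
    return OverlapReport(
        size_a=len(a), size_b=len(b), intersection=inter, jaccard=inter / union
    )


def tanimoto(a: FeatureVector, b: FeatureVector) -> float:
    """|a ∧ b| / |a ∨ b|; zero for a pair of all-zero vectors."""
    if a.spec != b.spec:
        raise SetStatsError(f"fingerprint spec mismatch: {a.spec} vs {b.spec}")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    return inter / union if union else 0.0


def avg_pairwise_tanimoto(
    vectors: Sequence[FeatureVector], sample_n: int, seed: int
) -> TanimotoSummary:
    """Sample `sample_n` compounds without replacement, enumerate all
    unordered pairs exhaustively and average their Tanimoto coefficients.

    Pairwise intersections come from one Gram matrix X X^T; unions follow
    from popcounts, so a 5000-compound sample (12,497,500 pairs) stays in
    dense linear algebra.
    """
    mat, spec, _ = stack_vectors(vectors)
    n = mat.shape[0]
    if sample_n > n:
        raise SetStatsError(f"sample_n {sample_n} exceeds population {n}")
    if sample_n < 2:
        raise SetStatsError("need at least two sampled compounds for a pair")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=sample_n, replace=False)
    x = mat[idx].astype(np.float32)
    inter = x @ x.T
    pop = x.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    iu = np.triu_indices(sample_n, k=1)
    inter_u = inter[iu]
    union_u = union[iu]
    tc = np.divide(
        inter_u, union_u, out=np.zeros_like(inter_u), where=union_u > 0
    )
    n_pairs = sample_n * (sample_n - 1) // 2
    assert tc.size == n_pairs
    return TanimotoSummary(
        n_sampled=sample_n,
        n_pairs=n_pairs,
        mean_tc=float(tc.mean()),
        seed=seed,
        spec=spec,
    )
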