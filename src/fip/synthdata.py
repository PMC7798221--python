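"""Synthetic binary feature vectors with planted pairwise co-occurrence.

The generator draws compounds as independent Bernoulli feature columns,
except for designated *planted pairs* (i, j, e) which are sampled jointly
from the 2×2 table with the requested marginals and joint on-probability
e · p_i · p_j. By construction the population PMI of a planted pair is
exactly log2(e), so every estimator in the package can be checked against
a known ground truth without any chemistry.

`scramble_columns` independently permutes each feature column across
compounds: marginals are conserved exactly while all co-occurrence
structure is destroyed — the standard surrogate for a structurally
incoherent ("hard") compound set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .featurize import FeatureVector, FingerprintSpec, stack_vectors, vectors_from_matrix


class SynthError(ValueError):
    pass


def synthetic_spec(n_features: int) -> FingerprintSpec:
    """Fingerprint spec for chemistry-free synthetic vectors (ecfp-shaped)."""
    return FingerprintSpec("ecfp", n_features, 2)


@dataclass(frozen=True)
class SyntheticDesign:
    """Specification of a synthetic compound set.

    n_features : vector length D
    marginals : per-feature on-probability p_i in (0, 1)
    planted_pairs : (i, j, e) triples; e is the co-occurrence enrichment,
        joint on-probability e·p_i·p_j, hence population PMI = log2 e.
        Pairs must be feature-disjoint so the joint law stays exactly
        specifiable.
    """

    n_features: int
    marginals: tuple
    planted_pairs: tuple = ()
    n_compounds: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.marginals, dtype=float)
        if p.size != self.n_features:
            raise SynthError("marginals length must equal n_features")
        if np.any((p <= 0) | (p >= 1)):
            raise SynthError("marginals must lie strictly in (0, 1)")
        used: set = set()
        for i, j, e in self.planted_pairs:
            if i == j or not (0 <= i < self.n_features) or not (0 <= j < self.n_features):
                raise SynthError(f"invalid planted pair ({i}, {j})")
            if i in used or j in used:
                raise SynthError("planted pairs must be feature-disjoint")
            used.update((i, j))
            if e <= 0:
                raise SynthError("enrichment must be positive")
            p11 = e * p[i] * p[j]
            if p11 > min(p[i], p[j]) + 1e-12:
                raise SynthError(
                    f"infeasible pair ({i},{j}): joint {p11:.4f} exceeds min marginal"
                )
            if 1 - p[i] - p[j] + p11 < -1e-12:
                raise SynthError(
                    f"infeasible pair ({i},{j}): negative 00-cell probability"
                )

    @classmethod
    def uniform(
        cls,
        n_features: int,
        p: float,
        planted_pairs: Sequence[tuple] = (),
        n_compounds: int = 1000,
        seed: int = 0,
    ) -> "SyntheticDesign":
        return cls(
            n_features=n_features,
            marginals=tuple([p] * n_features),
            planted_pairs=tuple(planted_pairs),
            n_compounds=n_compounds,
            seed=seed,
        )


def generate_matrix(design: SyntheticDesign) -> np.ndarray:
    """Draw the (n_compounds, n_features) binary matrix of a design."""
    rng = np.random.default_rng(design.seed)
    p = np.asarray(design.marginals, dtype=float)
    n, d = design.n_compounds, design.n_features
    mat = (rng.random((n, d)) < p[None, :]).astype(np.uint8)
    for i, j, e in design.planted_pairs:
        p11 = e * p[i] * p[j]
        p10 = p[i] - p11
        p01 = p[j] - p11
        # categorical draw over the 2x2 table (11, 10, 01, 00)
        u = rng.random(n)
        mat[:, i] = (u < p11 + p10).astype(np.uint8)
        mat[:, j] = ((u < p11) | ((u >= p11 + p10) & (u < p11 + p10 + p01))).astype(
            np.uint8
        )
    return mat


def generate(design: SyntheticDesign, id_prefix: str = "synth") -> list[FeatureVector]:
    """Materialize a design as FeatureVectors (reproducible from its seed)."""
    mat = generate_matrix(design)
    spec = synthetic_spec(design.n_features)
    ids = [f"{id_prefix}{k}" for k in range(design.n_compounds)]
    return vectors_from_matrix(mat, spec, ids)


def scramble_columns(
    vectors: Sequence[FeatureVector], seed: int
) -> list[FeatureVector]:
    """Independently permute every feature column across compounds.

    Column popcounts (marginals) are preserved exactly; pairwise
    co-occurrence structure is destroyed, restoring independence.
    """
    mat, spec, ids = stack_vectors(vectors)
    rng = np.random.default_rng(seed)
    out = mat.copy()
    for col in range(mat.shape[1]):
        out[:, col] = mat[rng.permutation(mat.shape[0]), col]
    return vectors_from_matrix(out, spec, ids)
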