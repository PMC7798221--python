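"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's vectorized paths: CORM by a
nested loop over compounds and feature pairs, PMI by direct evaluation of
the defining formula, AUC by Mann-Whitney pair counting, and the Youden
threshold by exhaustive scan. Tests compare the implementation against
these.
"""

import math
from importlib import resources

import numpy as np
import pytest

from fip.featurize import FeatureVector, vectors_from_matrix
from fip.relmat import accumulate_corm, corm_to_coprm, coprm_to_pmirm, pmirm_to_zpmirm
from fip.synthdata import synthetic_spec

#: the hand-worked 4-compound, 3-feature set used throughout
WORKED_SET = np.array([[1, 1, 0], [1, 1, 0], [1, 0, 1], [0, 0, 1]], dtype=np.uint8)


# --- independent oracles ----------------------------------------------------


def brute_corm(mat: np.ndarray) -> np.ndarray:
    """Naive pair counter: loop over compounds and all feature pairs."""
    n, d = mat.shape
    out = np.zeros((d, d), dtype=np.int64)
    for o in range(n):
        for i in range(d):
            if mat[o, i]:
                for j in range(d):
                    if mat[o, j]:
                        out[i, j] += 1
    return out


def brute_pmi(p_ij: float, p_i: float, p_j: float) -> float:
    return math.log2(p_ij / (p_i * p_j))


def brute_mean_product(coprm, ref_values, ref_mask, missing=0.0) -> float:
    """Cell-by-cell Hadamard mean with the undefined-cell convention."""
    d = coprm.shape[0]
    total = 0.0
    for i in range(d):
        for j in range(d):
            r = ref_values[i, j] if ref_mask[i, j] else missing
            total += coprm[i, j] * r
    return total / (d * d)


def brute_auc(es_scores, hs_scores) -> float:
    """Mann-Whitney probability over all ES x HS pairs, ties 0.5."""
    wins = 0.0
    for e in es_scores:
        for h in hs_scores:
            if e > h:
                wins += 1.0
            elif e == h:
                wins += 0.5
    return wins / (len(es_scores) * len(hs_scores))


def brute_youden(scores, is_es):
    """Exhaustive Youden scan; candidates are midpoints of consecutive
    distinct scores plus the infinities; lowest maximizer wins."""
    scores = np.asarray(scores, dtype=float)
    is_es = np.asarray(is_es, dtype=bool)
    distinct = np.unique(scores)
    candidates = [-np.inf] + [
        (a + b) / 2 for a, b in zip(distinct[:-1], distinct[1:])
    ] + [np.inf]
    best_thr, best_j = None, -np.inf
    for thr in candidates:
        pred = scores >= thr
        sn = (pred & is_es).sum() / is_es.sum()
        sp = (~pred & ~is_es).sum() / (~is_es).sum()
        j = sn + sp - 1
        if j > best_j + 1e-12:
            best_thr, best_j = thr, j
    return best_thr, best_j


def random_binary_set(rng, max_d=16, max_n=50):
    d = rng.integers(2, max_d + 1)
    n = rng.integers(1, max_n + 1)
    density = rng.uniform(0.1, 0.9)
    return (rng.random((n, d)) < density).astype(np.uint8)


# --- fixtures ---------------------------------------------------------------


@pytest.fixture
def worked_vectors() -> list[FeatureVector]:
    return vectors_from_matrix(WORKED_SET, synthetic_spec(3))


@pytest.fixture
def worked_chain(worked_vectors):
    corm = accumulate_corm(worked_vectors, provenance="worked")
    coprm = corm_to_coprm(corm)
    pmirm = coprm_to_pmirm(coprm)
    zpmirm = pmirm_to_zpmirm(pmirm)
    return corm, coprm, pmirm, zpmirm


@pytest.fixture(scope="session")
def smiles_fixture(tmp_path_factory) -> str:
    text = resources.files("fip.data").joinpath("druglike40.smi").read_text()
    path = tmp_path_factory.mktemp("smi") / "druglike40.smi"
    path.write_text(text)
    return str(path)
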