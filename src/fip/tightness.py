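"""Relative feature tightness: RFT and its Z-standardized form ZRFT.

RFT(S, S') = mean( COPRM(S) ∘ PMIRM(S') ) — the element-wise (Hadamard)
product of the query set's co-occurrence probabilities with the reference
set's interrelation profile, averaged over the matrix. ZRFT substitutes
the standardized reference ZPMIRM. Neither is symmetric in (S, S'), so
neither is a metric.

Averaging conventions (both recorded on every score):

* ``mean_over="all"`` (default): the denominator is D^2 regardless of how
  many reference cells are defined, so scores are comparable across
  queries; ``"defined"`` divides by the count of defined reference cells.
* ``missing_pair`` (default 0.0): the value substituted for reference
  cells with undefined PMI/Z; it is weighted by the query co-occurrence
  probability like any other cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .featurize import FeatureVector, stack_vectors
from .relmat import RelationMatrix, RelationMatrixError


class TightnessError(ValueError):
    pass


@dataclass(frozen=True)
class TightnessScore:
    value: float
    standardized: bool  # False = RFT, True = ZRFT
    query_size: int
    reference_label: str
    convention_flags: tuple  # (("mean_over", ...), ("missing_pair", ...))


def _reference_arrays(
    reference: RelationMatrix, standardized: bool
) -> tuple[np.ndarray, np.ndarray]:
    want = "zpmirm" if standardized else "pmirm"
    if reference.variant != want:
        raise TightnessError(
            f"reference must be a {want}, got {reference.variant}"
        )
    if reference.defined_mask is None:
        raise RelationMatrixError("reference lacks a defined_mask")
    return reference.values, reference.defined_mask


def _query_coprm(vectors: Iterable[FeatureVector], reference: RelationMatrix):
    mat, spec, ids = stack_vectors(vectors)
    if spec != reference.spec:
        raise TightnessError(
            f"fingerprint spec mismatch: query {spec} vs reference {reference.spec}"
        )
    x = mat.astype(np.float64)
    return (x.T @ x) / mat.shape[0], mat.shape[0], ids


def _mean_product(
    coprm: np.ndarray,
    ref_values: np.ndarray,
    ref_mask: np.ndarray,
    mean_over: str,
    missing_pair: float,
) -> float:
    ref = np.where(ref_mask, ref_values, missing_pair)
    total = float((coprm * ref).sum())
    if mean_over == "all":
        denom = coprm.size
    elif mean_over == "defined":
        denom = int(ref_mask.sum())
        if denom == 0:
            raise TightnessError("reference has no defined cells")
    else:
        raise TightnessError(f"unknown mean_over convention {mean_over!r}")
    return total / denom


def rft(
    query: Iterable[FeatureVector],
    reference: RelationMatrix,
    mean_over: str = "all",
    missing_pair: float = 0.0,
) -> TightnessScore:
    """Tightness of a query compound (set) against a reference PMI profile.

    Covers all three query/reference cases: a single-compound query, a
    set-vs-set comparison, and the inner tightness RFT(S, S).
    """
    ref_values, ref_mask = _reference_arrays(reference, standardized=False)
    coprm, n, _ = _query_coprm(query, reference)
    value = _mean_product(coprm, ref_values, ref_mask, mean_over, missing_pair)
    return TightnessScore(
        value=value,
        standardized=False,
        query_size=n,
        reference_label=reference.provenance,
        convention_flags=(("mean_over", mean_over), ("missing_pair", missing_pair)),
    )


def zrft(
    query: Iterable[FeatureVector],
    reference: RelationMatrix,
    mean_over: str = "all",
    missing_pair: float = 0.0,
) -> TightnessScore:
    """Tightness against a Z-standardized reference profile.

    Positive values mean the query's feature pairs are rated above the
    reference profile's average interrelation strength.
    """
    ref_values, ref_mask = _reference_arrays(reference, standardized=True)
    coprm, n, _ = _query_coprm(query, reference)
    value = _mean_product(coprm, ref_values, ref_mask, mean_over, missing_pair)
    return TightnessScore(
        value=value,
        standardized=True,
        query_size=n,
        reference_label=reference.provenance,
        convention_flags=(("mean_over", mean_over), ("missing_pair", missing_pair)),
    )


def zrft_per_compound(
    queries: Iterable[FeatureVector],
    reference: RelationMatrix,
    mean_over: str = "all",
    missing_pair: float = 0.0,
) -> pd.DataFrame:
    """Singleton-set ZRFT of every query compound.

    For one compound k the query COPRM is exactly the outer product
    k k^T, so the score is the quadratic form k^T Z k over the (filled)
    reference, divided by the cell count. Vectorized over compounds.

    Returns a DataFrame with columns (compound_id, zrft).
    """
    ref_values, ref_mask = _reference_arrays(reference, standardized=True)
    mat, spec, ids = stack_vectors(queries)
    if spec != reference.spec:
        raise TightnessError(
            f"fingerprint spec mismatch: query {spec} vs reference {reference.spec}"
        )
    ref = np.where(ref_mask, ref_values, missing_pair)
    if mean_over == "all":
        denom = ref.size
    elif mean_over == "defined":
        denom = int(ref_mask.sum())
        if denom == 0:
            raise TightnessError("reference has no defined cells")
    else:
        raise TightnessError(f"unknown mean_over convention {mean_over!r}")
    x = mat.astype(np.float64)
    scores = np.einsum("nd,de,ne->n", x, ref, x) / denom
    return pd.DataFrame({"compound_id": ids, "zrft": scores})
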