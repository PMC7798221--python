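"""The four relation matrices: CORM, COPRM, PMIRM and ZPMIRM.

A compound set S encoded as binary feature vectors k_o induces:

* CORM(S)   = sum_o k_o k_o^T          — integer co-occurrence counts,
* COPRM(S)  = CORM(S) / |S|            — co-occurrence probabilities,
* PMIRM(S)  = log2 p_ij / (p_ii p_jj)  — pointwise mutual information of
  every feature pair (the set's interrelation profile),
* ZPMIRM(S) — PMIRM standardized to Z-scores.

Conventions (documented in docs/methods.md): the PMIRM diagonal of
observed features is zero by definition; pairs with zero co-occurrence
probability are undefined (masked NaN), never smoothed; Z-standardization
uses the population mean/sd of the defined off-diagonal cells only.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .featurize import FeatureVector, FingerprintSpec, TOOLKIT, stack_vectors

VARIANTS = ("corm", "coprm", "pmirm", "zpmirm")

FORMAT_VERSION = 1

#: rows per dense accumulation block; bounds memory at D * 65536 bytes
_BLOCK = 65536


class RelationMatrixError(ValueError):
    pass


class DegenerateProfileError(RelationMatrixError):
    """All defined PMI values are equal: sigma = 0, no Z-scores exist."""


@dataclass
class RelationMatrix:
    """Symmetric feature x feature relation matrix with provenance.

    values : (D, D) array — counts (corm), probabilities (coprm), PMI
        (pmirm) or Z-scores (zpmirm). Undefined cells hold NaN.
    defined_mask : boolean (D, D) array for pmirm/zpmirm; None otherwise.
    standardization_stats : (mu, sigma) used for zpmirm.
    """

    values: np.ndarray
    variant: str
    set_size: int
    spec: FingerprintSpec
    defined_mask: Optional[np.ndarray] = None
    standardization_stats: Optional[tuple] = None
    provenance: str = ""
    toolkit: str = TOOLKIT

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise RelationMatrixError(f"unknown variant {self.variant!r}")
        self.values = np.asarray(self.values)
        d = self.values.shape
        if len(d) != 2 or d[0] != d[1]:
            raise RelationMatrixError("relation matrix must be square")
        if d[0] != self.spec.length:
            raise RelationMatrixError(
                f"matrix dimension {d[0]} != fingerprint length {self.spec.length}"
            )
        if self.defined_mask is not None:
            self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
            if self.defined_mask.shape != self.values.shape:
                raise RelationMatrixError("defined_mask shape mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def defined_offdiag_values(self) -> np.ndarray:
        """Unique (i < j) defined off-diagonal values, for profiles and stats."""
        if self.defined_mask is None:
            raise RelationMatrixError(f"{self.variant} has no defined_mask")
        iu = np.triu_indices(self.n_features, k=1)
        mask = self.defined_mask[iu]
        return self.values[iu][mask]


def accumulate_corm(
    vectors: Iterable[FeatureVector], provenance: str = ""
) -> RelationMatrix:
    """Build the co-occurrence count matrix CORM = sum of outer products.

    Accumulates X^T X over row blocks, which is element-wise identical to
    summing per-compound outer products.
    """
    mat, spec, _ = stack_vectors(vectors)
    d = mat.shape[1]
    counts = np.zeros((d, d), dtype=np.int64)
    for start in range(0, mat.shape[0], _BLOCK):
        block = mat[start : start + _BLOCK].astype(np.float64)
        counts += np.rint(block.T @ block).astype(np.int64)
    return RelationMatrix(
        values=counts,
        variant="corm",
        set_size=mat.shape[0],
        spec=spec,
        provenance=provenance,
    )


def merge_corms(a: RelationMatrix, b: RelationMatrix) -> RelationMatrix:
    """Element-wise sum of two count matrices over one fingerprint spec.

    Lets per-database CORMs over disjoint unique compound sets combine
    into a merged reference without re-reading the inputs.
    """
    for m in (a, b):
        if m.variant != "corm":
            raise RelationMatrixError("merge_corms requires corm variant inputs")
    if a.spec != b.spec:
        raise RelationMatrixError(f"fingerprint spec mismatch: {a.spec} vs {b.spec}")
    if a.toolkit != b.toolkit:
        raise RelationMatrixError(
            f"toolkit version mismatch: {a.toolkit!r} vs {b.toolkit!r}"
        )
    prov = " + ".join(p for p in (a.provenance, b.provenance) if p)
    return RelationMatrix(
        values=a.values + b.values,
        variant="corm",
        set_size=a.set_size + b.set_size,
        spec=a.spec,
        provenance=prov,
        toolkit=a.toolkit,
    )


def corm_to_coprm(c: RelationMatrix) -> RelationMatrix:
    """Divide counts by |S|; the diagonal becomes per-feature probabilities."""
    if c.variant != "corm":
        raise RelationMatrixError("corm_to_coprm requires a corm")
    if c.set_size < 1:
        raise RelationMatrixError("cannot normalize a corm with set_size 0")
    return RelationMatrix(
        values=c.values.astype(np.float64) / c.set_size,
        variant="coprm",
        set_size=c.set_size,
        spec=c.spec,
        provenance=c.provenance,
        toolkit=c.toolkit,
    )


def coprm_to_pmirm(p: RelationMatrix) -> RelationMatrix:
    """PMI_ij = log2( p_ij / (p_ii p_jj) ) for every defined feature pair.

    A cell is defined iff its pair co-occurrence probability p_ij > 0
    (which entails p_ii > 0 and p_jj > 0); the diagonal of every observed
    feature is 0 by convention; everything else is undefined (NaN).
    Pairs of individually observed features that never co-occur would have
    PMI = -inf and are masked rather than smoothed.
    """
    if p.variant != "coprm":
        raise RelationMatrixError("coprm_to_pmirm requires a coprm")
    prob = p.values
    diag = np.diag(prob)
    defined = prob > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log2(prob / np.outer(diag, diag))
    values = np.where(defined, pmi, np.nan)
    # observed features get a zero diagonal regardless of Eq.-literal -log2 p_ii
    present = diag > 0
    values[np.diag_indices_from(values)] = np.where(present, 0.0, np.nan)
    mask = defined.copy()
    mask[np.diag_indices_from(mask)] = present
    return RelationMatrix(
        values=values,
        variant="pmirm",
        set_size=p.set_size,
        spec=p.spec,
        defined_mask=mask,
        provenance=p.provenance,
        toolkit=p.toolkit,
    )


def pmirm_to_zpmirm(m: RelationMatrix) -> RelationMatrix:
    """Standardize defined PMI values to Z-scores.

    mu and sigma (population) are computed over the defined off-diagonal
    cells only — the zeroed diagonal is a convention, not data — and every
    defined cell, diagonal included, maps to (v - mu) / sigma.
    """
    if m.variant != "pmirm":
        raise RelationMatrixError("pmirm_to_zpmirm requires a pmirm")
    offdiag = m.defined_offdiag_values()
    if offdiag.size < 2:
        raise DegenerateProfileError(
            "fewer than two defined off-diagonal PMI values; no profile to standardize"
        )
    mu = float(offdiag.mean())
    sigma = float(offdiag.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateProfileError(
            f"degenerate interrelation profile {m.provenance!r}: all defined "
            f"off-diagonal PMI values equal {mu}; sigma = 0"
        )
    values = (m.values - mu) / sigma
    values = np.where(m.defined_mask, values, np.nan)
    return RelationMatrix(
        values=values,
        variant="zpmirm",
        set_size=m.set_size,
        spec=m.spec,
        defined_mask=m.defined_mask.copy(),
        standardization_stats=(mu, sigma),
        provenance=m.provenance,
        toolkit=m.toolkit,
    )


def transform(m: RelationMatrix, to: str) -> RelationMatrix:
    """Chain the variant pipeline corm -> coprm -> pmirm -> zpmirm up to `to`."""
    order = {v: i for i, v in enumerate(VARIANTS)}
    if to not in order:
        raise RelationMatrixError(f"unknown target variant {to!r}")
    if order[to] < order[m.variant]:
        raise RelationMatrixError(f"cannot transform {m.variant} back to {to}")
    steps = [corm_to_coprm, coprm_to_pmirm, pmirm_to_zpmirm]
    for step in steps[order[m.variant] : order[to]]:
        m = step(m)
    return m


# ---------------------------------------------------------------------------
# Container I/O: a zip archive holding a JSON metadata block and the packed
# upper triangle (row-major, diagonal included) of values and mask.
# ---------------------------------------------------------------------------


def _pack_triangle(a: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(a.shape[0])
    return np.ascontiguousarray(a[iu])


def _unpack_triangle(packed: np.ndarray, d: int) -> np.ndarray:
    iu = np.triu_indices(d)
    out = np.zeros((d, d), dtype=packed.dtype)
    out[iu] = packed
    out.T[iu] = packed
    return out


def save_matrix(m: RelationMatrix, path: str, command: str = "") -> None:
    """Serialize a relation matrix to a single-file .rm container."""
    meta = {
        "format_version": FORMAT_VERSION,
        "variant": m.variant,
        "set_size": m.set_size,
        "spec": m.spec.label(),
        "n_features": m.n_features,
        "standardization_stats": list(m.standardization_stats)
        if m.standardization_stats
        else None,
        "provenance": m.provenance,
        "toolkit": m.toolkit,
        "command": command,
        "has_mask": m.defined_mask is not None,
        "dtype": str(m.values.dtype),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        buf = io.BytesIO()
        np.save(buf, _pack_triangle(m.values))
        zf.writestr("values.npy", buf.getvalue())
        if m.defined_mask is not None:
            buf = io.BytesIO()
            np.save(buf, _pack_triangle(m.defined_mask))
            zf.writestr("mask.npy", buf.getvalue())


def load_matrix(path: str, expect_toolkit: Optional[str] = None) -> RelationMatrix:
    """Load an .rm container; refuses version or toolkit mismatches outright."""
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            values = np.load(io.BytesIO(zf.read("values.npy")))
            mask = (
                np.load(io.BytesIO(zf.read("mask.npy")))
                if meta.get("has_mask")
                else None
            )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise RelationMatrixError(f"corrupted relation matrix container {path}: {exc}")
    if meta.get("format_version") != FORMAT_VERSION:
        raise RelationMatrixError(
            f"unsupported container format version {meta.get('format_version')}"
        )
    if expect_toolkit is not None and meta["toolkit"] != expect_toolkit:
        raise RelationMatrixError(
            f"toolkit mismatch: container built with {meta['toolkit']!r}, "
            f"expected {expect_toolkit!r}"
        )
    d = int(meta["n_features"])
    stats = meta.get("standardization_stats")
    return RelationMatrix(
        values=_unpack_triangle(values, d),
        variant=meta["variant"],
        set_size=int(meta["set_size"]),
        spec=FingerprintSpec.from_label(meta["spec"]),
        defined_mask=_unpack_triangle(mask, d) if mask is not None else None,
        standardization_stats=tuple(stats) if stats else None,
        provenance=meta.get("provenance", ""),
        toolkit=meta["toolkit"],
    )
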