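"""Interrelation profiles: PMI/ZPMI histograms, size-ladder subsampling and
range-restricted exclusive-pair mining between compound sets."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .featurize import FeatureVector
from .relmat import RelationMatrix, RelationMatrixError

#: geometric x4 ladder of subset sizes used for size-dependence studies
DEFAULT_SIZE_LADDER = (8000, 32000, 128000, 512000, 2048000)

DEFAULT_BIN_WIDTH = 0.1


class ProfileError(ValueError):
    pass


@dataclass
class InterrelationProfile:
    """Histogram of the defined off-diagonal PMI (or ZPMI) values of a set.

    Bins are contiguous half-open intervals [lo, lo + width) whose edges
    are integer multiples of bin_width; counts sum to n_defined.
    """

    histogram: list  # [(bin lower edge, count), ...]
    bin_width: float
    matrix_ref: str
    n_defined: int
    bits_set: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.histogram, columns=["bin_lo", "count"])

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def profile(
    m: RelationMatrix, bin_width: float = DEFAULT_BIN_WIDTH
) -> InterrelationProfile:
    """Histogram the unique (i < j) defined PMI/ZPMI values of a matrix."""
    if m.variant not in ("pmirm", "zpmirm"):
        raise ProfileError(f"profile requires pmirm or zpmirm, got {m.variant}")
    if bin_width <= 0:
        raise ProfileError("bin_width must be positive")
    vals = m.defined_offdiag_values()
    if vals.size == 0:
        raise ProfileError("no defined off-diagonal pairs to profile")
    lo_idx = int(np.floor(vals.min() / bin_width))
    hi_idx = int(np.floor(vals.max() / bin_width))
    edges = (np.arange(lo_idx, hi_idx + 2)) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    # numpy closes the last bin; push any exact-top-edge value into its
    # own half-open bin to keep the [lo, lo+width) contract
    hist = [(float(edges[i]), int(counts[i])) for i in range(len(counts))]
    # bits_set: features observed at least once (diagonal defined)
    if m.defined_mask is not None:
        bits_set = int(np.diag(m.defined_mask).sum())
    else:
        bits_set = int((np.diag(m.values) > 0).sum())
    return InterrelationProfile(
        histogram=hist,
        bin_width=bin_width,
        matrix_ref=m.provenance,
        n_defined=int(vals.size),
        bits_set=bits_set,
    )


def subsample_sets(
    vectors: Sequence[FeatureVector],
    sizes: Sequence[int] = DEFAULT_SIZE_LADDER,
    seed: int = 0,
) -> list[list[FeatureVector]]:
    """Nested random subsets of ascending sizes, reproducible from a seed.

    Each larger subset contains every smaller one (a single permutation
    is prefix-sliced), matching the overlapping-subset protocol used for
    size-dependence studies.
    """
    vectors = list(vectors)
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ProfileError("subset sizes must be ascending")
    if sizes and sizes[-1] > len(vectors):
        raise ProfileError(
            f"largest subset size {sizes[-1]} exceeds population {len(vectors)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(vectors))
    return [[vectors[i] for i in order[:size]] for size in sizes]


def exclusive_pairs(
    target: RelationMatrix,
    others: Sequence[RelationMatrix],
    lo: float,
    hi: float,
    mode: str = "outside",
) -> tuple[set, int]:
    """Feature pairs whose PMI falls in [lo, hi] only in the target set.

    Returns (exclusive pairs, total in-range pair count in the target).
    mode="outside" (default): a pair counts as exclusive when every other
    matrix has it undefined or outside [lo, hi]. mode="absent": stricter —
    every other matrix must have the pair undefined (never co-occurring).
    """
    if target.variant not in ("pmirm", "zpmirm"):
        raise ProfileError("exclusive_pairs requires pmirm or zpmirm matrices")
    if mode not in ("outside", "absent"):
        raise ProfileError(f"unknown exclusivity mode {mode!r}")
    for o in others:
        if o.spec != target.spec:
            raise ProfileError(
                f"fingerprint spec mismatch: {o.spec} vs {target.spec}"
            )
        if o.variant != target.variant:
            raise ProfileError("all matrices must share one variant")
    iu, ju = np.triu_indices(target.n_features, k=1)
    tvals = target.values[iu, ju]
    tmask = target.defined_mask[iu, ju]
    in_range = tmask & (tvals >= lo) & (tvals <= hi)
    exclusive = in_range.copy()
    for o in others:
        ovals = o.values[iu, ju]
        omask = o.defined_mask[iu, ju]
        if mode == "absent":
            blocked = omask
        else:
            blocked = omask & (ovals >= lo) & (ovals <= hi)
        exclusive &= ~blocked
    pairs = {
        (int(i), int(j)) for i, j in zip(iu[exclusive], ju[exclusive])
    }
    return pairs, int(in_range.sum())
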