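"""Mutual-information linkage disequilibrium between pairs of phased variants.

MI is used as the LD metric driving tag selection: for two biallelic variants
the 2x2 joint haplotype frequency table gives the plug-in estimate

    I(X; Y) = sum_{a,b in {0,1}} p(a,b) log2[ p(a,b) / (p(a) p(b)) ]

in bits, with 0 * log(.) terms contributing zero.  The estimator is the plain
plug-in (no small-sample bias correction); missing haplotype entries are
dropped pairwise (complete cases per variant pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    MISSING,
    HaplotypePanel,
    InsufficientDataError,
    VariantKey,
    probes_required,
)

__all__ = [
    "binary_entropy",
    "mi_from_counts",
    "mutual_information",
    "pairwise_mi",
    "MIMatrix",
    "probes_required",
]


def binary_entropy(p: float) -> float:
    """Entropy in bits of a Bernoulli(p) variable."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p))


def mi_from_counts(n00: int, n01: int, n10: int, n11: int) -> float:
    """Plug-in MI (bits) from a 2x2 joint haplotype count table."""
    counts = np.array([[n00, n01], [n10, n11]], dtype=float)
    n = counts.sum()
    if n < 2:
        raise InsufficientDataError("fewer than 2 jointly observed haplotypes")
    p = counts / n
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    total = 0.0
    for a in range(2):
        for b in range(2):
            if p[a, b] > 0.0:
                total += p[a, b] * np.log2(p[a, b] / (pa[a] * pb[b]))
    # the plug-in MI is nonnegative; clamp float round-off
    return max(0.0, float(total))


def _joint_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    mask = (x != MISSING) & (y != MISSING)
    xm = x[mask]
    ym = y[mask]
    n11 = int(np.sum((xm == 1) & (ym == 1)))
    n10 = int(np.sum((xm == 1) & (ym == 0)))
    n01 = int(np.sum((xm == 0) & (ym == 1)))
    n00 = int(np.sum((xm == 0) & (ym == 0)))
    return n00, n01, n10, n11


def mutual_information(panel: HaplotypePanel, i: VariantKey, j: VariantKey) -> float:
    """MI in bits between two panel variants over jointly non-missing haplotypes."""
    return mi_from_counts(*_joint_counts(panel.row(i), panel.row(j)))


@dataclass
class MIMatrix:
    """Pairwise MI values for a block of variant pairs (NaN where undefined)."""

    variants_a: list[VariantKey]
    variants_b: list[VariantKey]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._ia = {v: k for k, v in enumerate(self.variants_a)}
        self._ib = {v: k for k, v in enumerate(self.variants_b)}

    def get(self, a: VariantKey, b: VariantKey) -> float:
        return float(self.values[self._ia[a], self._ib[b]])

    def has(self, a: VariantKey, b: VariantKey) -> bool:
        return a in self._ia and b in self._ib


def pairwise_mi(
    panel: HaplotypePanel,
    variant_set_a: Sequence[VariantKey],
    variant_set_b: Sequence[VariantKey],
) -> MIMatrix:
    """MI for every pair in ``A x B``; pairs with <2 joint observations are NaN."""
    rows_a = [panel.row(v) for v in variant_set_a]
    rows_b = [panel.row(v) for v in variant_set_b]
    out = np.full((len(rows_a), len(rows_b)), np.nan)
    for ai, ra in enumerate(rows_a):
        for bi, rb in enumerate(rows_b):
            try:
                out[ai, bi] = mi_from_counts(*_joint_counts(ra, rb))
            except InsufficientDataError:
                pass
    return MIMatrix(list(variant_set_a), list(variant_set_b), out)
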