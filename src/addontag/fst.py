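"""Hudson F_ST between two cohorts of phased haplotypes.

The Bhatia et al. ratio-of-averages form is used: per shared site the
numerator and denominator

    num = (p1 - p2)^2 - p1 (1 - p1) / (n1 - 1) - p2 (1 - p2) / (n2 - 1)
    den = p1 (1 - p2) + p2 (1 - p1)

are accumulated and the estimate is sum(num) / sum(den), never the mean of
per-site ratios.  Only autosomal biallelic sites that are common
(MAF > ``maf_min``) in the merged cohort enter the sums; slightly negative
estimates are possible and reported as-is.
"""

from __future__ import annotations

from .core import (
    MISSING,
    HaplotypePanel,
    InsufficientDataError,
    is_autosome,
)

import numpy as np


def hudson_site(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Per-site Hudson numerator and denominator.

    ``p1``/``p2`` are allele frequencies and ``n1``/``n2`` the observed
    haplotype counts in each cohort.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need at least 2 haplotypes per cohort")
    num = (
        (p1 - p2) ** 2
        - p1 * (1.0 - p1) / (n1 - 1)
        - p2 * (1.0 - p2) / (n2 - 1)
    )
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return num, den


def hudson_components(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    maf_min: float = 0.05,
) -> tuple[float, float, int]:
    """Summed Hudson numerator/denominator and retained-site count."""
    num_sum = 0.0
    den_sum = 0.0
    n_sites = 0
    for v in panel_a.variants:
        if v not in panel_b or not is_autosome(v.chrom):
            continue
        row_a = panel_a.row(v)
        row_b = panel_b.row(v)
        obs_a = row_a[row_a != MISSING]
        obs_b = row_b[row_b != MISSING]
        n1, n2 = obs_a.size, obs_b.size
        if n1 < 2 or n2 < 2:
            continue
        alt_total = float(obs_a.sum() + obs_b.sum())
        p_merged = alt_total / (n1 + n2)
        if min(p_merged, 1.0 - p_merged) <= maf_min:
            continue
        p1 = float(np.mean(obs_a))
        p2 = float(np.mean(obs_b))
        num, den = hudson_site(p1, n1, p2, n2)
        num_sum += num
        den_sum += den
        n_sites += 1
    return num_sum, den_sum, n_sites


def hudson_fst(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    maf_min: float = 0.05,
) -> float:
    """Ratio-of-averages Hudson F_ST over shared common autosomal sites."""
    num_sum, den_sum, n_sites = hudson_components(panel_a, panel_b, maf_min)
    if n_sites == 0 or den_sum <= 0.0:
        raise InsufficientDataError("no shared common autosomal sites retained")
    return num_sum / den_sum
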