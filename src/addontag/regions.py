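"""Genomic regions over which tag selection runs, for both selection settings.

Setting 1 works on user-supplied prioritized intervals (e.g. disease gene
lists), each screened for poor imputation coverage.  Setting 2 builds its own
regions around candidate target variants: the larger of the variant's
haplotype block and a fixed flank, with overlapping regions merged.

The block finder is a simplified Gabriel-et-al. procedure on D' confidence
intervals, mirroring the defaults of ``plink --blocks``: a pair is in "strong
LD" when the 90% CI of |D'| has lower bound >= 0.70 and upper bound >= 0.98,
shows "strong recombination" when the upper bound is < 0.90, and a span is a
block when its endpoints are in strong LD and at least 95% of its informative
pairs are.  Blocks are assembled greedily, longest first.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    MISSING,
    HaplotypePanel,
    ImputationQualityTable,
    InsufficientDataError,
    VariantKey,
)

logger = logging.getLogger(__name__)


@dataclass
class Region:
    """A 1-based closed genomic interval with its member variants."""

    id: str
    chrom: str
    start: int
    end: int
    setting: int
    members: list[VariantKey] = field(default_factory=list)
    targets: list[VariantKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.id}: start > end")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, v: VariantKey) -> bool:
        return v.chrom == self.chrom and self.start <= v.pos <= self.end

    def resolve_members(self, panel: HaplotypePanel) -> None:
        self.members = panel.variants_in(self.chrom, self.start, self.end)


@dataclass
class RegionQualification:
    """Why a prioritized region does or does not enter tag selection."""

    frac_poor: float
    sigma_poor: float
    sigma_well: float
    sigma_all_imputed: float
    sigma_wgs: float
    norm_spread_poor: float
    norm_spread_well: float
    qualifies: bool


def _sigma(positions: list[int]) -> float:
    if len(positions) < 2:
        return float("nan")
    return float(np.std(np.asarray(positions, dtype=float)))


def qualify_region(
    region: Region,
    quality: ImputationQualityTable,
    panel: HaplotypePanel,
    frac_threshold: float = 0.20,
    spread_ratio: float = 1.25,
    maf_min: float = 0.05,
    quality_threshold: float = 0.8,
) -> RegionQualification:
    """Decide whether a prioritized region needs add-on tags.

    A region qualifies when more than ``frac_threshold`` of its imputed common
    variants are poorly imputed (quality < ``quality_threshold``), or when the
    positional spread of the poorly imputed variants exceeds ``spread_ratio``
    times that of the well-imputed ones (both spreads normalized by the larger
    of the all-imputed and all-sequenced spreads).
    """
    common = [v for v in region.members if v in panel and panel.maf(v) > maf_min]
    if len(common) < 2:
        raise InsufficientDataError(
            f"region {region.id}: fewer than 2 common variants"
        )
    imputed = [v for v in common if v in quality]
    poor = [v for v in imputed if quality.quality(v) < quality_threshold]
    well = [v for v in imputed if quality.quality(v) >= quality_threshold]

    frac_poor = len(poor) / len(imputed) if imputed else 0.0
    sigma_wgs = _sigma([v.pos for v in common])
    sigma_all = _sigma([v.pos for v in imputed])
    sigma_poor = _sigma([v.pos for v in poor])
    sigma_well = _sigma([v.pos for v in well])

    denom_terms = [s for s in (sigma_all, sigma_wgs) if not math.isnan(s)]
    denom = max(denom_terms) if denom_terms else float("nan")
    norm_poor = sigma_poor / denom if denom and not math.isnan(sigma_poor) else float("nan")
    norm_well = sigma_well / denom if denom and not math.isnan(sigma_well) else float("nan")

    # spread criterion needs >=2 points in each subset; with <2 well-imputed
    # variants only the fraction criterion applies, with <2 poor it is false
    spread_flag = False
    if len(well) >= 2 and len(poor) >= 2:
        spread_flag = sigma_poor > spread_ratio * sigma_well

    return RegionQualification(
        frac_poor=frac_poor,
        sigma_poor=sigma_poor,
        sigma_well=sigma_well,
        sigma_all_imputed=sigma_all,
        sigma_wgs=sigma_wgs,
        norm_spread_poor=norm_poor,
        norm_spread_well=norm_well,
        qualifies=bool(frac_poor > frac_threshold or spread_flag),
    )


# ---------------------------------------------------------------------------
# haplotype blocks


def dprime_ci(
    x: np.ndarray, y: np.ndarray, grid: int = 200, mass: float = 0.05
) -> tuple[float, float] | None:
    """90% confidence bounds on |D'| for a haplotype pair via a likelihood grid.

    Returns None for uninformative pairs (monomorphic or <4 joint haplotypes).
    """
    mask = (x != MISSING) & (y != MISSING)
    xm, ym = x[mask], y[mask]
    n = xm.size
    if n < 4:
        return None
    pa = float(np.mean(xm))
    pb = float(np.mean(ym))
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    n11 = float(np.sum((xm == 1) & (ym == 1)))
    n10 = float(np.sum((xm == 1) & (ym == 0)))
    n01 = float(np.sum((xm == 0) & (ym == 1)))
    n00 = float(np.sum((xm == 0) & (ym == 0)))
    d_obs = n11 / n - pa * pb
    if d_obs >= 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
        sign = 1.0
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
        sign = -1.0
    if d_max <= 0:
        return None
    dprimes = np.linspace(0.0, 1.0, grid + 1)
    eps = 1e-12
    p11 = np.clip(pa * pb + sign * dprimes * d_max, eps, 1.0)
    p10 = np.clip(pa - p11, eps, 1.0)
    p01 = np.clip(pb - p11, eps, 1.0)
    p00 = np.clip(1.0 - pa - pb + p11, eps, 1.0)
    ll = (n11 * np.log(p11) + n10 * np.log(p10)
          + n01 * np.log(p01) + n00 * np.log(p00))
    post = np.exp(ll - ll.max())
    cdf = np.cumsum(post) / post.sum()
    low = float(dprimes[int(np.searchsorted(cdf, mass))])
    high = float(dprimes[int(np.searchsorted(cdf, 1.0 - mass))])
    return low, high


STRONG_LD = "strong"
RECOMB = "recomb"

def _classify_pair(
    panel: HaplotypePanel,
    i: VariantKey,
    j: VariantKey,
    ci_low: float = 0.70,
    ci_high: float = 0.98,
    recomb_high: float = 0.90,
) -> str | None:
    ci = dprime_ci(panel.row(i), panel.row(j))
    if ci is None:
        return None
    low, high = ci
    if low >= ci_low and high >= ci_high:
        return STRONG_LD
    if high < recomb_high:
        return RECOMB
    return None


def haplotype_blocks(
    panel: HaplotypePanel,
    region_scope: list[VariantKey] | None = None,
    maf_min: float = 0.05,
    max_span_bp: int = 200_000,
    informative_frac: float = 0.95,
) -> list[Region]:
    """Partition the common variants in scope into haplotype blocks.

    Variants not absorbed into a multi-variant block become singleton blocks,
    so the returned blocks cover every common variant exactly once.
    """
    scope = region_scope if region_scope is not None else list(panel.variants)
    common = [v for v in scope if v in panel and panel.maf(v) > maf_min]
    blocks: list[Region] = []
    counter = itertools.count()
    for chrom in sorted({v.chrom for v in common}):
        vs = sorted((v for v in common if v.chrom == chrom), key=lambda v: v.pos)
        m = len(vs)
        # classify every close-enough pair once
        cls: dict[tuple[int, int], str | None] = {}
        for a in range(m):
            for b in range(a + 1, m):
                if vs[b].pos - vs[a].pos > max_span_bp:
                    break
                cls[(a, b)] = _classify_pair(panel, vs[a], vs[b])
        candidates = []
        for (a, b), c in cls.items():
            if c != STRONG_LD:
                continue
            inner = [cls.get((p, q)) for p in range(a, b + 1) for q in range(p + 1, b + 1)]
            informative = [c2 for c2 in inner if c2 is not None]
            if not informative:
                continue
            strong = sum(1 for c2 in informative if c2 == STRONG_LD)
            if strong / len(informative) >= informative_frac:
                candidates.append((a, b))
        candidates.sort(key=lambda ab: (-(ab[1] - ab[0]), ab[0]))
        used = [False] * m
        spans: list[tuple[int, int]] = []
        for a, b in candidates:
            if any(used[a : b + 1]):
                continue
            spans.append((a, b))
            for k in range(a, b + 1):
                used[k] = True
        for k in range(m):
            if not used[k]:
                spans.append((k, k))
        spans.sort()
        for a, b in spans:
            members = vs[a : b + 1]
            blocks.append(
                Region(
                    id=f"block_{chrom}_{next(counter)}",
                    chrom=chrom,
                    start=members[0].pos,
                    end=members[-1].pos,
                    setting=2,
                    members=members,
                )
            )
    return blocks


def build_setting2_regions(
    targets: list[VariantKey],
    panel: HaplotypePanel,
    flank: int = 5000,
    blocks: list[Region] | None = None,
) -> list[Region]:
    """Regions for genome-wide selection: per target, the larger of its
    haplotype block and a +/-``flank`` window; overlapping regions are merged."""
    if not targets:
        return []
    if blocks is None:
        blocks = haplotype_blocks(panel)
    block_of: dict[VariantKey, Region] = {}
    for blk in blocks:
        for v in blk.members:
            block_of[v] = blk
    intervals: list[tuple[str, int, int, VariantKey]] = []
    for t in targets:
        win = (t.chrom, max(1, t.pos - flank), t.pos + flank)
        blk = block_of.get(t)
        if blk is not None and blk.span > (win[2] - win[1] + 1):
            intervals.append((blk.chrom, blk.start, blk.end, t))
        else:
            intervals.append((*win, t))
    merged: list[Region] = []
    counter = itertools.count()
    for chrom in sorted({iv[0] for iv in intervals}):
        ivs = sorted((iv for iv in intervals if iv[0] == chrom), key=lambda iv: iv[1])
        cur_start, cur_end = ivs[0][1], ivs[0][2]
        cur_targets = [ivs[0][3]]
        for _, s, e, t in ivs[1:]:
            if s <= cur_end:
                cur_end = max(cur_end, e)
                cur_targets.append(t)
            else:
                merged.append(_make_region(chrom, cur_start, cur_end, cur_targets, panel, counter))
                cur_start, cur_end, cur_targets = s, e, [t]
        merged.append(_make_region(chrom, cur_start, cur_end, cur_targets, panel, counter))
    return merged


def _make_region(chrom, start, end, targets, panel, counter) -> Region:
    region = Region(
        id=f"s2_{chrom}_{next(counter)}",
        chrom=chrom,
        start=start,
        end=end,
        setting=2,
        targets=sorted(set(targets), key=lambda v: v.pos),
    )
    region.resolve_members(panel)
    return region
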