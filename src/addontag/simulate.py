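"""Synthetic cohorts with controlled LD, divergence and array mismatch.

Haplotypes are founder mosaics: each block draws a small pool of founder
haplotypes with allele frequencies from ``allele_freq_range``, and every
simulated haplotype copies one founder per block, re-drawing the founder
between blocks with probability ``recomb_between_blocks``.  This yields
strong within-block LD, tunable between-block LD, and analytic oracles
(pool of two founders with no recombination gives a two-haplotype mixture
whose MI is known in closed form).

Two-population divergence follows the Balding-Nichols model: per site an
ancestral frequency p gives each population a frequency drawn from
Beta(p (1-F)/F, (1-p)(1-F)/F), so Hudson F_ST recovery tests have a known
truth.

``plant_mismatch_design`` emulates an array designed for the wrong
population: base-array tags are ranked by informativeness in an "array
population" panel whose founder pools (and hence LD and frequencies) differ
from the study population's, producing study-common variants that the base
array tags poorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    BASES,
    HaplotypePanel,
    ImputationQualityTable,
    ProbeInfo,
    ValidationError,
    VariantKey,
)
from .impute import quality_from_surrogate
from .ld import pairwise_mi

_BASE_LIST = sorted(BASES)


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic cohort generator (all draws seeded)."""

    n_haplotypes: int = 400
    n_blocks: int = 12
    variants_per_block: int = 8
    block_haplotype_pool_size: int = 4
    recomb_between_blocks: float = 0.1
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    fst_F: float = 0.1
    array_fraction: float = 0.25
    array_bias: float = 0.9
    seed: int = 0
    chrom: str = "1"
    variant_spacing: int = 250
    block_gap: int = 15000
    low_probe_frac: float = 0.2
    flank: int = 5000

    def __post_init__(self) -> None:
        for name in ("recomb_between_blocks", "fst_F", "array_fraction",
                     "array_bias", "low_probe_frac"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name}={val} outside [0, 1]")
        for name in ("n_haplotypes", "n_blocks", "variants_per_block",
                     "block_haplotype_pool_size"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @property
    def block_stride(self) -> int:
        return self.variants_per_block * self.variant_spacing + self.block_gap

    def position(self, block: int, offset: int) -> int:
        return 1 + block * self.block_stride + offset * self.variant_spacing

    def block_interval(self, block: int) -> tuple[int, int]:
        return (self.position(block, 0),
                self.position(block, self.variants_per_block - 1))


def _draw_keys(params: SimParams, rng: np.random.Generator) -> list[VariantKey]:
    keys = []
    for b in range(params.n_blocks):
        for t in range(params.variants_per_block):
            ref, alt = rng.choice(_BASE_LIST, size=2, replace=False)
            keys.append(VariantKey(params.chrom, params.position(b, t), str(ref), str(alt)))
    return keys


def simulate_panel(
    params: SimParams,
    seed: int | None = None,
    keys: list[VariantKey] | None = None,
    sample_prefix: str = "S",
) -> HaplotypePanel:
    """Simulate a phased block-structured haplotype panel.

    ``seed`` overrides ``params.seed``; passing ``keys`` reuses variant
    identities so a second population can share coordinates.
    """
    if params.block_haplotype_pool_size < 2:
        raise ValidationError("founder pool size must be >= 2 for within-block LD")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if keys is None:
        keys = _draw_keys(params, rng)
    n_hap = params.n_haplotypes
    pool = params.block_haplotype_pool_size
    vpb = params.variants_per_block
    lo, hi = params.allele_freq_range
    hap = np.empty((params.n_blocks * vpb, n_hap), dtype=np.int8)
    founder_idx = rng.integers(0, pool, size=n_hap)
    for b in range(params.n_blocks):
        freqs = rng.uniform(lo, hi, size=vpb)
        founders = (rng.random((pool, vpb)) < freqs).astype(np.int8)
        if b > 0:
            recomb = rng.random(n_hap) < params.recomb_between_blocks
            founder_idx = np.where(
                recomb, rng.integers(0, pool, size=n_hap), founder_idx
            )
        hap[b * vpb : (b + 1) * vpb, :] = founders[founder_idx].T
    n_samples = n_hap // 2
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    return HaplotypePanel(list(keys), hap[:, : 2 * n_samples], sample_ids)


def simulate_pair(
    params: SimParams, seed: int | None = None
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Two panels diverged at Balding-Nichols F = ``params.fst_F``.

    Sites are independent (no block structure) so the F_ST truth is clean.
    """
    if not 0.0 <= params.fst_F < 1.0:
        raise ValidationError("fst_F must be in [0, 1)")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    keys = _draw_keys(params, rng)
    n_sites = len(keys)
    lo, hi = params.allele_freq_range
    p_anc = rng.uniform(lo, hi, size=n_sites)
    f = params.fst_F
    if f == 0.0:
        p1 = p2 = p_anc
    else:
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    n_hap = params.n_haplotypes
    hap1 = (rng.random((n_sites, n_hap)) < p1[:, None]).astype(np.int8)
    hap2 = (rng.random((n_sites, n_hap)) < p2[:, None]).astype(np.int8)
    n_samples = n_hap // 2
    ids_a = [f"A{i:04d}" for i in range(n_samples)]
    ids_b = [f"B{i:04d}" for i in range(n_samples)]
    return (
        HaplotypePanel(list(keys), hap1[:, : 2 * n_samples], ids_a),
        HaplotypePanel(list(keys), hap2[:, : 2 * n_samples], ids_b),
    )


def simulate_study_and_array_panels(
    params: SimParams,
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Study and array-population panels sharing coordinates but with
    independent founder pools (different LD and allele frequencies)."""
    rng = np.random.default_rng([params.seed, 11])
    keys = _draw_keys(params, rng)
    study = simulate_panel(params, seed=int(rng.integers(2**31)), keys=keys,
                           sample_prefix="S")
    array_pop = simulate_panel(params, seed=int(rng.integers(2**31)), keys=keys,
                               sample_prefix="P")
    return study, array_pop


@dataclass
class MismatchDesign:
    """A planted base-array design plus everything selection needs."""

    array_tags: list[VariantKey]
    probes: dict[VariantKey, ProbeInfo]
    quality: ImputationQualityTable
    train: HaplotypePanel
    test: HaplotypePanel


def _informativeness_ranking(
    panel: HaplotypePanel, members: list[VariantKey]
) -> list[VariantKey]:
    """Block members ordered by total MI against the rest of the block."""
    mi = pairwise_mi(panel, members, members)
    totals = np.nansum(np.nan_to_num(mi.values, nan=0.0), axis=1) - np.nan_to_num(
        np.diag(mi.values), nan=0.0
    )
    order = np.argsort(-totals, kind="stable")
    return [members[i] for i in order]


def plant_mismatch_design(
    panel_study: HaplotypePanel,
    panel_array: HaplotypePanel,
    params: SimParams,
) -> MismatchDesign:
    """Choose base-array tags with an array-population bias and score the result.

    With probability ``array_bias`` a block's tags are the variants most
    informative in the array population (which may be uninformative or rare
    in the study population); otherwise the study population's own most
    informative variants are used.  Probe-ability scores are drawn with
    ``low_probe_frac`` of their mass below the 0.3 design threshold, and the
    quality table comes from running the surrogate evaluator with the planted
    array on a 3:1 train/test split of the study panel.
    """
    if panel_study.variants != panel_array.variants:
        raise ValidationError("study and array panels must share coordinates")
    rng = np.random.default_rng([params.seed, 23])
    vpb = params.variants_per_block
    n_tags = max(1, round(params.array_fraction * vpb))
    array_tags: list[VariantKey] = []
    for b in range(params.n_blocks):
        members = panel_study.variants[b * vpb : (b + 1) * vpb]
        use_array_pop = rng.random() < params.array_bias
        ranking = _informativeness_ranking(
            panel_array if use_array_pop else panel_study, members
        )
        array_tags.extend(ranking[:n_tags])

    probes: dict[VariantKey, ProbeInfo] = {}
    for v in panel_study.variants:
        if rng.random() < params.low_probe_frac:
            score = float(rng.uniform(0.0, 0.3))
        else:
            score = float(rng.uniform(0.3, 1.0))
        probes[v] = ProbeInfo.for_variant(v, score)

    n_train = (3 * panel_study.n_samples) // 4
    train = panel_study.subset_samples(panel_study.sample_ids[:n_train])
    test = panel_study.subset_samples(panel_study.sample_ids[n_train:])
    targets = [v for v in panel_study.variants if v not in set(array_tags)]
    quality = quality_from_surrogate(
        train, test, array_tags, targets, window=params.flank
    )
    return MismatchDesign(
        array_tags=sorted(array_tags),
        probes=probes,
        quality=quality,
        train=train,
        test=test,
    )


def make_mismatch_fixture(params: SimParams) -> MismatchDesign:
    """Convenience: simulate both populations and plant the mismatch design."""
    study, array_pop = simulate_study_and_array_panels(params)
    return plant_mismatch_design(study, array_pop, params)


def write_mismatch_fixture(params: SimParams, out_dir, n_priority_blocks: int = 3):
    """Write a complete, self-consistent input set to ``out_dir``.

    Emits train.vcf and test.vcf (the study-panel split), manifest.tsv (the
    planted base array), probes.tsv, quality.tsv and priority.bed (the first
    ``n_priority_blocks`` block intervals, padded by 500 bp) so the full
    pipeline can run off disk.  Returns the design object.
    """
    from pathlib import Path

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = make_mismatch_fixture(params)
    io.write_panel(design.train, out / "train.vcf")
    io.write_panel(design.test, out / "test.vcf")
    io.write_manifest(design.array_tags, out / "manifest.tsv")
    io.write_probe_table(design.probes, out / "probes.tsv")
    io.write_quality_table(design.quality, out / "quality.tsv")
    intervals = []
    for b in range(min(n_priority_blocks, params.n_blocks)):
        start, end = params.block_interval(b)
        intervals.append((params.chrom, max(1, start - 500), end + 500))
    io.write_bed(intervals, out / "priority.bed")
    return design
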