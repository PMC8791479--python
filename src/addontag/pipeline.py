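"""End-to-end orchestration: candidates -> regions -> selection -> evaluation.

The pipeline mirrors the three-step design workflow: (1) a per-variant
imputation-quality table identifies poorly imputed common variants, (2) the
greedy selector picks add-on tags in prioritized regions (Setting 1) and then
genome-wide under the remaining probe budget (Setting 2), and (3) the
surrogate evaluator compares the base array, a random add-on baseline, and
the proposed add-ons on held-out samples.  Every threshold is configurable
and defaults to the standard design values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .core import (
    HaplotypePanel,
    ImputationQualityTable,
    InsufficientDataError,
    ProbeInfo,
    VariantKey,
)
from .evaluate import DEFAULT_MAF_BINS, EvaluationReport, evaluate_designs
from .regions import Region, build_setting2_regions, qualify_region
from .select import (
    SelectionResult,
    SelectionState,
    find_candidates,
    random_selection,
    run_setting1,
    run_setting2,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, outputs and thresholds of one pipeline run."""

    train_vcf: str
    test_vcf: str | None
    quality: str
    array_manifest: str
    probes: str
    priority_bed: str | None = None
    site_list: str | None = None
    out_dir: str = "addontag_out"
    maf_min: float = 0.05
    quality_max: float = 0.8
    probeability_min: float = 0.3
    missingness_max: float = 0.5
    stop_frac: float = 0.005
    frac_threshold: float = 0.20
    spread_ratio: float = 1.25
    probe_budget: int = 5000
    flank: int = 5000
    seed: int = 7
    shared_budget: bool = True  # Setting-1 probes count against the budget
    maf_bins: tuple[float, ...] = DEFAULT_MAF_BINS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "maf_bins" in raw:
            raw["maf_bins"] = tuple(raw["maf_bins"])
        return cls(**raw)


@dataclass
class PipelineResult:
    proposed: SelectionResult
    random: SelectionResult
    report: EvaluationReport | None
    regions1: list[Region]
    regions2: list[Region]
    qualifications: pd.DataFrame
    targets: list[VariantKey]


def _build_states(
    regions: list[Region],
    panel: HaplotypePanel,
    quality: ImputationQualityTable,
    probes: dict[VariantKey, ProbeInfo],
    array: list[VariantKey],
    cfg: PipelineConfig,
    site_list: set[VariantKey] | None,
) -> list[SelectionState]:
    states = []
    for region in regions:
        sets = find_candidates(
            panel, quality, probes, array, region,
            maf_min=cfg.maf_min, quality_max=cfg.quality_max,
            probeability_min=cfg.probeability_min,
            missingness_max=cfg.missingness_max, site_list=site_list,
        )
        if not sets.s1:
            logger.info("region %s: no candidate targets, skipped", region.id)
            continue
        states.append(SelectionState(region, panel, sets, probes))
    return states


def run_pipeline(
    cfg: PipelineConfig,
    write_outputs: bool = True,
    do_random: bool = True,
    do_evaluate: bool = True,
) -> PipelineResult:
    """Execute the full design workflow and (optionally) write artifacts."""
    train = io.read_panel(cfg.train_vcf, missingness_max=1.0)
    test = io.read_panel(cfg.test_vcf, missingness_max=1.0) if cfg.test_vcf else None
    array, probes, quality, priority = io.read_tables(
        cfg.array_manifest, cfg.probes, cfg.quality,
        cfg.priority_bed if cfg.priority_bed else None,
    )
    site_list = set(io.read_manifest(cfg.site_list)) if cfg.site_list else None

    # ---- Setting 1: prioritized regions that qualify
    regions1: list[Region] = []
    qual_rows = []
    for i, (chrom, start, end) in enumerate(priority):
        region = Region(id=f"s1_{i}", chrom=chrom, start=start, end=end, setting=1)
        region.resolve_members(train)
        try:
            qual = qualify_region(
                region, quality, train,
                frac_threshold=cfg.frac_threshold, spread_ratio=cfg.spread_ratio,
                maf_min=cfg.maf_min, quality_threshold=cfg.quality_max,
            )
        except InsufficientDataError:
            logger.info("region %s: not qualifiable (too few common variants)", region.id)
            continue
        qual_rows.append({"region_id": region.id, "chrom": chrom, "start": start,
                          "end": end, **{k: v for k, v in vars(qual).items()}})
        if qual.qualifies:
            regions1.append(region)
    qualifications = pd.DataFrame(qual_rows)

    states1 = _build_states(regions1, train, quality, probes, array, cfg, site_list)
    result1 = run_setting1(states1, stop_frac=cfg.stop_frac)
    for acc in result1.accepted:
        acc.setting = 1

    # ---- Setting 2: genome-wide regions around remaining poor common variants
    selected1 = set(result1.keys)
    covered1 = regions1
    targets2 = []
    for v in train.variants:
        if any(r.contains(v) for r in covered1):
            continue
        try:
            if train.maf(v) <= cfg.maf_min:
                continue
        except InsufficientDataError:
            continue
        if quality.quality(v, default=0.0) < cfg.quality_max:
            targets2.append(v)
    regions2 = build_setting2_regions(targets2, train, flank=cfg.flank)
    array2 = array + sorted(selected1)
    states2 = _build_states(regions2, train, quality, probes, array2, cfg, site_list)
    used = result1.n_probes if cfg.shared_budget else 0
    result2 = run_setting2(states2, probe_budget=cfg.probe_budget, already_used=used)

    proposed = SelectionResult()
    proposed.extend(result1)
    proposed.extend(result2)

    # ---- random baseline with matching per-region counts
    all_regions = regions1 + regions2
    random_result = SelectionResult()
    if do_random and proposed.n_tags:
        random_result = random_selection(
            all_regions, proposed.counts_per_region(), train, quality, array,
            seed=cfg.seed, probes=probes, proposed=proposed.keys_per_region(),
            maf_min=cfg.maf_min, missingness_max=cfg.missingness_max,
            site_list=site_list,
        )

    # ---- evaluation of the three designs on the held-out panel
    report = None
    targets_eval: list[VariantKey] = []
    seen = set()
    for state in states1 + states2:
        for v in state.tagsets.s1:
            if v not in seen:
                seen.add(v)
                targets_eval.append(v)
    if do_evaluate and test is not None and targets_eval:
        designs = {"base": list(array)}
        if do_random:
            designs["random"] = list(array) + random_result.keys
        designs["proposed"] = list(array) + proposed.keys
        report = evaluate_designs(test, train, designs, targets_eval, window=cfg.flank)

    result = PipelineResult(
        proposed=proposed, random=random_result, report=report,
        regions1=regions1, regions2=regions2,
        qualifications=qualifications, targets=targets_eval,
    )
    if write_outputs:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: PipelineConfig, result: PipelineResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_selection(result.proposed, out / "selection.tsv")
    io.write_selection(result.random, out / "random_selection.tsv")
    result.qualifications.to_csv(out / "regions_setting1.tsv", sep="\t", index=False)
    region_rows = [
        {"region_id": r.id, "chrom": r.chrom, "start": r.start, "end": r.end,
         "setting": r.setting, "n_members": len(r.members),
         "n_targets": len(r.targets)}
        for r in result.regions1 + result.regions2
    ]
    pd.DataFrame(region_rows).to_csv(out / "regions.tsv", sep="\t", index=False)
    if result.report is not None:
        result.report.per_variant.to_csv(out / "report_per_variant.tsv",
                                         sep="\t", index=False)
        result.report.aggregate(bins=cfg.maf_bins).to_csv(
            out / "report_summary.tsv", sep="\t", index=False
        )
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    logger.info(
        "pipeline done: %d proposed tags (%d probes), %d random tags",
        result.proposed.n_tags, result.proposed.n_probes, result.random.n_tags,
    )
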