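"""Compare array designs by surrogate imputation quality on held-out samples.

A "design" is a tag set (the base array plus zero or more add-ons).  Every
target variant is imputed from each design's tags near it, and summarised by
the INFO-style dosage-variance score and the squared correlation with the
held-out truth, aggregated per MAF bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    HaplotypePanel,
    ImputationQualityTable,
    UndefinedScoreError,
    ValidationError,
    VariantKey,
)
from .impute import best_tag_impute, ground_truth_r2, info_score

DEFAULT_MAF_BINS = (0.01, 0.05, 0.1, 0.5)


@dataclass
class EvaluationReport:
    """Per-variant imputation metrics for each design, plus aggregation."""

    per_variant: pd.DataFrame  # chrom,pos,ref,alt,design,quality,r2,maf

    def aggregate(
        self,
        bins: tuple[float, ...] = DEFAULT_MAF_BINS,
        percentile_bins: int | None = None,
    ) -> pd.DataFrame:
        """Mean quality/r2, SE and >0.8 fraction per design and MAF bin.

        ``percentile_bins`` switches to equal-count MAF bins (as in
        percentile-binned reporting) instead of the fixed edges.
        """
        df = self.per_variant.copy()
        if percentile_bins is not None:
            df["maf_bin"] = pd.qcut(df["maf"], q=percentile_bins, duplicates="drop")
        else:
            df["maf_bin"] = pd.cut(df["maf"], bins=list(bins))
        grouped = df.groupby(["design", "maf_bin"], observed=True)
        out = grouped.agg(
            n=("quality", "size"),
            mean_quality=("quality", "mean"),
            se_quality=("quality", "sem"),
            mean_r2=("r2", "mean"),
            se_r2=("r2", "sem"),
            frac_above=("quality", lambda q: float(np.mean(q > 0.8))),
        ).reset_index()
        out["maf_bin"] = out["maf_bin"].astype(str)
        return out

    def mean_quality(self, design: str) -> float:
        sel = self.per_variant[self.per_variant["design"] == design]
        return float(sel["quality"].mean())


def evaluate_designs(
    test_panel: HaplotypePanel,
    train_panel: HaplotypePanel,
    designs: dict[str, list[VariantKey]],
    targets: list[VariantKey],
    window: int = 5000,
) -> EvaluationReport:
    """Impute every target under every design and collect quality metrics.

    The first design is the base array; every other design must contain it.
    Targets that are themselves on a design are imputed perfectly by
    construction (the tag search includes them).
    """
    names = list(designs)
    if not names:
        raise ValidationError("no designs supplied")
    base = set(designs[names[0]])
    for name in names[1:]:
        if not base <= set(designs[name]):
            raise ValidationError(f"design {name!r} does not contain the base array")

    by_design_chrom: dict[str, dict[str, list[VariantKey]]] = {}
    for name, tags in designs.items():
        per_chrom: dict[str, list[VariantKey]] = {}
        for t in sorted(set(tags)):
            per_chrom.setdefault(t.chrom, []).append(t)
        by_design_chrom[name] = per_chrom

    rows = []
    for v in targets:
        if v not in train_panel or v not in test_panel:
            continue
        truth = test_panel.dosages(v)
        maf = train_panel.maf(v)
        for name in names:
            near = [
                t for t in by_design_chrom[name].get(v.chrom, [])
                if abs(t.pos - v.pos) <= window
            ]
            res = best_tag_impute(train_panel, near, v, test_panel)
            try:
                q = info_score(res.dosages)
            except UndefinedScoreError:
                q = 0.0
            try:
                r2 = ground_truth_r2(res.dosages, truth)
            except UndefinedScoreError:
                r2 = float("nan")
            rows.append({
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "design": name, "quality": q, "r2": r2, "maf": maf,
            })
    return EvaluationReport(per_variant=pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "design", "quality", "r2", "maf"]
    ))


def tag_efficiency(
    report: EvaluationReport,
    base_design: str,
    addon_design: str,
    n_tags: int,
    n_probes: int,
    region_of: dict[VariantKey, str] | None = None,
    quality_tables: tuple[ImputationQualityTable, ImputationQualityTable] | None = None,
) -> dict[str, float]:
    """Per-tag/per-probe counts of targets improved by an add-on design.

    Reports targets with any quality improvement and targets lifted above
    0.8, each per tag and per probe; SE across regions when ``region_of`` is
    given; and, when two per-panel quality tables are supplied, the fraction
    of improved targets attributed to each panel by the higher score.
    """
    df = report.per_variant
    key_cols = ["chrom", "pos", "ref", "alt"]
    before = df[df["design"] == base_design].set_index(key_cols)["quality"]
    after = df[df["design"] == addon_design].set_index(key_cols)["quality"]
    joined = pd.DataFrame({"before": before, "after": after}).dropna()
    improved = joined[joined["after"] > joined["before"]]
    rescued = joined[(joined["after"] >= 0.8) & (joined["before"] < 0.8)]
    out: dict[str, float] = {
        "n_improved": float(len(improved)),
        "n_rescued": float(len(rescued)),
        "improved_per_tag": len(improved) / n_tags if n_tags else float("nan"),
        "improved_per_probe": len(improved) / n_probes if n_probes else float("nan"),
        "rescued_per_tag": len(rescued) / n_tags if n_tags else float("nan"),
        "rescued_per_probe": len(rescued) / n_probes if n_probes else float("nan"),
    }
    if region_of is not None and len(improved):
        keys = [VariantKey(c, p, r, a) for c, p, r, a in improved.index]
        regions = pd.Series([region_of.get(k, "?") for k in keys])
        per_region = regions.value_counts()
        out["improved_per_region_se"] = float(per_region.sem()) if len(per_region) > 1 else 0.0
    if quality_tables is not None and len(improved):
        qa, qb = quality_tables
        labels = []
        for c, p, r, a in improved.index:
            k = VariantKey(c, p, r, a)
            ra, rb = qa.get(k), qb.get(k)
            if ra is None and rb is None:
                continue
            if rb is None or (ra is not None and ra.quality >= rb.quality):
                labels.append("A")
            else:
                labels.append("B")
        if labels:
            out["frac_panel_a"] = labels.count("A") / len(labels)
            out["frac_panel_b"] = labels.count("B") / len(labels)
    return out
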