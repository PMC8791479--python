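"""Desk-scale surrogate for reference-panel imputation.

Real array evaluation pipelines phase the test cohort and impute masked sites
with a Li-Stephens-class HMM.  For ranking array designs a much smaller model
suffices: each hidden target variant is predicted from the single tag in
strongest LD (by MI) with it in the training panel, using the training-panel
conditional allele frequencies.  This keeps the evaluator deterministic and
fast while preserving the quantity that matters for design comparison - how
well the chosen tags carry information about the targets.

Quality is summarised by a MaCH/minimac-style dosage-variance ratio
("INFO score"): Var(dosage) / (2 p (1 - p)) with p the dosage-implied allele
frequency, clipped to [0, 1].  Ground-truth accuracy is the squared Pearson
correlation between imputed and true dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    MISSING,
    HaplotypePanel,
    ImputationQualityTable,
    QualityRecord,
    UndefinedScoreError,
    VariantKey,
)
from .ld import mutual_information
from .core import InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class ImputationResult:
    """Per-sample expected alt-allele dosages for one target variant."""

    dosages: np.ndarray  # in [0, 2], length = n test samples
    tag: VariantKey | None  # best tag used, None if unconditional
    untagged: bool


def best_tag_impute(
    train: HaplotypePanel,
    tags: list[VariantKey],
    target: VariantKey,
    test: HaplotypePanel,
) -> ImputationResult:
    """Predict test-panel dosages of ``target`` from its best training tag.

    The tag with maximal MI against the target in ``train`` is chosen; each
    test haplotype contributes the training conditional frequency
    P(target = 1 | tag allele).  With no usable tag the unconditional
    frequency is used and the result is flagged untagged.  Empty conditional
    strata fall back to the unconditional frequency.
    """
    usable: list[tuple[float, VariantKey]] = []
    for t in tags:
        if t not in train or t not in test:
            continue
        try:
            usable.append((mutual_information(train, t, target), t))
        except InsufficientDataError:
            continue
    p_uncond = train.alt_freq(target)
    if not usable:
        dos = np.full(test.n_samples, 2.0 * p_uncond)
        return ImputationResult(dosages=dos, tag=None, untagged=True)
    # deterministic tie-break: highest MI, then genomic order
    usable.sort(key=lambda mt: (-mt[0], mt[1]))
    best = usable[0][1]

    x = train.row(best)
    y = train.row(target)
    mask = (x != MISSING) & (y != MISSING)
    cond = {}
    for a in (0, 1):
        sel = mask & (x == a)
        n_a = int(sel.sum())
        cond[a] = float(y[sel].mean()) if n_a > 0 else p_uncond

    test_row = test.row(best).astype(float)
    hap_prob = np.where(
        test_row == MISSING, p_uncond,
        np.where(test_row == 1, cond[1], cond[0]),
    )
    dosages = hap_prob[0::2] + hap_prob[1::2]
    return ImputationResult(dosages=dosages, tag=best, untagged=False)


def info_score(dosages: np.ndarray) -> float:
    """Dosage-variance-ratio imputation quality in [0, 1].

    Raises :class:`UndefinedScoreError` when the dosage-implied allele
    frequency is 0 or 1 (zero expected variance).
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise UndefinedScoreError("no dosages")
    p_hat = float(d.mean()) / 2.0
    expected = 2.0 * p_hat * (1.0 - p_hat)
    if expected <= 0.0:
        raise UndefinedScoreError("zero expected dosage variance")
    return float(np.clip(d.var() / expected, 0.0, 1.0))


def ground_truth_r2(dosages: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation between imputed and true dosages."""
    d = np.asarray(dosages, dtype=float)
    t = np.asarray(truth, dtype=float)
    if d.shape != t.shape:
        raise ValueError("dosage and truth vectors differ in length")
    mask = ~(np.isnan(d) | np.isnan(t))
    d, t = d[mask], t[mask]
    if d.size < 2 or d.std() == 0.0 or t.std() == 0.0:
        raise UndefinedScoreError("zero variance in dosage or truth vector")
    r = float(np.corrcoef(d, t)[0, 1])
    return r * r


def merge_panel_qualities(
    qa: ImputationQualityTable, qb: ImputationQualityTable
) -> ImputationQualityTable:
    """Per variant keep the record with the higher quality score.

    Ties go to the first table; variants present in only one table pass
    through unchanged.
    """
    merged: dict[VariantKey, QualityRecord] = dict(qa.records)
    for key, rec in qb.records.items():
        prev = merged.get(key)
        if prev is None or rec.quality > prev.quality:
            merged[key] = rec
    return ImputationQualityTable(merged)


def quality_from_surrogate(
    train: HaplotypePanel,
    test: HaplotypePanel,
    array_tags: list[VariantKey],
    targets: list[VariantKey],
    window: int = 5000,
    panel_label: str = "internal",
) -> ImputationQualityTable:
    """Build an imputation-quality table by imputing every target from the array.

    Each target is imputed on the test panel using the array tags within
    ``window`` bp; undefined scores are recorded as 0.
    """
    by_chrom: dict[str, list[VariantKey]] = {}
    for t in sorted(array_tags):
        by_chrom.setdefault(t.chrom, []).append(t)
    records: dict[VariantKey, QualityRecord] = {}
    for v in targets:
        near = [
            t for t in by_chrom.get(v.chrom, [])
            if abs(t.pos - v.pos) <= window and t != v
        ]
        res = best_tag_impute(train, near, v, test)
        try:
            q = info_score(res.dosages)
        except UndefinedScoreError:
            q = 0.0
        records[v] = QualityRecord(quality=q, maf=train.maf(v), panel=panel_label)
    return ImputationQualityTable(records)
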