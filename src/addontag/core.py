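"""Core data model: variant identity, haplotype matrices, probe and quality records.

The whole package operates on phased biallelic SNVs.  A variant is identified
by ``(chrom, pos, ref, alt)`` with a 1-based position, matching VCF
conventions; all interval arithmetic elsewhere in the package is 1-based
closed, with BED conversion happening at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np

BASES = frozenset("ACGT")

#: sentinel for a missing haplotype allele in the int8 matrix
MISSING = -1

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AddonTagError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(AddonTagError):
    """Malformed or inconsistent input."""


class EmptyPanelError(AddonTagError):
    """No variants survived reading/filtering a genotype file."""


class InsufficientDataError(AddonTagError):
    """Too few observations to compute the requested statistic."""


class UndefinedScoreError(AddonTagError):
    """A quality score is undefined (zero variance, no data)."""


class VariantKey(NamedTuple):
    """Identity of a biallelic SNV: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str


def validate_key(v: VariantKey) -> VariantKey:
    """Check the VariantKey invariants, raising :class:`ValidationError` on failure."""
    if v.ref not in BASES or v.alt not in BASES:
        raise ValidationError(f"{v}: ref/alt must be single bases in ACGT")
    if v.ref == v.alt:
        raise ValidationError(f"{v}: ref equals alt")
    if v.pos < 1:
        raise ValidationError(f"{v}: position must be >= 1")
    return v


def probes_required(v: VariantKey) -> int:
    """Number of Illumina Infinium probes needed to assay a SNV.

    A/T and C/G substitutions are strand-ambiguous (the two alleles are
    complementary) and need two bead types; every other substitution needs one.
    """
    return 2 if COMPLEMENT[v.ref] == v.alt else 1


def is_autosome(chrom: str) -> bool:
    """True for numeric chromosome labels, with or without a ``chr`` prefix."""
    label = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return label.isdigit()


@dataclass(frozen=True)
class ProbeInfo:
    """Probe annotation for one candidate tag: design score and probe count."""

    probeability: float
    n_probes: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.probeability <= 1.0:
            raise ValidationError(f"probeability {self.probeability} outside [0, 1]")
        if self.n_probes not in (1, 2):
            raise ValidationError(f"n_probes must be 1 or 2, got {self.n_probes}")

    @classmethod
    def for_variant(cls, v: VariantKey, probeability: float) -> "ProbeInfo":
        return cls(probeability=probeability, n_probes=probes_required(v))


class QualityRecord(NamedTuple):
    """Per-variant imputation quality: INFO-style score, MAF and source panel."""

    quality: float
    maf: float
    panel: str


@dataclass
class ImputationQualityTable:
    """Per-variant imputation-quality records keyed by :class:`VariantKey`."""

    records: dict[VariantKey, QualityRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, rec in self.records.items():
            if not 0.0 <= rec.quality <= 1.0:
                raise ValidationError(f"{key}: quality {rec.quality} outside [0, 1]")
            if not 0.0 <= rec.maf <= 0.5:
                raise ValidationError(f"{key}: maf {rec.maf} outside [0, 0.5]")

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.records

    def __len__(self) -> int:
        return len(self.records)

    def get(self, key: VariantKey) -> QualityRecord | None:
        return self.records.get(key)

    def quality(self, key: VariantKey, default: float = 0.0) -> float:
        rec = self.records.get(key)
        return rec.quality if rec is not None else default


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix over biallelic SNVs.

    ``haplotypes`` has shape ``(n_variants, n_haplotypes)`` with int8 entries
    0 (ref), 1 (alt) or :data:`MISSING`.  Columns ``2i`` and ``2i + 1`` are the
    two haplotypes of sample ``i``.  Variants are kept sorted by
    ``(chrom, pos)``.
    """

    variants: list[VariantKey]
    haplotypes: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != len(self.variants):
            raise ValidationError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"{len(self.variants)} variants"
            )
        if self.haplotypes.shape[1] != 2 * len(self.sample_ids):
            raise ValidationError("haplotype count must equal 2 x sample count")
        order = sorted(range(len(self.variants)),
                       key=lambda i: (self.variants[i].chrom, self.variants[i].pos))
        if order != list(range(len(self.variants))):
            self.variants = [self.variants[i] for i in order]
            self.haplotypes = self.haplotypes[order]
        self._index = {v: i for i, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValidationError("duplicate variant keys in panel")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, v: VariantKey) -> bool:
        return v in self._index

    def index(self, v: VariantKey) -> int:
        try:
            return self._index[v]
        except KeyError:
            raise KeyError(f"variant {v} not in panel") from None

    def row(self, v: VariantKey) -> np.ndarray:
        return self.haplotypes[self.index(v)]

    def missingness(self, v: VariantKey) -> float:
        row = self.row(v)
        return float(np.mean(row == MISSING))

    def alt_freq(self, v: VariantKey) -> float:
        """Alt-allele frequency over non-missing haplotypes."""
        row = self.row(v)
        obs = row[row != MISSING]
        if obs.size == 0:
            raise InsufficientDataError(f"{v}: all haplotype entries missing")
        return float(np.mean(obs))

    def maf(self, v: VariantKey) -> float:
        p = self.alt_freq(v)
        return min(p, 1.0 - p)

    def dosages(self, v: VariantKey) -> np.ndarray:
        """Per-sample alt-allele dosage (0/1/2); NaN where either haplotype is missing."""
        row = self.row(v).astype(float)
        row[row == MISSING] = np.nan
        return row[0::2] + row[1::2]

    def subset(self, keys: Iterable[VariantKey]) -> "HaplotypePanel":
        idx = [self.index(k) for k in keys]
        return HaplotypePanel(
            variants=[self.variants[i] for i in idx],
            haplotypes=self.haplotypes[idx].copy(),
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "HaplotypePanel":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        cols: list[int] = []
        for s in wanted:
            if s not in pos:
                raise KeyError(f"sample {s} not in panel")
            cols.extend((2 * pos[s], 2 * pos[s] + 1))
        return HaplotypePanel(
            variants=list(self.variants),
            haplotypes=self.haplotypes[:, cols].copy(),
            sample_ids=wanted,
        )

    def variants_in(self, chrom: str, start: int, end: int) -> list[VariantKey]:
        """Member variants within a 1-based closed interval."""
        return [v for v in self.variants if v.chrom == chrom and start <= v.pos <= end]
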