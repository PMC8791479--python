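"""Readers and writers for every external file the tool touches.

Genotypes come in as VCF (read through cyvcf2), tag manifests / probe tables /
imputation-quality tables as headered TSV, and region lists as BED.  BED's
0-based half-open intervals are converted to the internal 1-based closed
convention at this boundary and back on output.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    BASES,
    MISSING,
    EmptyPanelError,
    HaplotypePanel,
    ImputationQualityTable,
    ProbeInfo,
    QualityRecord,
    ValidationError,
    VariantKey,
    validate_key,
)

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]  # chrom, start, end -- 1-based closed


def read_panel(
    vcf_path: str | Path,
    missingness_max: float = 0.5,
    exclude: Sequence[Interval] | None = None,
) -> HaplotypePanel:
    """Read phased biallelic SNVs from a VCF into a :class:`HaplotypePanel`.

    Multiallelic sites and non-SNVs are dropped, as are variants whose
    haplotype missingness exceeds ``missingness_max`` and variants inside any
    ``exclude`` interval (e.g. pseudoautosomal regions).  Unphased
    heterozygotes are pseudo-phased deterministically with the alt allele on
    the first haplotype; genotypes with any missing allele are treated as
    fully missing.
    """
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise OSError(f"cannot read VCF {vcf_path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    variants: list[VariantKey] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if ref not in BASES or alt not in BASES:
            continue
        key = VariantKey(str(rec.CHROM), int(rec.POS), ref, alt)
        if exclude and any(
            c == key.chrom and s <= key.pos <= e for c, s, e in exclude
        ):
            continue
        row = np.empty(2 * len(sample_ids), dtype=np.int8)
        for si, gt in enumerate(rec.genotypes):
            a0, a1 = int(gt[0]), int(gt[1])
            phased = bool(gt[2])
            if a0 < 0 or a1 < 0:
                a0 = a1 = MISSING
            elif not phased and a0 + a1 == 1:
                a0, a1 = 1, 0  # deterministic pseudo-phasing
            row[2 * si] = a0
            row[2 * si + 1] = a1
        if np.mean(row == MISSING) > missingness_max:
            continue
        variants.append(key)
        rows.append(row)
    if not variants:
        raise EmptyPanelError(f"no biallelic SNVs retained from {vcf_path}")
    return HaplotypePanel(variants, np.vstack(rows), sample_ids)


def write_panel(panel: HaplotypePanel, out_path: str | Path) -> None:
    """Write a panel as an uncompressed phased VCF (GT only)."""
    chroms = sorted({v.chrom for v in panel.variants})
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            max_pos = max(v.pos for v in panel.variants if v.chrom == c)
            fh.write(f"##contig=<ID={c},length={max_pos + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for v, row in zip(panel.variants, panel.haplotypes):
            alleles = ["." if a == MISSING else str(int(a)) for a in row]
            gts = "\t".join(
                f"{alleles[2 * i]}|{alleles[2 * i + 1]}"
                for i in range(panel.n_samples)
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _key_from_row(row: pd.Series) -> VariantKey:
    return validate_key(
        VariantKey(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
    )


def read_manifest(path: str | Path) -> list[VariantKey]:
    """Read an array tag manifest TSV (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    keys = [_key_from_row(r) for _, r in df.iterrows()]
    if len(set(keys)) != len(keys):
        raise ValidationError(f"duplicate variants in manifest {path}")
    return keys


def read_probe_table(path: str | Path) -> dict[VariantKey, ProbeInfo]:
    """Read probe annotations TSV (chrom, pos, ref, alt, probeability)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    probes: dict[VariantKey, ProbeInfo] = {}
    for _, row in df.iterrows():
        key = _key_from_row(row)
        if key in probes:
            raise ValidationError(f"duplicate variant {key} in probe table {path}")
        probes[key] = ProbeInfo.for_variant(key, float(row["probeability"]))
    return probes


def read_quality_table(path: str | Path) -> ImputationQualityTable:
    """Read an imputation-quality TSV (chrom, pos, ref, alt, info, maf, panel)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "panel": str})
    records: dict[VariantKey, QualityRecord] = {}
    for _, row in df.iterrows():
        key = _key_from_row(row)
        if key in records:
            raise ValidationError(f"duplicate variant {key} in quality table {path}")
        records[key] = QualityRecord(
            quality=float(row["info"]), maf=float(row["maf"]), panel=str(row["panel"])
        )
    return ImputationQualityTable(records)


def write_quality_table(table: ImputationQualityTable, path: str | Path) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt,
         "info": rec.quality, "maf": rec.maf, "panel": rec.panel}
        for k, rec in sorted(table.records.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "info", "maf", "panel"]).to_csv(
        path, sep="\t", index=False
    )


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED intervals, converting 0-based half-open to 1-based closed."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            if end0 <= start0:
                raise ValidationError(f"empty BED interval in {path}: {line!r}")
            intervals.append((chrom, start0 + 1, end0))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write 1-based closed intervals back out as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_tables(
    manifest_path: str | Path,
    probe_path: str | Path,
    quality_path: str | Path,
    regions_path: str | Path | None = None,
) -> tuple[list[VariantKey], dict[VariantKey, ProbeInfo], ImputationQualityTable, list[Interval]]:
    """Read the manifest, probe, quality and (optionally) region files together."""
    manifest = read_manifest(manifest_path)
    probes = read_probe_table(probe_path)
    quality = read_quality_table(quality_path)
    regions = read_bed(regions_path) if regions_path else []
    return manifest, probes, quality, regions


SELECTION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "setting", "region_id",
    "order", "n_probes", "probeability", "e_k",
]


def write_selection(result, out_path: str | Path) -> None:
    """Write a :class:`~addontag.select.SelectionResult` as a manifest TSV.

    Rows appear in acceptance order; an empty result yields a header-only file.
    """
    rows = []
    for acc in result.accepted:
        v = acc.key
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "setting": acc.setting, "region_id": acc.region_id, "order": acc.order,
            "n_probes": acc.score.n_probes, "probeability": acc.score.probeability,
            "e_k": acc.score.e_k,
        })
    pd.DataFrame(rows, columns=SELECTION_COLUMNS).to_csv(out_path, sep="\t", index=False)


def read_selection(path: str | Path) -> pd.DataFrame:
    """Read back a selection manifest written by :func:`write_selection`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SELECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"selection file {path} lacks columns {sorted(missing)}")
    return df


def selection_keys(df: pd.DataFrame) -> list[VariantKey]:
    return [_key_from_row(r) for _, r in df.iterrows()]


def read_haplogroup_tree(
    path: str | Path,
) -> tuple[dict[str, str | None], dict[str, list[VariantKey]]]:
    """Read a haplogroup marker table TSV.

    Columns: node, parent (empty for the root), marker_chrom, marker_pos,
    marker_ref, marker_alt; one row per marker SNP.  Returns the parent map
    and the node -> marker list map.
    """
    df = pd.read_csv(path, sep="\t", dtype={"node": str, "marker_chrom": str})
    parents: dict[str, str | None] = {}
    markers: dict[str, list[VariantKey]] = {}
    for _, row in df.iterrows():
        node = str(row["node"])
        parent = row["parent"]
        parent = None if pd.isna(parent) or parent == "" else str(parent)
        if node in parents and parents[node] != parent:
            raise ValidationError(f"node {node} has conflicting parents in {path}")
        parents[node] = parent
        key = validate_key(VariantKey(
            str(row["marker_chrom"]), int(row["marker_pos"]),
            str(row["marker_ref"]), str(row["marker_alt"]),
        ))
        markers.setdefault(node, []).append(key)
    return parents, markers


def write_probe_table(probes: dict[VariantKey, ProbeInfo], path: str | Path) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt,
         "probeability": info.probeability}
        for k, info in sorted(probes.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "probeability"]).to_csv(
        path, sep="\t", index=False
    )


def write_manifest(keys: Iterable[VariantKey], path: str | Path) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt}
        for k in sorted(keys)
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )
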