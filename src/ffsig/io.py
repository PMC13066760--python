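"""Readers and writers for panels, count tables, VCFs and JSON reports.

Conventions: genomic coordinates are 1-based (as in VCF); count tables carry
no coordinates and are keyed by ``snp_id``; in phased VCF genotypes the
first allele of ``a|b`` maps to haplotype 1 (M1 for the mother, P1 for the
father).  Getting the M1/M2 orientation wrong flips every Type-4 sign, so
the caller layer warns when a nominally normal sample shows both Type-4
subtypes strongly signed the same way.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from . import __version__
from .panel import Panel, SnpLocus, build_panel
from .signature import ALLELES, AlleleCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_panel_tsv",
    "write_panel_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_phased_vcf",
    "write_report",
]

_PANEL_COLUMNS = ("snp_id", "chrom", "pos", "M1", "M2", "P1", "P2", "is_y")
_COUNT_COLUMNS = ("snp_id",) + ALLELES


def write_panel_tsv(panel: Panel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PANEL_COLUMNS) + "\n")
        for locus in panel:
            if locus.is_y_locus:
                fields = (locus.snp_id, locus.chrom, str(locus.pos),
                          ".", ".", ".", ".", "1")
            else:
                fields = (
                    locus.snp_id, locus.chrom, str(locus.pos),
                    *locus.maternal_hap, *locus.paternal_hap, "0",
                )
            fh.write("\t".join(fields) + "\n")


def read_panel_tsv(path) -> Panel:
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _PANEL_COLUMNS:
            raise ValueError(
                f"{path}: expected header {'/'.join(_PANEL_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_PANEL_COLUMNS):
                raise ValueError(f"{path}:{lineno}: malformed row")
            snp_id, chrom, pos, m1, m2, p1, p2, is_y = fields
            if is_y == "1":
                loci.append(
                    SnpLocus(snp_id, chrom, int(pos), is_y_locus=True)
                )
            else:
                loci.append(
                    SnpLocus(snp_id, chrom, int(pos), (m1, m2), (p1, p2))
                )
    return build_panel(loci)


def write_counts_tsv(table: AlleleCountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COUNT_COLUMNS) + "\n")
        for snp_id in table.snp_ids:
            row = table.counts(snp_id)
            cells = [
                str(int(c)) if float(c).is_integer() else repr(float(c))
                for c in row
            ]
            fh.write("\t".join([snp_id, *cells]) + "\n")


def read_counts_tsv(path) -> AlleleCountTable:
    counts: Dict[str, Tuple[float, ...]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COUNT_COLUMNS:
            raise ValueError(
                f"{path}: expected header {'/'.join(_COUNT_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: malformed row")
            snp_id = fields[0]
            try:
                row = tuple(float(c) for c in fields[1:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if any(c < 0 for c in row):
                raise ValueError(f"{path}:{lineno}: negative count")
            if sum(row) == 0:
                logger.warning("%s:%d: zero-depth SNP %s", path, lineno, snp_id)
            counts[snp_id] = row
    return AlleleCountTable(counts)


def read_phased_vcf(path, mother_id: str, father_id: str) -> Panel:
    """Build a panel from phased parental genotypes in a VCF.

    Only biallelic SNV records with both parents fully phased are used;
    skipped records are counted and logged.  The first allele of a phased
    genotype is haplotype 1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        mother_idx = samples.index(mother_id)
        father_idx = samples.index(father_id)
    except ValueError as exc:
        raise ValueError(
            f"sample ids {mother_id!r}/{father_id!r} not in VCF "
            f"(found {samples})"
        ) from exc

    loci = []
    skipped = 0
    for record in vcf:
        alleles = [record.REF, *record.ALT]
        if len(alleles) != 2 or any(len(a) != 1 for a in alleles):
            skipped += 1
            continue
        gts = record.genotypes  # [a, b, phased] per sample
        gm, gf = gts[mother_idx], gts[father_idx]
        if not (gm[2] and gf[2]) or -1 in gm[:2] or -1 in gf[:2]:
            skipped += 1
            continue
        snp_id = record.ID or f"{record.CHROM}:{record.POS}"
        loci.append(
            SnpLocus(
                snp_id=snp_id,
                chrom=record.CHROM,
                pos=record.POS,
                maternal_hap=(alleles[gm[0]], alleles[gm[1]]),
                paternal_hap=(alleles[gf[0]], alleles[gf[1]]),
            )
        )
    if skipped:
        logger.info("%s: skipped %d unusable records", path, skipped)
    if not loci:
        raise ValueError(f"{path}: no usable phased biallelic SNVs")
    return build_panel(loci)


def write_report(
    path,
    call=None,
    signature=None,
    regression=None,
    config: Optional[dict] = None,
) -> dict:
    """Self-contained JSON report; returns the serialised dict."""
    report = {
        "tool": "ffsig",
        "version": __version__,
        "config": config or {},
        "signature": signature.to_dict() if signature is not None else None,
        "regression": (
            regression.to_dict() if regression is not None else None
        ),
        "call": call.to_dict() if call is not None else None,
    }
    if regression is None:
        report["notes"] = ["regression section absent (no maternal sample?)"]
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    return report
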