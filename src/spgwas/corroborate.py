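"""Cross-referencing of association hits with bulk-segregant regions.

:func:`overlap` checks which significant association SNPs fall inside called
BSA regions (same chromosome, boundaries inclusive on both ends, 1-based
coordinates on both sides); :func:`annotate_nearby_genes` lists gene models
from a GFF3 file whose span intersects a window (default 150 kb) around each
SNP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class OverlapReport:
    """Per-SNP region matches plus run totals."""

    table: pd.DataFrame  # chrom, pos, p_value, region_left, region_right, overlapped
    n_snps: int
    n_regions: int
    n_overlaps: int


def overlap(snps: pd.DataFrame, regions) -> OverlapReport:
    """Match significant SNPs against BSA regions.

    A SNP overlaps a region iff they share a chromosome label and
    ``left <= pos <= right`` (inclusive boundaries).  If both inputs are
    nonempty and their chromosome label sets are disjoint, the coordinate
    conventions likely differ and an error naming the labels is raised.
    """
    from .bsa import regions_to_frame

    if not isinstance(regions, pd.DataFrame):
        regions = regions_to_frame(list(regions))
    snp_chroms = set(map(str, snps["chrom"])) if len(snps) else set()
    reg_chroms = set(map(str, regions["chrom"])) if len(regions) else set()
    if snp_chroms and reg_chroms and not (snp_chroms & reg_chroms):
        raise ValueError(
            "chromosome labels of SNPs and regions do not intersect: "
            f"SNPs use {sorted(snp_chroms)[:5]}, regions use {sorted(reg_chroms)[:5]}"
        )
    rows = []
    for _, snp in snps.iterrows():
        hit = None
        for _, reg in regions.iterrows():
            if str(reg["chrom"]) == str(snp["chrom"]) and reg["left_pos"] <= snp["pos"] <= reg["right_pos"]:
                hit = reg
                break
        rows.append(
            {
                "chrom": snp["chrom"],
                "pos": snp["pos"],
                "p_value": snp.get("p_value", np.nan),
                "region_left": hit["left_pos"] if hit is not None else pd.NA,
                "region_right": hit["right_pos"] if hit is not None else pd.NA,
                "overlapped": hit is not None,
            }
        )
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "p_value", "region_left", "region_right", "overlapped"]
    )
    n_over = int(table["overlapped"].sum()) if len(table) else 0
    return OverlapReport(
        table=table, n_snps=len(snps), n_regions=len(regions), n_overlaps=n_over
    )


def _read_genes(gff_path) -> pd.DataFrame:
    """Parse gene features from a GFF3 file, skipping malformed lines."""
    from gffutils.feature import feature_from_line

    genes = []
    n_bad = 0
    for lineno, line in enumerate(Path(gff_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            if len(fields) != 9 or int(fields[3]) > int(fields[4]):
                raise ValueError("not a 9-column GFF3 feature line")
            feat = feature_from_line(line)
        except Exception:
            n_bad += 1
            warnings.warn(f"{gff_path}:{lineno}: malformed GFF line skipped", stacklevel=2)
            continue
        if feat.featuretype != "gene":
            continue
        gene_id = feat.attributes.get("ID", feat.attributes.get("Name", [f"gene_{lineno}"]))[0]
        genes.append(
            {"gene_id": gene_id, "chrom": feat.seqid, "start": feat.start, "end": feat.end,
             "strand": feat.strand, "attributes": str(feat.attributes)}
        )
    if n_bad:
        logger.warning("%s: skipped %d malformed GFF lines", gff_path, n_bad)
    return pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand", "attributes"])


def annotate_nearby_genes(
    snps: pd.DataFrame, gff_path, window: int = 150_000
) -> pd.DataFrame:
    """Genes whose span intersects ``[pos - window, pos + window]`` per SNP.

    Distance is 0 when the SNP lies inside the gene span (relation
    ``"SNP in candidate"``), else the bp distance from the SNP to the nearest
    gene boundary (relation ``"nearby"``).
    """
    genes = _read_genes(gff_path)
    rows = []
    for _, snp in snps.iterrows():
        pos = int(snp["pos"])
        near = genes[
            (genes["chrom"].astype(str) == str(snp["chrom"]))
            & (genes["end"] >= pos - window)
            & (genes["start"] <= pos + window)
        ]
        for _, gene in near.iterrows():
            inside = gene["start"] <= pos <= gene["end"]
            distance = 0 if inside else min(abs(pos - gene["start"]), abs(pos - gene["end"]))
            rows.append(
                {
                    "chrom": snp["chrom"],
                    "pos": pos,
                    "gene_id": gene["gene_id"],
                    "gene_start": gene["start"],
                    "gene_end": gene["end"],
                    "distance": distance,
                    "relation": "SNP in candidate" if inside else "nearby",
                    "attributes": gene["attributes"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "gene_id", "gene_start", "gene_end",
                 "distance", "relation", "attributes"],
    )
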