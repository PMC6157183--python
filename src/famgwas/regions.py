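"""Genic/intergenic region construction and within-region LD pruning.

A region is either the interval covered by one gene or the gap between
two consecutive genes on a chromosome; only regions that contain at
least one genotyped SNP are kept, and each SNP belongs to every region
covering it.  SNPs upstream of the first gene or downstream of the last
gene fall into terminal ("telomeric") intergenic regions, emitted by
default.  Within a region, SNPs in strong linkage disequilibrium
(dosage r-squared above 0.5) are greedily removed before the joint
association test.  Strand is ignored throughout; regions are intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import GenotypeMatrix, chrom_sort_key

__all__ = ["GenomicRegion", "read_gene_bed", "build_regions", "ld_prune",
           "prune_regions", "regions_table"]


@dataclass
class GenomicRegion:
    region_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    kind: str  # genic | intergenic | intergenic_telomeric
    flank_gene_ids: tuple[str, ...] = ()
    snp_ids: list[str] = field(default_factory=list)
    pruned_snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region {self.region_id}: start > end")
        if self.kind not in {"genic", "intergenic", "intergenic_telomeric"}:
            raise ValueError(f"unknown region kind {self.kind!r}")


def read_gene_bed(path) -> pd.DataFrame:
    """Gene annotation from BED (0-based half-open on disk).

    Returns a DataFrame with 1-based inclusive ``start``/``end`` and a
    ``gene`` name, sorted by (chrom, start).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start0", "end0", "gene"], usecols=range(4),
        dtype={"chrom": str},
    )
    if (df["end0"] <= df["start0"]).any():
        raise ValueError("invalid BED intervals (end <= start)")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start0"].astype(int) + 1,
            "end": df["end0"].astype(int),
            "gene": df["gene"].astype(str),
        }
    )
    out = out.sort_values(
        by=["chrom", "start", "end"],
        key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
    )
    return out.reset_index(drop=True)


def build_regions(
    genes: pd.DataFrame,
    G: GenotypeMatrix,
    merge_overlapping: bool = False,
    emit_telomeric: bool = True,
) -> list[GenomicRegion]:
    """Genic and intergenic regions that contain genotyped SNPs.

    ``genes``: DataFrame with 1-based ``chrom/start/end/gene`` columns
    (see :func:`read_gene_bed`).  One genic region per gene and one
    intergenic region per positive gap between consecutive genes (by
    sorted start); overlapping genes are kept as distinct genic regions
    unless ``merge_overlapping``.  Regions without SNPs are omitted.
    """
    need = {"chrom", "start", "end", "gene"}
    if not need <= set(genes.columns):
        raise ValueError(f"gene table must have columns {sorted(need)}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("invalid gene intervals")
    snps = G.snps
    regions: list[GenomicRegion] = []

    def add(region: GenomicRegion) -> None:
        sel = snps[
            (snps["chrom"] == region.chrom)
            & (snps["bp"] >= region.start)
            & (snps["bp"] <= region.end)
        ]
        if len(sel):
            region.snp_ids = sel["snp_id"].tolist()
            regions.append(region)

    for chrom, sub in genes.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"]).reset_index(drop=True)
        if not sub["start"].is_monotonic_increasing:
            raise ValueError(f"gene intervals unsorted on {chrom}")
        if merge_overlapping:
            merged = []
            for _, g in sub.iterrows():
                if merged and g["start"] <= merged[-1]["end"]:
                    merged[-1]["end"] = max(merged[-1]["end"], g["end"])
                    merged[-1]["gene"] += "+" + g["gene"]
                else:
                    merged.append(dict(g))
            sub = pd.DataFrame(merged)
        for _, g in sub.iterrows():
            add(
                GenomicRegion(
                    region_id=f"genic:{g['gene']}",
                    chrom=chrom,
                    start=int(g["start"]),
                    end=int(g["end"]),
                    kind="genic",
                    flank_gene_ids=(g["gene"],),
                )
            )
        # gaps between consecutive genes (by running max end)
        run_end = int(sub["end"].iloc[0])
        prev_gene = sub["gene"].iloc[0]
        for _, g in sub.iloc[1:].iterrows():
            gap_lo, gap_hi = run_end + 1, int(g["start"]) - 1
            if gap_lo <= gap_hi:
                add(
                    GenomicRegion(
                        region_id=f"intergenic:{prev_gene}|{g['gene']}",
                        chrom=chrom,
                        start=gap_lo,
                        end=gap_hi,
                        kind="intergenic",
                        flank_gene_ids=(prev_gene, g["gene"]),
                    )
                )
            if int(g["end"]) >= run_end:
                run_end = int(g["end"])
                prev_gene = g["gene"]
        if emit_telomeric:
            chrom_snps = snps[snps["chrom"] == chrom]
            first_start = int(sub["start"].iloc[0])
            if first_start > 1:
                add(
                    GenomicRegion(
                        region_id=f"intergenic:{chrom}:telomere|{sub['gene'].iloc[0]}",
                        chrom=chrom,
                        start=1,
                        end=first_start - 1,
                        kind="intergenic_telomeric",
                        flank_gene_ids=(sub["gene"].iloc[0],),
                    )
                )
            if len(chrom_snps):
                last_bp = int(chrom_snps["bp"].max())
                if last_bp > run_end:
                    add(
                        GenomicRegion(
                            region_id=f"intergenic:{prev_gene}|{chrom}:telomere",
                            chrom=chrom,
                            start=run_end + 1,
                            end=last_bp,
                            kind="intergenic_telomeric",
                            flank_gene_ids=(prev_gene,),
                        )
                    )
    return regions


def ld_prune(
    G: GenotypeMatrix, snp_ids: list[str], r2_max: float = 0.5
) -> list[str]:
    """Greedy left-to-right LD pruning on dosage correlation.

    SNPs are visited in base-pair order; a SNP is kept iff its squared
    Pearson correlation with every already-kept SNP is <= ``r2_max``
    (strictly greater is removed, so a pair at exactly the threshold
    survives).  Dosages must be complete (post-QC); a zero-variance
    column raises.  Deterministic, and idempotent by construction.
    """
    if not snp_ids:
        raise ValueError("no SNPs to prune")
    sub = G.select(snp_ids)
    order = np.argsort(sub.snps["bp"].to_numpy(), kind="stable")
    X = sub.dosages
    if np.isnan(X).any():
        raise ValueError("missing dosages; run QC before pruning")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [snp_ids[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance dosage columns {bad} (QC should remove)")
    kept: list[int] = []
    for j in order:
        ok = True
        for k in kept:
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return [sub.snps["snp_id"].iloc[j] for j in kept]


def prune_regions(
    regions: list[GenomicRegion], G: GenotypeMatrix, r2_max: float = 0.5
) -> list[GenomicRegion]:
    """Fill ``pruned_snp_ids`` of every region in place (returned too)."""
    for reg in regions:
        reg.pruned_snp_ids = ld_prune(G, reg.snp_ids, r2_max=r2_max)
    return regions


def regions_table(regions: list[GenomicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "kind": [r.kind for r in regions],
            "n_snps": [len(r.snp_ids) for r in regions],
            "n_pruned": [len(r.pruned_snp_ids) for r in regions],
        }
    )
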