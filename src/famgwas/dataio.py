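"""Genotype, phenotype and covariate input/output plus SNP-level QC.

Genotypes are stored as minor-allele dosages in {0, 1, 2} with ``NaN``
for missing calls; the minor allele is determined from the data itself,
so a site where REF is the rarer allele has its dosages complemented.
Coordinates are 1-based inclusive everywhere inside the package.

Phenotypes are triglyceride (TG) and HDL cholesterol levels (mg/dL)
measured at four clinic visits; visits 1-2 precede the fenofibrate
treatment and visits 3-4 follow it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "TRAITS",
    "VISITS",
    "PRE_VISITS",
    "POST_VISITS",
    "PHENO_COLUMNS",
    "read_genotypes",
    "qc_filter",
    "read_phenotypes",
    "write_phenotypes",
    "read_covariates",
    "write_covariates",
]

TRAITS = ("tg", "hdl")
VISITS = (1, 2, 3, 4)
PRE_VISITS = (1, 2)
POST_VISITS = (3, 4)
PHENO_COLUMNS = [f"{t}_v{v}" for t in TRAITS for v in VISITS]

_CHROM_ORDER = {str(c): c for c in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26})


def chrom_sort_key(chrom: str):
    c = str(chrom).removeprefix("chr")
    return (_CHROM_ORDER.get(c, 99), c)


@dataclass
class GenotypeMatrix:
    """n x m minor-allele dosage matrix with a SNP map.

    ``dosages``: float array, entries in {0, 1, 2} or NaN (missing).
    ``snps``: DataFrame with columns ``snp_id``, ``chrom``, ``bp``
    (1-based), one row per dosage column, sorted by (chrom, bp).
    """

    dosages: np.ndarray
    iids: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        if self.dosages.shape[0] != len(self.iids):
            raise ValueError("row count does not match iid list")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("column count does not match SNP map")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be 0, 1, 2 or missing")
        if (self.snps["bp"] <= 0).any():
            raise ValueError("bp positions must be positive (1-based)")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(j) != 1:
            raise KeyError(f"snp {snp_id!r} not present exactly once")
        return self.dosages[:, j[0]]

    def select(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: j for j, s in enumerate(self.snps["snp_id"])}
        idx = [pos[s] for s in snp_ids]
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.iids), self.snps.iloc[idx]
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        key = [
            (chrom_sort_key(c), bp)
            for c, bp in zip(self.snps["chrom"], self.snps["bp"])
        ]
        order = sorted(range(self.m), key=lambda j: key[j])
        return GenotypeMatrix(
            self.dosages[:, order], list(self.iids), self.snps.iloc[order]
        )


@dataclass
class QcReport:
    n_input: int = 0
    n_missing_removed: int = 0
    n_monomorphic_removed: int = 0
    n_rare_genotype_removed: int = 0
    removed: dict[str, str] = field(default_factory=dict)  # snp_id -> rule

    @property
    def n_kept(self) -> int:
        return (
            self.n_input
            - self.n_missing_removed
            - self.n_monomorphic_removed
            - self.n_rare_genotype_removed
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": list(self.removed),
                "rule": list(self.removed.values()),
            }
        )


# ---------------------------------------------------------------------------
# genotype readers


def read_genotypes(path, format: str = "vcf", strict_biallelic: bool = True,
                   iids: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read genotypes from a VCF (via cyvcf2) or PLINK .ped/.map text pair.

    For ``plink_text``, ``path`` is the ``.ped`` file or the common prefix.
    Dosages always count the minor allele as observed in this file; with
    ``strict_biallelic`` a multiallelic VCF record raises, otherwise it is
    skipped.  ``iids``, when given, must match the sample ids in the file
    (order is taken from the file); mismatches raise with the offenders.
    """
    if format == "vcf":
        g = _read_vcf(path, strict_biallelic)
    elif format == "plink_text":
        g = _read_ped_map(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if iids is not None:
        extra = sorted(set(g.iids) - set(iids))
        missing = sorted(set(iids) - set(g.iids))
        if extra or missing:
            raise ValueError(
                f"sample id mismatch: unexpected {extra}, absent {missing}"
            )
    return g.sorted_by_position()


def _minorize(alt_counts: np.ndarray) -> np.ndarray:
    """Flip ALT-allele counts to minor-allele counts where ALT is major."""
    out = alt_counts.astype(float)
    obs = ~np.isnan(out)
    if obs.any():
        freq = out[obs].sum() / (2 * obs.sum())
        if freq > 0.5:
            out[obs] = 2.0 - out[obs]
    return out


def _read_vcf(path, strict_biallelic: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    iids = list(vcf.samples)
    cols, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            if strict_biallelic:
                raise ValueError(
                    f"non-biallelic record at {var.CHROM}:{var.POS} "
                    f"({var.REF}->{var.ALT})"
                )
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        alt = np.asarray(var.gt_types, dtype=float)
        alt[alt == 3] = np.nan
        cols.append(_minorize(alt))
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "bp": int(var.POS),
            }
        )
    dos = (
        np.column_stack(cols) if cols else np.empty((len(iids), 0))
    )
    return GenotypeMatrix(dos, iids, pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"]))


def _read_ped_map(path) -> GenotypeMatrix:
    path = str(path)
    prefix = path[:-4] if path.endswith(".ped") else path
    snps = pd.read_csv(
        prefix + ".map",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str},
    )[["snp_id", "chrom", "bp"]]
    iids, allele_rows = [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            if not line.strip():
                continue
            tok = line.split()
            iids.append(tok[1])
            alleles = tok[6:]
            if len(alleles) != 2 * len(snps):
                raise ValueError(
                    f"individual {tok[1]}: expected {2 * len(snps)} alleles, "
                    f"got {len(alleles)}"
                )
            allele_rows.append(alleles)
    m = len(snps)
    alle = np.array(allele_rows, dtype=object).reshape(len(iids), m, 2)
    cols = []
    for j in range(m):
        pair = alle[:, j, :]
        obs = (pair != "0").all(axis=1)
        seen = sorted({a for a in pair[obs].ravel()})
        if len(seen) > 2:
            raise ValueError(f"snp {snps['snp_id'][j]}: more than 2 alleles")
        counts = {a: int((pair[obs] == a).sum()) for a in seen}
        # count the rarer observed allele; ties resolve to the later-sorted
        minor = min(seen, key=lambda a: (counts[a], seen.index(a))) if seen else None
        dos = np.full(len(iids), np.nan)
        if minor is not None:
            dos[obs] = (pair[obs] == minor).sum(axis=1)
        cols.append(dos)
    dosages = np.column_stack(cols) if cols else np.empty((len(iids), 0))
    return GenotypeMatrix(dosages, iids, snps)


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    g: GenotypeMatrix,
    max_missing: float = 0.0,
    rare_genotype_threshold: float = 0.05,
    maf_min: float | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """SNP-level quality control, applied in a fixed order.

    1. drop SNPs whose missing-call fraction exceeds ``max_missing``
       (default 0: any missing genotype removes the SNP);
    2. drop monomorphic SNPs (a single observed genotype class);
    3. for SNPs with exactly two observed genotype classes, drop the SNP
       when the rarer class frequency is below ``rare_genotype_threshold``.

    SNPs with three observed genotype classes are never removed by rule 3;
    the optional ``maf_min`` adds a conventional minor-allele-frequency
    filter on top (off by default).
    """
    rep = QcReport(n_input=g.m)
    keep = []
    for j in range(g.m):
        col = g.dosages[:, j]
        sid = g.snps["snp_id"].iloc[j]
        miss = np.isnan(col)
        if miss.mean() > max_missing:
            rep.n_missing_removed += 1
            rep.removed[sid] = "missing"
            continue
        obs = col[~miss]
        classes, counts = np.unique(obs, return_counts=True)
        if len(classes) <= 1:
            rep.n_monomorphic_removed += 1
            rep.removed[sid] = "monomorphic"
            continue
        if len(classes) == 2 and counts.min() / counts.sum() < rare_genotype_threshold:
            rep.n_rare_genotype_removed += 1
            rep.removed[sid] = "rare_genotype"
            continue
        if maf_min is not None:
            maf = obs.mean() / 2.0
            maf = min(maf, 1.0 - maf)
            if maf < maf_min:
                rep.removed[sid] = "maf"
                continue
        keep.append(j)
    if not keep:
        raise ValueError(
            "all SNPs removed by QC; review thresholds "
            f"(input {g.m}, removals {rep.removed})"
        )
    out = GenotypeMatrix(g.dosages[:, keep], list(g.iids), g.snps.iloc[keep])
    return out, rep


# ---------------------------------------------------------------------------
# phenotype / covariate tables


def read_phenotypes(path, iids: Sequence[str] | None = None) -> pd.DataFrame:
    """Longitudinal phenotype TSV: ``iid tg_v1..tg_v4 hdl_v1..hdl_v4``.

    Returns a DataFrame indexed by iid with the eight raw-scale columns;
    blank cells become NaN.  Raw values must be strictly positive (the
    downstream log-log transform is undefined otherwise) and unknown
    ids raise when ``iids`` is supplied.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"iid": str}, float_precision="round_trip"
    ).set_index("iid")
    missing_cols = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype table missing columns {missing_cols}")
    df = df[PHENO_COLUMNS].astype(float)
    bad = df.le(0)
    if bad.any().any():
        cell = [(i, c) for c in df.columns for i in df.index[bad[c]]]
        raise ValueError(f"nonpositive raw phenotype values at cells {cell[:10]}")
    if iids is not None:
        unknown = sorted(set(df.index) - set(iids))
        if unknown:
            raise ValueError(f"phenotype ids not in pedigree: {unknown}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="iid", float_format="%.17g")


def read_covariates(path, iids: Sequence[str] | None = None) -> pd.DataFrame:
    """Covariate TSV with columns ``iid age smoking`` (extras kept)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"iid": str}, float_precision="round_trip"
    ).set_index("iid")
    for col in ("age", "smoking"):
        if col not in df.columns:
            raise ValueError(f"covariate table missing column {col!r}")
    if df[["age", "smoking"]].isna().any().any():
        raise ValueError("missing covariate values after validation")
    if not df["smoking"].isin([0, 1]).all():
        raise ValueError("smoking must be binary 0/1")
    if iids is not None:
        unknown = sorted(set(df.index) - set(iids))
        if unknown:
            raise ValueError(f"covariate ids not in pedigree: {unknown}")
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="iid", float_format="%.17g")


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal uncompressed VCF v4.2.

    Dosage d is emitted as the ALT-allele count (REF=A, ALT=C,
    placeholders — the simulator tracks no sequence).  Columns where the
    stored allele is the major one in this sample are complemented on
    write so that reading the file back (minor-allele convention)
    reproduces the minor-allele dosages.
    """
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.iids)
            + "\n"
        )
        for j in range(g.m):
            col = g.dosages[:, j].copy()
            obs = ~np.isnan(col)
            if obs.any() and col[obs].sum() > obs.sum():  # ALT would be major
                col[obs] = 2.0 - col[obs]
            snp = g.snps.iloc[j]
            calls = "\t".join(
                "./." if np.isnan(v) else gt_code[v] for v in col
            )
            fh.write(
                f"{snp['chrom']}\t{snp['bp']}\t{snp['snp_id']}\tA\tC\t.\t.\t.\tGT\t"
                + calls
                + "\n"
            )
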