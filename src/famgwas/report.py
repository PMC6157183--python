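"""Multiple-testing correction, result tables, plot-ready outputs.

BH adjustment is applied separately within each analysis family (the
longitudinal SNP scan, the response SNP scan, the region scan); the
number of tests counts only units whose fit succeeded — failed fits
propagate as missing and do not enter the correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataio import chrom_sort_key

__all__ = ["bh_adjust", "top_table", "manhattan_data"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    ``adj_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1, over the m
    non-missing p-values; missing entries stay missing.  Values outside
    (0, 1] raise.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    obs = ~np.isnan(p)
    if obs.any():
        po = p[obs]
        if (po <= 0).any() or (po > 1).any():
            raise ValueError("p-values must lie in (0, 1]")
        out[obs] = multipletests(po, method="fdr_bh")[1]
    return out


def top_table(t: pd.DataFrame, k: int, p_col: str = "p") -> pd.DataFrame:
    """The k rows with smallest raw p; ties broken by (chrom, bp).

    Adds a ``rank`` column (1 = smallest p).  Rows with missing p are
    never selected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = t[t[p_col].notna()].copy()
    df["_ck"] = df["chrom"].map(chrom_sort_key) if "chrom" in df else 0
    bp = df["bp"] if "bp" in df else 0
    df = df.assign(_bp=bp).sort_values([p_col, "_ck", "_bp"], kind="stable")
    df = df.drop(columns=["_ck", "_bp"]).head(k)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def manhattan_data(t: pd.DataFrame, p_col: str = "p") -> pd.DataFrame:
    """Cumulative genome coordinate and -log10(p) per row.

    Chromosomes are laid end to end in karyotype order; ``color_index``
    alternates 0/1 by chromosome for the conventional two-tone plot.
    Row order of the input is preserved.
    """
    if "chrom" not in t or "bp" not in t:
        raise ValueError("need chrom and bp columns")
    chroms = sorted(t["chrom"].astype(str).unique(), key=chrom_sort_key)
    offset: dict[str, float] = {}
    color: dict[str, int] = {}
    run = 0.0
    for k, c in enumerate(chroms):
        offset[c] = run
        color[c] = k % 2
        run += float(t.loc[t["chrom"].astype(str) == c, "bp"].max())
    out = t.copy()
    cs = out["chrom"].astype(str)
    out["genome_bp"] = out["bp"].astype(float) + cs.map(offset)
    out["neglog10_p"] = -np.log10(out[p_col])
    out["color_index"] = cs.map(color)
    return out
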