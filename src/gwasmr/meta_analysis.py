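"""Inverse-variance-weighted fixed-effect meta-analysis and genomic control.

Effects are pooled per SNP across cohorts with weights w_i = 1/se_i^2 under
a fixed-effect model; SNPs present in only a subset of cohorts are pooled
over the cohorts that carry them, with the number of contributing studies K
recorded per SNP.  Genomic control then rescales the pooled test statistics
by the inflation factor lambda = median(z^2) / 0.4549364 (the median of a
chi-square with 1 df) when lambda > 1; deflation (lambda <= 1) is recorded
but never applied, the standard convention.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import CohortTable

#: median of the chi-square distribution with one degree of freedom
CHI2_1_MEDIAN = 0.4549364

META_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA",
    "BETA_META", "SE_META", "Z", "P", "K", "LAMBDA_GC",
]


class MetaEffect(NamedTuple):
    beta_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    K: int


def ivw_fixed_effect_meta(per_cohort: Sequence[tuple[float, float]]) -> MetaEffect:
    """Pool (beta, se) pairs for one SNP by fixed-effect inverse variance.

    beta_meta = sum(w_i * beta_i) / sum(w_i),  se_meta = sum(w_i)^(-1/2),
    with w_i = 1/se_i^2; the two-sided p comes from the standard normal.
    """
    if len(per_cohort) == 0:
        raise ValueError("cannot meta-analyze an empty collection of effects")
    beta = np.asarray([b for b, _ in per_cohort], dtype=float)
    se = np.asarray([s for _, s in per_cohort], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    beta_meta = float(np.sum(w * beta) / np.sum(w))
    se_meta = float(np.sum(w) ** -0.5)
    z = beta_meta / se_meta
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaEffect(beta_meta, se_meta, z, max(p, np.nextafter(0, 1)), len(per_cohort))


def meta_analyze(tables: Iterable[CohortTable]) -> pd.DataFrame:
    """IVW fixed-effect meta-analysis of harmonized cohort tables.

    Returns a DataFrame with the META_COLUMNS layout (LAMBDA_GC = 1 until
    :func:`genomic_control` is applied).  Alleles are taken from the first
    cohort carrying each SNP; callers are expected to have harmonized the
    tables first (see :func:`gwasmr.sumstats_io.harmonize_alleles`).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no cohort tables supplied")
    stacked = pd.concat(
        [t.records.assign(_cohort=t.cohort_name) for t in tables], ignore_index=True
    )
    w = 1.0 / stacked["SE"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["BETA"])
    grouped = stacked.groupby("SNP", sort=False)
    agg = grouped.agg(
        CHR=("CHR", "first"), POS=("POS", "first"),
        EA=("EA", "first"), OA=("OA", "first"),
        _w=("_w", "sum"), _wb=("_wb", "sum"), K=("_w", "size"),
    )
    beta_meta = agg["_wb"] / agg["_w"]
    se_meta = agg["_w"] ** -0.5
    z = beta_meta / se_meta
    out = pd.DataFrame({
        "SNP": agg.index, "CHR": agg["CHR"].to_numpy(), "POS": agg["POS"].to_numpy(),
        "EA": agg["EA"].to_numpy(), "OA": agg["OA"].to_numpy(),
        "BETA_META": beta_meta.to_numpy(), "SE_META": se_meta.to_numpy(),
        "Z": z.to_numpy(),
        "P": np.maximum(2.0 * stats.norm.sf(np.abs(z.to_numpy())), 5e-324),
        "K": agg["K"].to_numpy(dtype=int),
        "LAMBDA_GC": 1.0,
    })
    return out.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)


def lambda_gc(z: np.ndarray) -> float:
    """Genomic-control inflation factor: median(z^2) / median(chi2_1)."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("cannot compute lambda on zero statistics")
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def genomic_control(meta: pd.DataFrame) -> pd.DataFrame:
    """Apply genomic control to a meta-analysis table.

    If lambda > 1 every Z is divided by sqrt(lambda), SE_META multiplied by
    sqrt(lambda), and P recomputed; if lambda <= 1 the statistics are left
    untouched.  LAMBDA_GC records the measured lambda on every row either
    way.
    """
    if len(meta) == 0:
        raise ValueError("cannot apply genomic control to an empty table")
    lam = lambda_gc(meta["Z"].to_numpy())
    out = meta.copy()
    out["LAMBDA_GC"] = lam
    if lam > 1.0:
        scale = np.sqrt(lam)
        out["Z"] = out["Z"] / scale
        out["SE_META"] = out["SE_META"] * scale
        out["P"] = np.maximum(2.0 * stats.norm.sf(np.abs(out["Z"].to_numpy())), 5e-324)
    return out


def genomic_control_per_cohort(tables: Sequence[CohortTable]) -> list[CohortTable]:
    """Pre-meta genomic control applied to each cohort separately.

    Provided for pipelines that correct per-cohort statistics before
    pooling; the default pipeline corrects once, post-meta.
    """
    out = []
    for t in tables:
        df = t.records.copy()
        z = (df["BETA"] / df["SE"]).to_numpy()
        lam = lambda_gc(z)
        if lam > 1.0:
            df["SE"] = df["SE"] * np.sqrt(lam)
            df["P"] = np.maximum(
                2.0 * stats.norm.sf(np.abs(df["BETA"] / df["SE"])), 5e-324
            )
        out.append(CohortTable(t.cohort_name, t.trait, df, list(t.rejection_log)))
    return out


def qq_data(meta: pd.DataFrame) -> pd.DataFrame:
    """Expected vs observed -log10(p) pairs for a quantile-quantile plot.

    Observed p sorted ascending; expected quantiles (i - 0.5)/n.
    """
    if len(meta) == 0:
        raise ValueError("cannot build QQ data from an empty table")
    p = np.sort(meta["P"].to_numpy())
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "EXPECTED_NLOG10P": -np.log10(expected),
        "OBSERVED_NLOG10P": -np.log10(p),
    })


def write_meta(meta: pd.DataFrame, path) -> None:
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"meta-analysis table missing columns: {missing}")
    return df
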