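"""Two-sample Mendelian randomization from summary statistics.

Instruments are genome-wide-significant exposure SNPs pruned to mutual
independence by LD clumping (r^2 < 0.001 within 250 kb by default); missing
instruments in the outcome study may be replaced by user-supplied proxy
SNPs.  Causal estimates:

* **IVW** — fixed-effect inverse-variance weighting of per-SNP Wald ratios,
  equivalent to a through-origin weighted regression of outcome betas on
  exposure betas with weights 1/se_y^2 (first-order weights).
* **MR-Egger** — the same regression with an intercept; the intercept
  estimates directional pleiotropy, the slope the causal effect.
* **Weighted median** — the weight-interpolated median of Wald ratios,
  consistent while valid instruments carry more than half the weight;
  its standard error comes from a seeded parametric bootstrap.

Cochran's Q quantifies heterogeneity across instruments; instruments whose
Bonferroni-corrected Q contribution is extreme can be excluded in a single
pass as likely pleiotropic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal quantile

GENOME_WIDE_ALPHA = 5e-9
CLUMP_R2_MAX = 0.001
CLUMP_WINDOW = 250_000
PROXY_R2_MIN = 0.8


@dataclass
class MRResult:
    method: str                      # IVW | Egger | WeightedMedian
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    p: float
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _wald_result(method: str, estimate: float, se: float, n: int, **extra) -> MRResult:
    p = float(2.0 * stats.norm.sf(abs(estimate) / se)) if se > 0 else (1.0 if estimate == 0 else 0.0)
    return MRResult(
        method=method, estimate=float(estimate), se=float(se),
        ci_lower=float(estimate - Z_95 * se), ci_upper=float(estimate + Z_95 * se),
        p=p, n_instruments=n, **extra,
    )


# ---------------------------------------------------------------------------
# Instrument selection
# ---------------------------------------------------------------------------

def clump_instruments(
    sumstats: pd.DataFrame,
    ld: pd.DataFrame,
    alpha: float = GENOME_WIDE_ALPHA,
    r2_max: float = CLUMP_R2_MAX,
    window: int = CLUMP_WINDOW,
) -> list[str]:
    """Greedy LD clumping of significant SNPs into independent instruments.

    ``sumstats`` is a meta-analysis table (SNP, CHR, POS, P columns used);
    ``ld`` a symmetric r^2 matrix indexed and columned by SNP id.  Ranked by
    p ascending (ties by CHR, POS), the best remaining SNP is accepted and
    every remaining SNP that is BOTH within ±window of it on the same
    chromosome AND has r^2 >= r2_max with it is discarded.  SNPs absent
    from ``ld`` are treated as unlinked (r^2 = 0) with a logged warning.
    Returns accepted SNP ids in acceptance order.
    """
    sig = sumstats.loc[sumstats["P"] < alpha]
    sig = sig.sort_values(["P", "CHR", "POS"], kind="mergesort")
    snps = sig["SNP"].astype(str).to_numpy()
    chrom = sig["CHR"].astype(str).to_numpy()
    pos = sig["POS"].to_numpy(dtype=np.int64)

    missing = [s for s in snps if s not in ld.index]
    if missing:
        logger.warning(
            "%d significant SNP(s) absent from the LD matrix; treated as unlinked: %s",
            len(missing), ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""),
        )
    missing_set = set(missing)

    accepted: list[str] = []
    alive = np.ones(len(snps), dtype=bool)
    for i in range(len(snps)):
        if not alive[i]:
            continue
        lead = snps[i]
        accepted.append(lead)
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        if not near.any():
            continue
        if lead in missing_set:
            continue  # unlinked to everything
        row = ld.loc[lead]
        for j in np.flatnonzero(near):
            other = snps[j]
            r2 = float(row.get(other, 0.0)) if other not in missing_set else 0.0
            if r2 >= r2_max:
                alive[j] = False
    return accepted


def substitute_proxies(
    instruments: Sequence[str],
    outcome_snps: Sequence[str],
    proxy_table: Mapping[str, Sequence[tuple[str, float]]] | pd.DataFrame | None = None,
    r2_min: float = PROXY_R2_MIN,
) -> list[tuple[str, str]]:
    """Replace instruments missing from the outcome study by proxy SNPs.

    ``proxy_table`` maps each instrument to candidate (proxy_id, r^2) pairs
    (a DataFrame with SNP, PROXY, R2 columns is also accepted).  Instruments
    present in the outcome are used unchanged; a missing instrument is
    replaced by its highest-r^2 proxy that is present in the outcome and has
    r^2 >= r2_min, and dropped (with a logged reason) otherwise.

    Returns (instrument, used_id) pairs; used_id == instrument when no
    substitution happened.
    """
    if isinstance(proxy_table, pd.DataFrame):
        mapping: dict[str, list[tuple[str, float]]] = {}
        for snp, proxy, r2 in proxy_table[["SNP", "PROXY", "R2"]].itertuples(index=False):
            mapping.setdefault(str(snp), []).append((str(proxy), float(r2)))
        proxy_table = mapping
    proxy_table = proxy_table or {}
    outcome = set(map(str, outcome_snps))

    used: list[tuple[str, str]] = []
    for snp in map(str, instruments):
        if snp in outcome:
            used.append((snp, snp))
            continue
        candidates = [
            (pid, r2) for pid, r2 in proxy_table.get(snp, [])
            if pid in outcome and r2 >= r2_min
        ]
        if candidates:
            best = max(candidates, key=lambda c: c[1])[0]
            used.append((snp, best))
        else:
            logger.info("instrument %s dropped: absent from outcome, no eligible proxy", snp)
    return used


def harmonize_instruments(
    exposure: pd.DataFrame, outcome: pd.DataFrame, used: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Build the harmonized instrument table (beta_x, se_x, beta_y, se_y).

    Both inputs are canonical summary tables.  Outcome effects are aligned
    to the exposure's effect allele: a swapped allele pair flips the sign of
    beta_y; irreconcilable or strand-ambiguous pairs are dropped (the same
    rules as cohort harmonization).  ``used`` optionally maps instrument ids
    to the outcome ids standing in for them (proxy substitution).
    """
    exp = exposure.set_index(exposure["SNP"].astype(str))
    out = outcome.set_index(outcome["SNP"].astype(str))
    pairs = used if used is not None else [(s, s) for s in exp.index if s in out.index]

    rows = []
    for snp, used_id in pairs:
        if snp not in exp.index or used_id not in out.index:
            continue
        e, o = exp.loc[snp], out.loc[used_id]
        ecols = {"beta": "BETA_META", "se": "SE_META"} if "BETA_META" in exp.columns \
            else {"beta": "BETA", "se": "SE"}
        sign = 1.0
        if snp == used_id:
            if (e["EA"], e["OA"]) == (o["EA"], o["OA"]):
                sign = 1.0
            elif (e["EA"], e["OA"]) == (o["OA"], o["EA"]):
                sign = -1.0
            else:
                logger.info("instrument %s dropped: irreconcilable alleles", snp)
                continue
        rows.append({
            "SNP": snp,
            "beta_x": float(e[ecols["beta"]]), "se_x": float(e[ecols["se"]]),
            "beta_y": sign * float(o["BETA"]), "se_y": float(o["SE"]),
            "proxy_of": None if snp == used_id else snp,
        })
    return pd.DataFrame(rows, columns=["SNP", "beta_x", "se_x", "beta_y", "se_y", "proxy_of"])


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _arrays(instruments: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = instruments["beta_x"].to_numpy(dtype=float)
    sx = instruments["se_x"].to_numpy(dtype=float)
    by = instruments["beta_y"].to_numpy(dtype=float)
    sy = instruments["se_y"].to_numpy(dtype=float)
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("instrument standard errors must be positive")
    return bx, sx, by, sy


def ivw_estimate(instruments: pd.DataFrame) -> MRResult:
    """Fixed-effect IVW causal estimate.

    theta = sum(bx*by/sy^2) / sum(bx^2/sy^2);  se = (sum bx^2/sy^2)^(-1/2).
    A single instrument degenerates to the Wald ratio (method still IVW,
    with a warning); Cochran's Q is attached when J >= 2.
    """
    if len(instruments) == 0:
        raise ValueError("no instruments supplied")
    bx, _, by, sy = _arrays(instruments)
    if len(bx) == 1:
        if bx[0] == 0:
            raise ValueError("Wald ratio undefined: beta_x = 0 for the only instrument")
        logger.warning("single instrument: IVW degenerates to the Wald ratio")
    denom = np.sum(bx**2 / sy**2)
    theta = float(np.sum(bx * by / sy**2) / denom)
    se = float(denom ** -0.5)
    res = _wald_result("IVW", theta, se, len(bx))
    if len(bx) >= 2:
        res.q_stat, res.q_df, res.q_p = cochran_q(instruments, theta)
    return res


def egger_estimate(instruments: pd.DataFrame) -> MRResult:
    """MR-Egger regression: WLS of beta_y on beta_x with intercept.

    Instruments are oriented so beta_x >= 0 (both betas flipped where
    needed); weights 1/se_y^2.  The slope is the causal estimate, the
    intercept the directional-pleiotropy test.
    """
    if len(instruments) < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    bx, _, by, sy = _arrays(instruments)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    intercept, slope = fit.params
    i_se, s_se = fit.bse
    res = _wald_result(
        "Egger", slope, float(s_se), len(bx),
        egger_intercept=float(intercept), egger_intercept_se=float(i_se),
        egger_intercept_p=float(2.0 * stats.norm.sf(abs(intercept) / i_se)) if i_se > 0 else 1.0,
    )
    return res


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated median: order ratios, standardized cumulative
    weight s_j = (cum_j - w_j/2)/sum(w), linear interpolation at s = 0.5."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median_estimate(
    instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weighted-median causal estimate with a seeded parametric bootstrap se.

    Ratios beta_y/beta_x carry weights (beta_x/se_y)^2.  The bootstrap
    redraws beta_x ~ N(beta_x, se_x^2) and beta_y ~ N(beta_y, se_y^2)
    ``n_boot`` times; the se is the standard deviation of the replicate
    estimates.
    """
    if len(instruments) < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    bx, sx, by, sy = _arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("beta_x = 0 gives an undefined Wald ratio")
    est = _weighted_median(by / bx, (bx / sy) ** 2)

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, bx.size))
    bys = rng.normal(by, sy, size=(n_boot, by.size))
    bxs[bxs == 0] = np.finfo(float).tiny
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median(bys[b] / bxs[b], (bxs[b] / sy) ** 2)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
    return _wald_result("WeightedMedian", est, se, len(bx))


def cochran_q(instruments: pd.DataFrame, theta: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around a causal estimate.

    Q = sum w_j (ratio_j - theta)^2 with w_j = (beta_x_j/se_y_j)^2;
    df = J - 1; p from the chi-square upper tail.
    """
    if len(instruments) < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments (df = J - 1)")
    bx, _, by, sy = _arrays(instruments)
    w = (bx / sy) ** 2
    q = float(np.sum(w * (by / bx - theta) ** 2))
    df = len(bx) - 1
    return q, df, float(stats.chi2.sf(q, df))


def exclude_pleiotropic(
    instruments: pd.DataFrame, q_alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Single-pass exclusion of likely-pleiotropic instruments.

    Per-SNP Q contributions q_j = w_j (ratio_j - theta_IVW)^2 are compared
    against the chi-square(1) upper quantile at the Bonferroni-corrected
    level q_alpha/J; instruments exceeding it are dropped and the retained
    set is returned (re-estimate once on it).  Raises if every instrument
    would be excluded.
    """
    if len(instruments) < 3:
        raise ValueError("pleiotropy exclusion needs at least 3 instruments")
    bx, _, by, sy = _arrays(instruments)
    theta = ivw_estimate(instruments).estimate
    w = (bx / sy) ** 2
    qj = w * (by / bx - theta) ** 2
    cutoff = stats.chi2.isf(q_alpha / len(bx), df=1)
    drop = qj > cutoff
    if drop.all():
        raise ValueError("pleiotropy exclusion would remove every instrument")
    excluded = [str(s) for s in instruments["SNP"].to_numpy()[drop]]
    return instruments.loc[~drop].reset_index(drop=True), excluded


def implied_wald_p(estimate: float, ci_lower: float, ci_upper: float) -> float:
    """Two-sided p implied by a point estimate and its 95% CI.

    se = (ci_upper - ci_lower)/(2*1.959964); p = 2*Phi(-|estimate|/se).
    Useful for consistency-checking reported results.  Warns when the
    estimate is not the CI midpoint (within 1e-3).
    """
    if ci_upper <= ci_lower:
        raise ValueError("CI upper bound must exceed the lower bound")
    midpoint = 0.5 * (ci_lower + ci_upper)
    if abs(estimate - midpoint) > 1e-3:
        logger.warning(
            "estimate %.6g is not the CI midpoint %.6g; p uses the stated estimate",
            estimate, midpoint,
        )
    se = (ci_upper - ci_lower) / (2.0 * Z_95)
    return float(2.0 * stats.norm.sf(abs(estimate) / se))


def mr_report(results: Sequence[MRResult], trait: str = "") -> pd.DataFrame:
    """One row per method: the MR report table."""
    rows = []
    for r in results:
        d = r.to_dict()
        if trait:
            d = {"trait": trait, **d}
        rows.append(d)
    return pd.DataFrame(rows)
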