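"""Simulation of multi-cohort GWAS summary statistics and MR instrument sets
with known ground truth.

Everything the pipeline consumes can be generated here at the summary level:
no individual genotypes are simulated.  Per locus, z-scores are drawn from a
multivariate normal whose correlation is an AR(1) LD matrix
R_ij = rho^|i-j|; a causal SNP c adds the non-centrality (R e_c) * causal_z,
scaled per cohort by sqrt(n_k / n_total) so the inverse-variance meta-
analysis of the cohorts recovers a combined non-centrality of ~causal_z at
the causal SNP.  Betas are back-computed through the standard-error identity
se = 1/sqrt(2 n f (1-f)) for an inverse-normal-transformed trait, so every
generated record satisfies the Wald p/z consistency the readers enforce.

MR instrument sets are generated under the linear instrumental-variable
model beta_y = theta * beta_x + alpha + e, where alpha is zero for valid
instruments and Normal(mr_pleiotropy_mean, 0.01^2) for the pleiotropic
fraction (drawn independently of beta_x, so the InSIDE assumption holds and
MR-Egger remains consistent).  Exposure betas are oriented positive
(exposure-increasing allele), which is what makes directional pleiotropy
directional after the Egger orientation step.

All randomness flows from the single config seed; rerunning any simulation
with the same config is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import CohortTable

#: base-pair spacing of SNPs within a simulated locus
SNP_SPACING = 10_000
#: gap between consecutive simulated loci
LOCUS_GAP = 1_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the summary-statistics and MR simulators.

    Cohort sizes default to the two white-blood-cell-count cohorts of the
    motivating meta-analysis (2,741 + 15,061 = 17,802); the MR outcome size
    defaults to a 7,009-case / 7,645-control asthma study (n = 14,654).
    """

    seed: int = 0
    n_cohorts: int = 2
    n_per_cohort: tuple[int, ...] = (2741, 15061)
    n_loci: int = 20
    snps_per_locus: int = 50
    ld_rho: float = 0.5
    causal_fraction: float = 0.2
    causal_z: float = 8.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    mr_true_theta: float = 0.2
    mr_n_instruments: int = 50
    mr_pleiotropy_fraction: float = 0.0
    mr_pleiotropy_mean: float = 0.02
    mr_exposure_n: int = 17802
    mr_outcome_n: int = 14654
    beta_x_sd: float = 0.05
    beta_x_min: float = 0.01    # |beta_x| truncation, keeps Wald ratios stable

    def validate(self) -> None:
        if self.n_cohorts < 1 or len(self.n_per_cohort) != self.n_cohorts:
            raise ValueError("n_per_cohort must list one size per cohort")
        if any(n < 2 for n in self.n_per_cohort):
            raise ValueError("cohort sizes must be >= 2")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.causal_fraction <= 1:
            raise ValueError("causal_fraction must be in [0, 1]")
        low, high = self.maf_range
        if not 0 < low <= high < 1:
            raise ValueError("maf_range must satisfy 0 < low <= high < 1")
        if min(self.n_loci, self.snps_per_locus, self.mr_n_instruments) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.mr_pleiotropy_fraction <= 1:
            raise ValueError("mr_pleiotropy_fraction must be in [0, 1]")


@dataclass
class SimulatedStudy:
    """Cohort tables plus the ground truth behind them."""

    tables: list[CohortTable]
    causal_snps: list[str]              # one per causal locus
    causal_loci: list[int]              # locus indices carrying a causal SNP
    ld: dict[str, pd.DataFrame]         # per-locus r (correlation) matrices
    snp_loci: pd.DataFrame              # SNP -> locus bookkeeping
    config: SimulationConfig = field(repr=False, default=None)

    def ld_r2(self) -> pd.DataFrame:
        """Genome-wide r^2 matrix (block diagonal across loci)."""
        snps = [s for block in self.ld.values() for s in block.index]
        full = pd.DataFrame(0.0, index=snps, columns=snps)
        for block in self.ld.values():
            full.loc[block.index, block.columns] = block.to_numpy() ** 2
        return full


def ar1_corr(n: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix R_ij = rho^|i-j|."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_cohort_sumstats(config: SimulationConfig) -> SimulatedStudy:
    """Generate per-cohort summary statistics with known causal structure.

    Returns the cohort tables (one per cohort, shared SNPs and allele
    frequencies), the list of causal SNP ids, and the exact per-locus LD
    matrices used for generation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.snps_per_locus
    n_total = float(sum(config.n_per_cohort))

    R = ar1_corr(m, config.ld_rho)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(m)) if config.ld_rho > 0 else np.eye(m)

    n_causal = int(round(config.causal_fraction * config.n_loci))
    causal_loci = sorted(
        rng.choice(config.n_loci, size=n_causal, replace=False).tolist()
    )
    causal_set = set(causal_loci)

    snp_rows, causal_snps = [], []
    ld: dict[str, pd.DataFrame] = {}
    eaf_all, mean_all = [], []
    start = 1
    for l in range(config.n_loci):
        snps = [f"rs{l:03d}_{i:03d}" for i in range(m)]
        pos = start + SNP_SPACING * np.arange(m)
        eaf = rng.uniform(*config.maf_range, size=m)
        mean = np.zeros(m)
        if l in causal_set:
            c = int(rng.integers(m))
            mean = R[:, c] * config.causal_z
            causal_snps.append(snps[c])
        ld[f"locus_{l + 1}"] = pd.DataFrame(R, index=snps, columns=snps)
        for i in range(m):
            snp_rows.append({"SNP": snps[i], "LOCUS": f"locus_{l + 1}",
                             "CHR": "1", "POS": int(pos[i])})
        eaf_all.append(eaf)
        mean_all.append(mean)
        start = int(pos[-1]) + LOCUS_GAP

    snp_loci = pd.DataFrame(snp_rows)
    eaf_vec = np.concatenate(eaf_all)
    mean_vec = np.concatenate(mean_all)

    tables = []
    for k, n_k in enumerate(config.n_per_cohort):
        scale = np.sqrt(n_k / n_total)
        z = np.empty(len(snp_loci))
        for l in range(config.n_loci):
            sl = slice(l * m, (l + 1) * m)
            z[sl] = mean_vec[sl] * scale + L @ rng.standard_normal(m)
        se = 1.0 / np.sqrt(2.0 * n_k * eaf_vec * (1.0 - eaf_vec))
        df = pd.DataFrame({
            "SNP": snp_loci["SNP"], "CHR": snp_loci["CHR"], "POS": snp_loci["POS"],
            "EA": "A", "OA": "G",
            "EAF": eaf_vec, "BETA": z * se, "SE": se,
            "P": np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324),
            "N": n_k,
        })
        tables.append(CohortTable(f"cohort_{k + 1}", "simulated", df))
    return SimulatedStudy(tables, causal_snps, causal_loci, ld, snp_loci, config)


@dataclass
class SimulatedMRTruth:
    theta: float
    valid: np.ndarray        # boolean, True where alpha_j = 0
    alpha: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {"theta": self.theta, "valid": self.valid.tolist(),
                "alpha": self.alpha.tolist(), "seed": self.seed}


def simulate_mr_dataset(
    config: SimulationConfig,
) -> tuple[CohortTable, CohortTable, pd.DataFrame, SimulatedMRTruth]:
    """Generate exposure/outcome instrument summary statistics.

    Instruments are mutually independent (identity LD).  Exposure effects
    beta_x are |Normal(0, beta_x_sd^2)| truncated below at beta_x_min;
    outcome effects follow beta_y = theta*beta_x + alpha + Normal(0, se_y)
    with alpha = 0 for valid instruments and Normal(mr_pleiotropy_mean,
    0.01^2) for the pleiotropic fraction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    J = config.mr_n_instruments

    beta_x = np.abs(rng.normal(0.0, config.beta_x_sd, size=J))
    for _ in range(1000):
        small = beta_x <= config.beta_x_min
        if not small.any():
            break
        beta_x[small] = np.abs(rng.normal(0.0, config.beta_x_sd, size=int(small.sum())))
    beta_x = np.maximum(beta_x, config.beta_x_min * (1 + 1e-9))

    eaf = rng.uniform(*config.maf_range, size=J)
    se_x = 1.0 / np.sqrt(2.0 * config.mr_exposure_n * eaf * (1.0 - eaf))
    se_y = 1.0 / np.sqrt(2.0 * config.mr_outcome_n * eaf * (1.0 - eaf))

    n_invalid = int(round(config.mr_pleiotropy_fraction * J))
    invalid_idx = rng.choice(J, size=n_invalid, replace=False)
    alpha = np.zeros(J)
    alpha[invalid_idx] = rng.normal(config.mr_pleiotropy_mean, 0.01, size=n_invalid)
    valid = np.ones(J, dtype=bool)
    valid[invalid_idx] = False

    beta_y = config.mr_true_theta * beta_x + alpha + rng.normal(0.0, se_y)

    snps = [f"iv{j:03d}" for j in range(J)]
    pos = 1 + LOCUS_GAP * np.arange(J)

    def _table(name: str, beta: np.ndarray, se: np.ndarray, n: int) -> CohortTable:
        df = pd.DataFrame({
            "SNP": snps, "CHR": "1", "POS": pos, "EA": "A", "OA": "G",
            "EAF": eaf, "BETA": beta, "SE": se,
            "P": np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), 5e-324),
            "N": n,
        })
        return CohortTable(name, "simulated", df)

    exposure = _table("exposure", beta_x, se_x, config.mr_exposure_n)
    outcome = _table("outcome", beta_y, se_y, config.mr_outcome_n)
    ld = pd.DataFrame(np.eye(J), index=snps, columns=snps)
    truth = SimulatedMRTruth(config.mr_true_theta, valid, alpha, config.seed)
    return exposure, outcome, ld, truth


def config_header(config: SimulationConfig) -> str:
    """One-line provenance header recording the seed and parameters."""
    return "# " + " ".join(f"{k}={v}" for k, v in asdict(config).items())
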