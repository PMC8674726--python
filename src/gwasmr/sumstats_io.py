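"""Reading, validation, harmonization and filtering of GWAS summary statistics.

A cohort's association results live in a :class:`CohortTable`: a pandas
DataFrame with the canonical columns ``SNP, CHR, POS, EA, OA, EAF, BETA, SE,
P, N`` plus cohort metadata.  All downstream stages (meta-analysis,
fine-mapping, Mendelian randomization) consume these tables, so validation
happens once, here: rows that violate the record invariants are dropped and
accounted for in a rejection log rather than silently propagated.

Invariants enforced per record
------------------------------
* ``SE > 0``, ``0 < EAF < 1``, ``0 < P <= 1``, ``N >= 1``
* effect and other allele are single upper-case bases A/C/G/T and differ
* when both BETA/SE and P are present, the Wald p implied by z = BETA/SE
  agrees with the reported P to within 0.05 (an integrity check on the
  upstream file, not a statistical test)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

#: maximum tolerated |2*Phi(-|beta/se|) - p| before a row is rejected
P_Z_CONSISTENCY_TOL = 0.05

#: minor-allele-frequency above which a palindromic (A/T or C/G) SNP is
#: considered strand-ambiguous and dropped during harmonization
PALINDROMIC_MAF_MAX = 0.4

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Raised for unrecoverable summary-statistics input problems."""


@dataclass
class CohortTable:
    """Validated per-cohort summary statistics for one trait.

    ``records`` is a DataFrame with the canonical columns, unique SNP ids,
    sorted by (CHR, POS).
    """

    cohort_name: str
    trait: str
    records: pd.DataFrame
    rejection_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_cohort(self) -> int:
        """Trait-level sample size: the maximum per-record N.

        Per-SNP N may vary with missingness; consortia report the trait-level
        n as the largest analyzed set.
        """
        if len(self.records) == 0:
            return 0
        return int(self.records["N"].max())


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.drop_duplicates(subset="SNP", keep="first")
    df = df.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)
    return df


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the record invariants, returning (kept rows, rejection log).

    Alleles are upper-cased before validation.  Each rejected row yields one
    log entry with a machine-readable ``reason`` code.
    """
    df = df.copy()
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()

    checks = {
        "nonpositive_se": ~(df["SE"] > 0),
        "eaf_out_of_range": ~((df["EAF"] > 0) & (df["EAF"] < 1)),
        "p_out_of_range": ~((df["P"] > 0) & (df["P"] <= 1)),
        "nonpositive_n": ~(df["N"] >= 1),
        "invalid_allele": ~(
            df["EA"].isin(_VALID_ALLELES) & df["OA"].isin(_VALID_ALLELES)
        ),
        "identical_alleles": df["EA"] == df["OA"],
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        z = df["BETA"] / df["SE"]
        implied_p = 2.0 * stats.norm.sf(np.abs(z))
    checks["p_z_inconsistent"] = (
        np.abs(implied_p - df["P"]) > P_Z_CONSISTENCY_TOL
    ) & (df["SE"] > 0)

    bad = pd.Series(False, index=df.index)
    log: list[dict] = []
    for reason, mask in checks.items():
        mask = mask.fillna(True) if mask.isna().any() else mask
        newly = mask & ~bad
        for snp in df.loc[newly, "SNP"]:
            log.append({"snp": str(snp), "reason": reason})
        bad |= mask
    # rows with any missing mandatory value
    missing = df[CANONICAL_COLUMNS].isna().any(axis=1) & ~bad
    for snp in df.loc[missing, "SNP"]:
        log.append({"snp": str(snp), "reason": "missing_value"})
    bad |= df[CANONICAL_COLUMNS].isna().any(axis=1)
    return df.loc[~bad], log


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    cohort_name: str = "cohort",
    trait: str = "trait",
    sep: str = "\t",
) -> CohortTable:
    """Read a delimited summary-statistics file into a validated CohortTable.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with a header row.
    column_map : mapping, optional
        Canonical-name -> file-column-name translation for dialects
        (e.g. ``{"SNP": "rs_number", "EA": "reference_allele"}``).  Canonical
        names absent from the map are looked up verbatim.

    Raises
    ------
    SumstatsError
        If the file is empty or a mandatory column is missing (the error
        names the column).
    """
    try:
        raw = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError:
        raise SumstatsError(f"empty summary-statistics file: {path}") from None
    if len(raw) == 0:
        raise SumstatsError(f"summary-statistics file has no data rows: {path}")

    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise SumstatsError(f"missing mandatory column: {canon} (file column {src!r})")
        rename[src] = canon
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS]

    df = df.astype(
        {"SNP": str, "CHR": str, "POS": "int64", "EA": str, "OA": str,
         "EAF": float, "BETA": float, "SE": float, "P": float}
    )
    kept, log = validate_records(df)
    kept = kept.astype({"N": "int64"})
    return CohortTable(cohort_name, trait, _finalize(kept), log)


def write_sumstats(table: CohortTable, path, sep: str = "\t") -> None:
    """Write a CohortTable back to canonical tab-separated text."""
    table.records[CANONICAL_COLUMNS].to_csv(path, sep=sep, index=False)


def write_rejection_log(table: CohortTable, path) -> None:
    """Write the rejection log as JSON lines (one dropped row per line)."""
    with open(path, "w") as fh:
        for entry in table.rejection_log:
            fh.write(json.dumps(entry) + "\n")


def filter_maf(table: CohortTable, threshold: float = 0.05) -> CohortTable:
    """Keep records whose minor-allele frequency strictly exceeds ``threshold``.

    MAF = min(EAF, 1 - EAF); the boundary is excluded (``MAF > threshold``),
    so a SNP at exactly the threshold is dropped.
    """
    if not 0 < threshold < 0.5:
        raise ValueError(f"MAF threshold must be in (0, 0.5), got {threshold}")
    maf = np.minimum(table.records["EAF"], 1.0 - table.records["EAF"])
    kept = table.records.loc[maf > threshold]
    return CohortTable(table.cohort_name, table.trait, kept, list(table.rejection_log))


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


def harmonize_alleles(
    tables: Sequence[CohortTable], reference: CohortTable
) -> list[CohortTable]:
    """Align each table's effect alleles to a reference table.

    For every SNP shared with the reference:

    * same (EA, OA) -> kept as-is;
    * swapped (EA, OA) -> BETA sign flipped, EAF complemented;
    * any other allele pair -> dropped as irreconcilable.

    Palindromic SNPs (A/T or C/G) with MAF > 0.4 are dropped everywhere
    (including when the alleles nominally match) because their strand cannot
    be resolved from summary data.  SNPs absent from the reference pass
    through unchanged.  All drops and flips are appended to each table's
    rejection log.  Applying the operation twice equals applying it once.
    """
    ref = reference.records.set_index("SNP")
    out: list[CohortTable] = []
    for table in tables:
        df = table.records.copy()
        log = list(table.rejection_log)
        shared = df["SNP"].isin(ref.index)
        if not shared.any():
            raise SumstatsError(
                f"cohort {table.cohort_name!r} shares no SNP with the reference"
            )
        ref_ea = df["SNP"].map(ref["EA"])
        ref_oa = df["SNP"].map(ref["OA"])

        same = shared & (df["EA"] == ref_ea) & (df["OA"] == ref_oa)
        swapped = shared & (df["EA"] == ref_oa) & (df["OA"] == ref_ea)
        irreconcilable = shared & ~same & ~swapped

        maf = np.minimum(df["EAF"], 1.0 - df["EAF"])
        ambiguous = shared & _is_palindromic(df["EA"], df["OA"]) & (maf > PALINDROMIC_MAF_MAX)

        df.loc[swapped, "BETA"] = -df.loc[swapped, "BETA"]
        df.loc[swapped, "EAF"] = 1.0 - df.loc[swapped, "EAF"]
        df.loc[swapped, ["EA", "OA"]] = df.loc[swapped, ["OA", "EA"]].to_numpy()
        for snp in df.loc[swapped & ~ambiguous, "SNP"]:
            log.append({"snp": str(snp), "reason": "allele_swap_flipped"})

        drop = irreconcilable | ambiguous
        for snp in df.loc[ambiguous, "SNP"]:
            log.append({"snp": str(snp), "reason": "palindromic_ambiguous"})
        for snp in df.loc[irreconcilable & ~ambiguous, "SNP"]:
            log.append({"snp": str(snp), "reason": "irreconcilable_alleles"})

        out.append(CohortTable(table.cohort_name, table.trait, df.loc[~drop], log))
    return out


def sample_size_report(tables: Iterable[CohortTable]) -> pd.DataFrame:
    """Per-trait sample-size bookkeeping across cohorts.

    Returns a DataFrame with one row per trait, one column per cohort
    (trait-level n = max per-record N in that cohort) and a ``Total`` column
    summing the cohort columns.
    """
    rows: dict[str, dict[str, int]] = {}
    cohorts: list[str] = []
    for table in tables:
        if table.cohort_name not in cohorts:
            cohorts.append(table.cohort_name)
        rows.setdefault(table.trait, {})[table.cohort_name] = table.n_cohort
    report = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cohorts)
    report = report.fillna(0).astype(int)
    report["Total"] = report.sum(axis=1)
    report.index.name = "Trait"
    return report
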