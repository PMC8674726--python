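"""Genome-wide-significant SNP selection, locus definition and novelty flags.

A locus is a ±window (default 250 kb) region anchored on a lead SNP.  Leads
are chosen greedily: the remaining significant SNP with the smallest p-value
becomes a lead, every significant SNP within the window on the same
chromosome joins its locus, and the process repeats until no significant
SNP is unassigned.  A locus is "known" when its lead lies within the window
of a user-supplied reference position (e.g. sentinel SNPs from a previously
published scan), otherwise "novel".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOME_WIDE_ALPHA = 5e-9
LOCUS_WINDOW = 250_000

LOCUS_COLUMNS = ["LOCUS_ID", "CHR", "START", "END", "LEAD_SNP", "LEAD_P", "N_SNPS", "NOVEL"]


@dataclass
class Locus:
    locus_id: str
    chrom: str
    start: int              # 1-based inclusive, clipped at 1
    end: int
    lead_snp: str
    lead_pos: int
    lead_p: float
    member_snps: list[str] = field(default_factory=list)
    novel: bool | None = None  # None until novelty_check runs


def select_significant(meta: pd.DataFrame, alpha: float = GENOME_WIDE_ALPHA) -> pd.DataFrame:
    """Rows with P strictly below alpha (boundary excluded)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return meta.loc[meta["P"] < alpha].reset_index(drop=True)


def define_loci(significant: pd.DataFrame, window: int = LOCUS_WINDOW) -> list[Locus]:
    """Greedy p-ranked locus assignment.

    Ties on p are broken by (CHR, POS) ascending so the result does not
    depend on input row order.  A SNP exactly ``window`` bp from a lead is
    inside the locus (±window inclusive).
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    df = significant.sort_values(
        ["P", "CHR", "POS"], kind="mergesort"
    ).reset_index(drop=True)
    chrom = df["CHR"].to_numpy()
    pos = df["POS"].to_numpy(dtype=np.int64)
    snp = df["SNP"].to_numpy()
    p = df["P"].to_numpy()

    unassigned = np.ones(len(df), dtype=bool)
    loci: list[Locus] = []
    for i in range(len(df)):
        if not unassigned[i]:
            continue
        members = unassigned & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        loci.append(Locus(
            locus_id=f"locus_{len(loci) + 1}",
            chrom=str(chrom[i]),
            start=max(1, int(pos[i]) - window),
            end=int(pos[i]) + window,
            lead_snp=str(snp[i]),
            lead_pos=int(pos[i]),
            lead_p=float(p[i]),
            member_snps=[str(s) for s in snp[members]],
        ))
        unassigned &= ~members
    return loci


def novelty_check(
    loci: list[Locus],
    reference: pd.DataFrame,
    window: int = LOCUS_WINDOW,
) -> list[Locus]:
    """Flag each locus known/novel against reference (CHR, POS) points.

    A locus is known when its lead SNP's position lies within ±window
    (inclusive) of a reference position on the same chromosome.  An empty
    reference marks every locus novel.  Loci are annotated in place and
    returned.
    """
    by_chrom: dict[str, np.ndarray] = {}
    if len(reference):
        for c, grp in reference.groupby("CHR"):
            by_chrom[str(c)] = np.sort(grp["POS"].to_numpy(dtype=np.int64))
    for L in loci:
        ref = by_chrom.get(L.chrom)
        L.novel = True
        if ref is not None and ref.size:
            idx = np.searchsorted(ref, L.lead_pos)
            for j in (idx - 1, idx):
                if 0 <= j < ref.size and abs(int(ref[j]) - L.lead_pos) <= window:
                    L.novel = False
                    break
    return loci


def read_reference_loci(path) -> pd.DataFrame:
    """Read reference positions as (CHR, POS).

    Accepts either a 2-column headerless TSV (CHR, POS, 1-based points) or a
    3-column BED (0-based half-open intervals, converted to 1-based points
    at the interval midpoint).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 2:
        df.columns = ["CHR", "POS"]
    elif df.shape[1] >= 3:
        df = df.iloc[:, :3]
        df.columns = ["CHR", "START", "END"]
        # BED midpoint, shifted to 1-based coordinates
        df["POS"] = (df["START"] + df["END"] - 1) // 2 + 1
        df = df[["CHR", "POS"]]
    else:
        raise ValueError("reference locus file needs 2 (CHR,POS) or 3 (BED) columns")
    df["CHR"] = df["CHR"].astype(str)
    df["POS"] = df["POS"].astype(np.int64)
    return df


def merge_loci_across_traits(per_trait_loci: dict[str, list[Locus]],
                             window: int = LOCUS_WINDOW) -> list[Locus]:
    """Optional cross-trait union: re-run the greedy assignment on the pooled
    lead SNPs so overlapping loci from different traits collapse to one."""
    rows = []
    for trait, loci in per_trait_loci.items():
        for L in loci:
            rows.append({"SNP": f"{trait}:{L.lead_snp}", "CHR": L.chrom,
                         "POS": L.lead_pos, "P": L.lead_p})
    if not rows:
        return []
    return define_loci(pd.DataFrame(rows), window=window)


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    """Locus summary table in the LOCUS_COLUMNS layout."""
    return pd.DataFrame([
        {"LOCUS_ID": L.locus_id, "CHR": L.chrom, "START": L.start, "END": L.end,
         "LEAD_SNP": L.lead_snp, "LEAD_P": L.lead_p, "N_SNPS": len(L.member_snps),
         "NOVEL": L.novel}
        for L in loci
    ], columns=LOCUS_COLUMNS)
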