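"""Trait-associated loci: genome-wide-significant leads and nonoverlapping
1 Mbp windows.

A locus is the window lead position ± 500 kb (inclusive bounds, clamped at
position 1). Within a trait, the most significant remaining variant absorbs
all significant variants inside its window; across traits, overlapping
windows are resolved by retaining the smallest lead p-value. All tie-breaks
are deterministic: smaller p, then larger chi-square, then trait label, then
(chrom, pos).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

GENOME_WIDE_P = 5e-8
DEFAULT_FLANK = 500_000


@dataclass
class Locus:
    locus_id: str
    trait: str
    chrom: str
    start: int
    end: int
    lead: tuple[str, int, str, str]
    lead_p: float
    lead_chi2: float
    members: pd.DataFrame | None = field(default=None, repr=False)


def ensure_pvalues(df: pd.DataFrame) -> pd.DataFrame:
    """Fill a missing/NaN P column from the 1-df chi-square upper tail."""
    out = df.copy()
    if "P" not in out.columns:
        out["P"] = np.nan
    p = pd.to_numeric(out["P"], errors="coerce")
    need = p.isna()
    if need.any():
        if "CHI2" not in out.columns:
            raise ValueError("P missing and no CHI2 column to derive it from")
        p = p.copy()
        p[need] = chi2_dist.sf(out.loc[need, "CHI2"].to_numpy(dtype=float), df=1)
    out["P"] = p
    return out


def select_significant(df: pd.DataFrame, threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Keep genome-wide-significant rows (P <= threshold, inclusive)."""
    df = ensure_pvalues(df)
    return df.loc[df["P"] <= threshold].copy()


def _ordered(sig: pd.DataFrame) -> pd.DataFrame:
    chi2 = sig["CHI2"] if "CHI2" in sig else chi2_dist.isf(sig["P"], df=1)
    return sig.assign(_chi2=chi2).sort_values(
        ["P", "_chi2", "CHROM", "POS"],
        ascending=[True, False, True, True],
        kind="stable",
    )


def build_loci(sig: pd.DataFrame, flank: int = DEFAULT_FLANK) -> list[Locus]:
    """Per-trait greedy locus construction.

    Repeatedly take the most significant remaining variant as lead, form
    [lead - flank, lead + flank] (start clamped at 1), and drop every
    significant variant of that trait inside the window.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    loci: list[Locus] = []
    traits = sorted(sig["TRAIT"].unique()) if "TRAIT" in sig else [None]
    for trait in traits:
        sub = sig if trait is None else sig[sig["TRAIT"] == trait]
        sub = _ordered(sub)
        chrom = sub["CHROM"].astype(str).to_numpy()
        pos = sub["POS"].to_numpy(dtype=np.int64)
        taken = np.zeros(len(sub), dtype=bool)
        for i in range(len(sub)):
            if taken[i]:
                continue
            row = sub.iloc[i]
            start = max(1, int(row["POS"]) - flank)
            end = int(row["POS"]) + flank
            absorb = (chrom == str(row["CHROM"])) & (pos >= start) & (pos <= end)
            taken |= absorb
            loci.append(
                Locus(
                    locus_id=f"{trait or 'all'}_{row['CHROM']}_{int(row['POS'])}",
                    trait=str(trait) if trait is not None else "all",
                    chrom=str(row["CHROM"]),
                    start=start,
                    end=end,
                    lead=(str(row["CHROM"]), int(row["POS"]), str(row["REF"]), str(row["ALT"])),
                    lead_p=float(row["P"]),
                    lead_chi2=float(row["_chi2"]),
                )
            )
    return loci


def resolve_overlaps(loci: list[Locus]) -> list[Locus]:
    """Greedy cross-trait resolution: sort by lead p (ties: trait label,
    then chrom/pos) and retain a locus iff its window does not intersect any
    already-retained window on the same chromosome."""
    ordered = sorted(loci, key=lambda l: (l.lead_p, -l.lead_chi2, l.trait, l.chrom, l.start))
    retained: list[Locus] = []
    for loc in ordered:
        clash = any(
            r.chrom == loc.chrom and loc.start <= r.end and loc.end >= r.start
            for r in retained
        )
        if not clash:
            retained.append(loc)
    return retained


def assign_variants(
    loci: list[Locus], records: pd.DataFrame
) -> tuple[list[Locus], pd.DataFrame]:
    """Populate each nonoverlapping locus with its member variants
    (inclusive bounds) and return the in-locus vs rest-of-genome partition
    counts by class.

    Loci are disjoint, so every record lands in at most one locus; the
    partition table conserves counts.
    """
    chrom = records["CHROM"].astype(str).to_numpy()
    pos = records["POS"].to_numpy(dtype=np.int64)
    in_locus = np.zeros(len(records), dtype=bool)
    for loc in loci:
        mask = (chrom == loc.chrom) & (pos >= loc.start) & (pos <= loc.end)
        if (mask & in_locus).any():
            raise ValueError("overlapping loci passed to assign_variants")
        in_locus |= mask
        loc.members = records.loc[mask].copy()
    is_indel = (
        records["is_indel"].to_numpy()
        if "is_indel" in records
        else np.zeros(len(records), bool)
    )
    partition = pd.DataFrame(
        {
            "class": ["SNP", "indel"],
            "in_loci": [
                int((in_locus & ~is_indel).sum()),
                int((in_locus & is_indel).sum()),
            ],
            "rest_of_genome": [
                int((~in_locus & ~is_indel).sum()),
                int((~in_locus & is_indel).sum()),
            ],
        }
    )
    return loci, partition


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    """Flat per-locus summary table (for the TSV report)."""
    return pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "trait": [l.trait for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "lead": [":".join(map(str, l.lead)) for l in loci],
            "lead_p": [l.lead_p for l in loci],
            "n_members": [0 if l.members is None else len(l.members) for l in loci],
        }
    )
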