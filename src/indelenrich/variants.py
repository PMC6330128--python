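"""Variant tables: parsing, allele classification, QC filters, reference lookup.

The analysis consumes biallelic SNPs and indels from imputed GWAS call sets.
Coordinates are 1-based VCF-style: ``pos`` is the first reference base and an
indel's reference footprint is ``[pos, pos + len(ref) - 1]``. Multiallelic
rows and multi-nucleotide substitutions (MNPs) are rejected loudly rather
than silently reinterpreted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

_ACGT = re.compile(r"^[ACGT]+$")

#: canonical column names for summary-statistic tables
SUMSTAT_COLUMNS = ["CHROM", "POS", "REF", "ALT", "MAF", "RSQR"]


@dataclass(frozen=True)
class VariantClass:
    """Classification of a biallelic ref/alt pair.

    ``indel_length`` is the number of inserted or deleted bases
    (0 for a SNP).
    """

    category: str  # "SNP" | "insertion" | "deletion"
    indel_length: int

    @property
    def is_indel(self) -> bool:
        return self.category != "SNP"

    @property
    def is_single_base_indel(self) -> bool:
        return self.indel_length == 1


def _check_allele(allele: str, which: str) -> None:
    if not allele:
        raise ValueError(f"{which} allele is empty")
    if not _ACGT.match(allele):
        raise ValueError(f"{which} allele {allele!r} contains non-ACGT characters")


def classify_allele_pair(ref: str, alt: str) -> VariantClass:
    """Classify a biallelic allele pair as SNP, insertion or deletion.

    A SNP is a single-base substitution (both alleles length 1); a deletion
    removes ``len(ref) - len(alt)`` bases; an insertion adds
    ``len(alt) - len(ref)``. Equal-length multi-base substitutions are not
    part of the call set and raise ``ValueError``.
    """
    _check_allele(ref, "ref")
    _check_allele(alt, "alt")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r})")
    if len(ref) == len(alt):
        if len(ref) == 1:
            return VariantClass("SNP", 0)
        raise ValueError(
            f"equal-length multi-base substitution {ref}>{alt}: "
            "only biallelic SNPs and indels are accepted"
        )
    if len(ref) > len(alt):
        return VariantClass("deletion", len(ref) - len(alt))
    return VariantClass("insertion", len(alt) - len(ref))


def classify_variants(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification of a variant table.

    Adds columns ``vclass`` ("SNP"/"insertion"/"deletion"), ``indel_len``,
    ``is_indel`` and ``is_single_base``. Any invalid row (empty/non-ACGT
    allele, ref == alt, MNP) raises with the offending positions listed.
    """
    ref = df["REF"].astype(str)
    alt = df["ALT"].astype(str)
    bad = ~(ref.str.fullmatch("[ACGT]+") & alt.str.fullmatch("[ACGT]+"))
    bad |= ref.values == alt.values
    lr, la = ref.str.len().to_numpy(), alt.str.len().to_numpy()
    bad |= (lr == la) & (lr > 1)
    if bad.any():
        rows = df.loc[np.asarray(bad)].head(5)
        raise ValueError(
            f"{int(bad.sum())} invalid variant row(s) (empty/non-ACGT allele, "
            f"ref==alt, or MNP); first offenders:\n{rows.to_string()}"
        )
    out = df.copy()
    out["indel_len"] = np.abs(lr - la)
    out["vclass"] = np.where(lr == la, "SNP", np.where(lr > la, "deletion", "insertion"))
    out["is_indel"] = out["indel_len"] > 0
    out["is_single_base"] = out["indel_len"] == 1
    return out


def apply_qc_filters(
    df: pd.DataFrame,
    maf_min: float = 0.01,
    rsqr_common: float = 0.3,
    rsqr_rare: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage post-imputation QC.

    Stage 1 (imputation quality): keep RSQR > 0.3 when MAF >= 1%, and
    RSQR > 0.6 when MAF < 1%. Stage 2 (analysis set): keep MAF >= 1%.
    Returns ``(passed, rejected)`` where ``rejected`` carries a
    ``reject_reason`` column ("rsqr" or "maf"); the two frames partition the
    input.
    """
    maf = pd.to_numeric(df["MAF"], errors="coerce")
    rsqr = pd.to_numeric(df["RSQR"], errors="coerce")
    missing = maf.isna() | rsqr.isna()
    if missing.any():
        ids = df.loc[missing].apply(
            lambda r: r.get("ID") or f"{r['CHROM']}:{r['POS']}:{r['REF']}:{r['ALT']}",
            axis=1,
        )
        raise ValueError(f"missing MAF/RSQR for: {', '.join(map(str, ids.head(10)))}")
    common = maf >= maf_min
    stage1 = np.where(common, rsqr > rsqr_common, rsqr > rsqr_rare)
    keep = stage1 & common
    rejected = df.loc[~keep].copy()
    rejected["reject_reason"] = np.where(stage1[~keep], "maf", "rsqr")
    return df.loc[keep].copy(), rejected


def compute_maf(af: np.ndarray | pd.Series) -> np.ndarray:
    """Fold an allele frequency onto the minor-allele scale min(af, 1-af)."""
    af = np.asarray(af, dtype=float)
    if ((af < 0) | (af > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return np.minimum(af, 1.0 - af)


def _chrom_dialect(labels: Iterable[str]) -> set[str]:
    return {"chr" if str(c).lower().startswith("chr") else "plain" for c in labels}


class ReferenceVariantList:
    """A presence/absence catalogue of (chrom, pos, ref, alt) keys.

    Lookup is an exact match on all four components — no left-alignment or
    normalisation is attempted, and mismatched chromosome naming dialects
    ("chr1" vs "1") are an error rather than being silently reconciled.
    """

    def __init__(self, entries: Iterable[tuple[str, int, str, str]]):
        self.entries = {(str(c), int(p), str(r), str(a)) for c, p, r, a in entries}
        self._dialects = _chrom_dialect(c for c, _, _, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        c, p, r, a = key
        return (str(c), int(p), str(r), str(a)) in self.entries

    @classmethod
    def from_vcf(cls, path: str | Path) -> "ReferenceVariantList":
        """Load from a sites-only VCF; multiallelic ALTs contribute one key each."""
        from cyvcf2 import VCF

        entries = []
        for rec in VCF(str(path)):
            for alt in rec.ALT:
                entries.append((rec.CHROM, rec.POS, rec.REF, alt))
        return cls(entries)

    @classmethod
    def from_table(cls, path: str | Path) -> "ReferenceVariantList":
        """Load from 4-column tab-separated text (CHROM POS REF ALT, no header)."""
        tab = pd.read_csv(
            path, sep="\t", header=None, names=["CHROM", "POS", "REF", "ALT"],
            dtype={"CHROM": str},
        )
        return cls(tab.itertuples(index=False, name=None))


def match_reference_list(
    df: pd.DataFrame, ref_list: ReferenceVariantList
) -> tuple[np.ndarray, dict]:
    """Flag each record's presence in a reference variant list.

    Returns a boolean array (True = present by exact 4-tuple match) and a
    summary dict with ``n``, ``n_absent`` and ``fraction_absent``.
    Raises if the records and the list use different chromosome dialects.
    """
    rec_dialects = _chrom_dialect(df["CHROM"].unique())
    if ref_list._dialects and rec_dialects and rec_dialects != ref_list._dialects:
        raise ValueError(
            f"chromosome naming dialects differ: records use {sorted(rec_dialects)}, "
            f"reference list uses {sorted(ref_list._dialects)}; "
            "normalise explicitly before matching"
        )
    keys = zip(
        df["CHROM"].astype(str),
        df["POS"].astype(int),
        df["REF"].astype(str),
        df["ALT"].astype(str),
    )
    present = np.fromiter((k in ref_list.entries for k in keys), bool, len(df))
    n_absent = int((~present).sum())
    summary = {
        "n": len(df),
        "n_absent": n_absent,
        "fraction_absent": n_absent / len(df) if len(df) else float("nan"),
    }
    return present, summary


def strip_chr_prefix(df: pd.DataFrame) -> pd.DataFrame:
    """Explicit one-shot chromosome normalisation: drop a leading 'chr'."""
    out = df.copy()
    out["CHROM"] = out["CHROM"].astype(str).str.replace(r"^chr", "", regex=True)
    return out


def read_sumstats(path: str | Path, trait: str | None = None) -> pd.DataFrame:
    """Read an EPACTS-like tab-separated summary-statistic table.

    Requires header columns CHROM, POS, REF, ALT, MAF, RSQR; CHI2, P, BETA,
    SE, IS_MISSENSE and TRAIT are optional. ``trait`` overrides/supplies the
    TRAIT column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df["POS"] = df["POS"].astype(int)
    if trait is not None:
        df["TRAIT"] = trait
    return df
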