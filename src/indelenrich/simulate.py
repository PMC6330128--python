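"""Synthetic cohorts with known ground truth.

Generates variant tables, coding/low-complexity interval files, and GWAS
summary statistics under the same one-causal-variant model the estimator
assumes, with a planted enrichment parameter ``lambda_true``. Defaults
emulate the study conditions the pipeline targets: ~89 nonoverlapping loci,
a 5.5% indel fraction among common variants, 58% of indels deletions,
geometric indel lengths with 56% single-base, and genome-wide-significant
leads driven by a causal noncentrality of 40.

Statistics are simulated directly on the chi-square scale (no genotypes):
the causal variant at each locus draws a noncentral chi2(1, ncp), all other
variants a central chi2(1), optionally with an exchangeable correlation on
the underlying normal scores standing in for LD.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .regions import IntervalSet

_BASES = np.array(list("ACGT"))
_SLOT = 16  # bp between variant slots; keeps reference footprints disjoint
_MAX_INDEL = 12


@dataclass
class SimulationConfig:
    """Ground-truth generator settings (defaults = the emulated study)."""

    n_loci: int = 89
    variants_per_locus: int = 50
    background_variants: int = 5000
    indel_fraction: float = 0.055
    deletion_share: float = 0.58         # of indels
    single_base_geom_p: float = 0.56     # P(indel length = 1)
    p_coding_snp: float = 0.007
    p_coding_indel: float = 0.002
    p_missense_given_coding_snp: float = 0.5
    p_lowcomplexity_snp: float = 0.011
    p_lowcomplexity_indel: float = 0.043
    annotation: str = "indel"            # indel | missense | coding_indel
    lambda_true: float = 0.0
    causal_ncp: float = 40.0
    r: float = 0.0                       # exchangeable within-locus correlation
    trait: str = "trait1"
    seed: int = 0

    def __post_init__(self):
        for name in ("indel_fraction", "deletion_share", "single_base_geom_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.causal_ncp < 0:
            raise ValueError("causal_ncp must be nonnegative")
        if not 0 <= self.r <= 0.99:
            raise ValueError("r must lie in [0, 0.99]")


def _alleles(rng: np.random.Generator, is_indel: np.ndarray,
             deletion_share: float, geom_p: float) -> tuple[list[str], list[str]]:
    n = len(is_indel)
    ref, alt = [], []
    for i in range(n):
        base = _BASES[rng.integers(4)]
        if not is_indel[i]:
            other = _BASES[rng.integers(3)]
            if other == base:
                other = _BASES[3]
            ref.append(base)
            alt.append(str(other))
        else:
            length = min(int(rng.geometric(geom_p)), _MAX_INDEL)
            extra = "".join(_BASES[rng.integers(0, 4, size=length)])
            if rng.random() < deletion_share:
                ref.append(base + extra)
                alt.append(str(base))
            else:
                ref.append(str(base))
                alt.append(base + extra)
    return ref, alt


def simulate_variant_genome(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, IntervalSet, IntervalSet]:
    """Generate the variant table plus coding and low-complexity interval
    sets with known membership truth.

    Locus variants sit on 16-bp slots inside ±200 kb of locus centres spaced
    3 Mb apart across 22 synthetic autosomes, so reference footprints never
    collide and every locus fits a single 1 Mb window. Locus variants are
    drawn QC-passing (the emulated loci are built from the post-QC set);
    background variants span the MAF and RSQR thresholds so the filters are
    exercised. Identical seeds give bit-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    rows_per_chrom = -(-config.n_loci // 22)
    bg_base = 2_000_000 + rows_per_chrom * 3_000_000 + 10_000_000

    chroms, positions, locus_ids = [], [], []
    for l in range(config.n_loci):
        chrom = str(l % 22 + 1)
        center = 2_000_000 + (l // 22) * 3_000_000
        slots = rng.choice(25_000, size=config.variants_per_locus, replace=False)
        pos = np.sort(center - 200_000 + slots * _SLOT)
        chroms += [chrom] * config.variants_per_locus
        positions += pos.tolist()
        locus_ids += [l] * config.variants_per_locus
    # background: far from every locus window, spread over the autosomes
    for i in range(config.background_variants):
        chroms.append(str(i % 22 + 1))
        positions.append(bg_base + (i // 22) * _SLOT)
        locus_ids.append(-1)

    n = len(positions)
    is_indel = rng.random(n) < config.indel_fraction
    ref, alt = _alleles(rng, is_indel, config.deletion_share, config.single_base_geom_p)

    in_locus = np.array(locus_ids) >= 0
    maf = np.where(
        in_locus,
        rng.uniform(0.01, 0.5, n),
        np.where(rng.random(n) < 0.85, rng.uniform(0.01, 0.5, n),
                 rng.uniform(0.001, 0.01, n)),
    )
    rsqr = np.where(
        in_locus,
        rng.uniform(0.35, 1.0, n),
        np.where(rng.random(n) < 0.9, rng.beta(8, 1.5, n), rng.uniform(0.0, 1.0, n)),
    )

    p_coding = np.where(is_indel, config.p_coding_indel, config.p_coding_snp)
    is_coding = rng.random(n) < p_coding
    is_missense = (
        is_coding & ~is_indel
        & (rng.random(n) < config.p_missense_given_coding_snp)
    )
    p_lc = np.where(is_indel, config.p_lowcomplexity_indel, config.p_lowcomplexity_snp)
    is_lc = rng.random(n) < p_lc

    df = pd.DataFrame(
        {
            "CHROM": chroms,
            "POS": np.asarray(positions, dtype=np.int64),
            "REF": ref,
            "ALT": alt,
            "MAF": np.round(maf, 6),
            "RSQR": np.round(rsqr, 6),
            "IS_MISSENSE": is_missense.astype(int),
            "locus_truth": locus_ids,
        }
    )
    reflen = df["REF"].str.len().to_numpy()
    coding = IntervalSet.from_records(
        "coding",
        zip(df.loc[is_coding, "CHROM"],
            df.loc[is_coding, "POS"],
            df.loc[is_coding, "POS"] + reflen[is_coding] - 1),
    )
    lowc = IntervalSet.from_records(
        "low_complexity",
        zip(df.loc[is_lc, "CHROM"],
            df.loc[is_lc, "POS"],
            df.loc[is_lc, "POS"] + reflen[is_lc] - 1),
    )
    return df, coding, lowc


def _annotation_vector(df: pd.DataFrame, which: str,
                       coding: IntervalSet | None = None) -> np.ndarray:
    is_indel = df["REF"].str.len().to_numpy() != df["ALT"].str.len().to_numpy()
    if which == "indel":
        return is_indel
    if which == "missense":
        return df["IS_MISSENSE"].to_numpy().astype(bool)
    if which == "coding_indel":
        if coding is None:
            raise ValueError("coding intervals required for coding_indel annotation")
        from .regions import annotate_membership

        return is_indel & annotate_membership(df, coding)
    raise ValueError(f"unknown annotation {which!r}")


def simulate_trait_associations(
    genome: pd.DataFrame,
    config: SimulationConfig,
    coding: IntervalSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-variant association statistics with a planted enrichment.

    At each locus one causal variant is drawn with probability proportional
    to exp(lambda_true * a_i); its chi-square is noncentral chi2(1, ncp),
    all others central chi2(1) (optionally exchangeably correlated through
    the underlying normal scores). Returns (summary statistics, truth
    table of causal variants).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    out = genome.copy()
    a = _annotation_vector(out, config.annotation, coding)
    z = rng.standard_normal(len(out))
    if config.r > 0:
        locus_factor = {}
        for l in np.unique(out["locus_truth"]):
            locus_factor[l] = rng.standard_normal()
        f = out["locus_truth"].map(locus_factor).to_numpy()
        z = np.sqrt(config.r) * f + np.sqrt(1 - config.r) * z

    truth_rows = []
    locus = out["locus_truth"].to_numpy()
    for l in range(config.n_loci):
        idx = np.flatnonzero(locus == l)
        if idx.size == 0:
            raise ValueError(f"locus {l} has zero variants")
        w = np.exp(config.lambda_true * a[idx].astype(float))
        causal = idx[rng.choice(idx.size, p=w / w.sum())]
        z[causal] += np.sqrt(config.causal_ncp)
        truth_rows.append(
            {
                "locus_truth": l,
                "CHROM": out.at[causal, "CHROM"],
                "POS": int(out.at[causal, "POS"]),
                "REF": out.at[causal, "REF"],
                "ALT": out.at[causal, "ALT"],
                "annotated": bool(a[causal]),
            }
        )
    chi2 = z**2
    out["CHI2"] = chi2
    out["P"] = chi2_dist.sf(chi2, df=1)
    se = 1.0 / np.sqrt(2 * 5000 * out["MAF"] * (1 - out["MAF"]))
    out["SE"] = se
    out["BETA"] = z * se
    out["TRAIT"] = config.trait
    return out, pd.DataFrame(truth_rows)


def simulate_chi2_matrix(
    n_loci: int,
    variants_per_locus: int,
    annotation_freq: float,
    lambda_true: float,
    ncp: float,
    rng: np.random.Generator,
    r: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast equal-size-locus draw used for estimator calibration studies.

    Returns (chi2 matrix [loci x variants], annotation matrix, causal
    column index per locus) under the same model as
    :func:`simulate_trait_associations`.
    """
    ann = rng.random((n_loci, variants_per_locus)) < annotation_freq
    w = np.where(ann, np.exp(lambda_true), 1.0)
    p = w / w.sum(axis=1, keepdims=True)
    causal = (p.cumsum(axis=1) > rng.random((n_loci, 1))).argmax(axis=1)
    z = rng.standard_normal((n_loci, variants_per_locus))
    if r > 0:
        f = rng.standard_normal((n_loci, 1))
        z = np.sqrt(r) * f + np.sqrt(1 - r) * z
    z[np.arange(n_loci), causal] += np.sqrt(ncp)
    return z**2, ann, causal


def _write_bed(iset: IntervalSet, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(iset.intervals, key=lambda c: (len(c), c)):
            s, e = iset.intervals[chrom]
            for a, b in zip(s, e):
                fh.write(f"{chrom}\t{a - 1}\t{b}\n")


def write_dataset(outdir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Generate a full dataset and write it in the dialects the readers
    consume: sumstats TSV, coding/low-complexity BED, truth TSV and a
    key=value config file. Byte-identical for identical configs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, coding, lowc = simulate_variant_genome(config)
    sumstats, truth = simulate_trait_associations(genome, config, coding)
    paths = {
        "sumstats": outdir / "sumstats.tsv",
        "coding": outdir / "coding.bed",
        "lowcomplexity": outdir / "lowcomplexity.bed",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.txt",
    }
    cols = ["CHROM", "POS", "REF", "ALT", "MAF", "RSQR",
            "CHI2", "P", "BETA", "SE", "IS_MISSENSE", "TRAIT"]
    sumstats[cols].to_csv(paths["sumstats"], sep="\t", index=False, float_format="%.10g")
    _write_bed(coding, paths["coding"])
    _write_bed(lowc, paths["lowcomplexity"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        for k, v in asdict(config).items():
            fh.write(f"{k}={v}\n")
    return paths
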