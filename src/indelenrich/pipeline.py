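"""End-to-end orchestration: QC -> loci -> credible sets -> enrichment ->
contingency tests -> report tables.

Every stage conserves counts (each input variant ends up in exactly one of
rejected-QC / in-locus / rest-of-genome) and reruns with identical inputs
produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import finemap, loci as loci_mod, variants
from .enrich import EnrichmentData, estimate_lambda, rerun_excluding
from .regions import IntervalSet, annotate_membership, annotation_summary
from .stat_tests import chi_square_2x2, mann_whitney_u

log = logging.getLogger(__name__)

VARIANT_KEY = ["CHROM", "POS", "REF", "ALT"]


@dataclass
class RunConfig:
    p_threshold: float = 5e-8
    maf_min: float = 0.01
    rsqr_common: float = 0.3
    rsqr_rare: float = 0.6
    flank: int = 500_000
    mass: float = 0.95
    posterior_cutoff: float = 0.1
    annotations: tuple[str, ...] = ("indel", "missense", "coding_indel")
    exclude_low_complexity_rerun: bool = True

    def __post_init__(self):
        if not 0 < self.p_threshold < 1 or not 0 < self.mass <= 1:
            raise ValueError("thresholds out of range")
        if self.flank <= 0 or not 0 <= self.maf_min <= 0.5:
            raise ValueError("thresholds out of range")


def _annotation_mask(df: pd.DataFrame, which: str) -> np.ndarray:
    is_indel = df["is_indel"].to_numpy()
    if which == "indel":
        return is_indel
    if which == "missense":
        if "IS_MISSENSE" not in df:
            raise ValueError("missense annotation requested but IS_MISSENSE column absent")
        return df["IS_MISSENSE"].to_numpy().astype(bool)
    if which == "coding_indel":
        if "is_coding" not in df:
            raise ValueError("coding_indel annotation requested but no coding intervals given")
        return is_indel & df["is_coding"].to_numpy()
    raise ValueError(f"unknown annotation {which!r}")


def run_full_analysis(
    sumstats: pd.DataFrame,
    coding: IntervalSet | None = None,
    lowcomplexity: IntervalSet | None = None,
    ref_list: variants.ReferenceVariantList | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Run the complete analysis on a (possibly multi-trait) summary-
    statistic table; returns a results dict of tables, fits and counts."""
    cfg = config or RunConfig()
    results: dict = {"config": asdict(cfg), "stage_counts": {}}

    classified = variants.classify_variants(sumstats)
    analysis, rejected = variants.apply_qc_filters(
        classified, cfg.maf_min, cfg.rsqr_common, cfg.rsqr_rare
    )
    results["stage_counts"]["input_rows"] = len(classified)
    results["stage_counts"]["qc_rejected"] = len(rejected)
    results["rejected"] = rejected
    log.info("QC: %d rows in, %d rejected", len(classified), len(rejected))

    if coding is not None:
        analysis["is_coding"] = annotate_membership(analysis, coding)
    if lowcomplexity is not None:
        analysis["is_lc"] = annotate_membership(analysis, lowcomplexity)

    uniq = analysis.drop_duplicates(subset=VARIANT_KEY).reset_index(drop=True)
    if coding is not None:
        results["table1"] = annotation_summary(uniq, uniq["is_coding"].to_numpy(), "coding")

    if ref_list is not None:
        indels = uniq[uniq["is_indel"]]
        _, ref_summary = variants.match_reference_list(indels, ref_list)
        results["reference_absence"] = ref_summary

    sig = loci_mod.select_significant(analysis, cfg.p_threshold)
    results["stage_counts"]["significant_rows"] = len(sig)
    if sig.empty:
        log.warning("no genome-wide-significant variants: loci/enrichment skipped")
        results["loci"] = []
        results["n_loci"] = 0
        return results

    candidates = loci_mod.build_loci(sig, cfg.flank)
    retained = loci_mod.resolve_overlaps(candidates)
    retained, partition = loci_mod.assign_variants(retained, uniq)
    results["loci"] = retained
    results["n_loci"] = len(retained)
    results["partition"] = partition
    results["loci_table"] = loci_mod.loci_table(retained)

    # per-locus statistics come from the lead trait of each retained locus
    locus_frames = []
    for loc in retained:
        trait_stats = analysis[analysis["TRAIT"] == loc.trait] if "TRAIT" in analysis else analysis
        members = loc.members.merge(
            trait_stats[VARIANT_KEY + ["CHI2"]], on=VARIANT_KEY, how="inner",
            suffixes=("", "_trait"),
        )
        if members.empty:
            log.warning("locus %s: no member statistics for trait %s", loc.locus_id, loc.trait)
            continue
        members["locus_id"] = loc.locus_id
        locus_frames.append(members)

    sets = []
    for members in locus_frames:
        log_bf = finemap.log_bayes_factor(members["CHI2"].to_numpy())
        post = finemap.locus_posteriors(log_bf)
        sets.append(finemap.credible_set(members, post, cfg.mass, members["locus_id"].iloc[0]))
    results["credible_sets"] = sets
    results["credible_summary"] = finemap.summarize_sets(sets, cfg.posterior_cutoff)

    enr_frames = [f for f in locus_frames]
    fits = {}
    for which in cfg.annotations:
        try:
            data = EnrichmentData.from_loci(
                [
                    (finemap.log_bayes_factor(f["CHI2"].to_numpy()), _annotation_mask(f, which))
                    for f in enr_frames
                ],
                [f["locus_id"].iloc[0] for f in enr_frames],
            )
        except ValueError as exc:
            log.warning("annotation %s skipped: %s", which, exc)
            continue
        fits[which] = estimate_lambda(data)
        if which == "indel" and cfg.exclude_low_complexity_rerun and "is_lc" in analysis:
            exclude = np.concatenate([f["is_lc"].to_numpy() for f in enr_frames])
            fit_excl, dropped = rerun_excluding(data, exclude)
            if dropped:
                log.warning("low-complexity rerun dropped %d emptied loci", dropped)
            fits["indel_excl_lowcomplexity"] = fit_excl
    results["enrichment"] = fits

    tests: dict = {}
    if "is_lc" in analysis:
        inl = pd.concat(locus_frames) if locus_frames else uniq.iloc[0:0]
        t = [
            [int((inl["is_indel"] & inl["is_lc"]).sum()),
             int((inl["is_indel"] & ~inl["is_lc"]).sum())],
            [int((~inl["is_indel"] & inl["is_lc"]).sum()),
             int((~inl["is_indel"] & ~inl["is_lc"]).sum())],
        ]
        try:
            tests["lowcomplexity_chi2_yates"] = chi_square_2x2(t, correction=True)
            tests["lowcomplexity_chi2"] = chi_square_2x2(t, correction=False)
            tests["lowcomplexity_table"] = t
        except ValueError as exc:
            log.warning("low-complexity chi-square skipped: %s", exc)
    t2 = results["credible_summary"]["class_by_cutoff_table"]
    try:
        tests["posterior_cutoff_chi2"] = chi_square_2x2(t2, correction=False)
    except ValueError as exc:
        log.warning("posterior-cutoff chi-square skipped: %s", exc)
    if "BETA" in analysis.columns and sets:
        in_sets = pd.concat([cs.table[cs.table["in_set"]] for cs in sets])
        if "BETA" not in in_sets.columns:
            in_sets = in_sets.merge(
                analysis[VARIANT_KEY + ["BETA"]].drop_duplicates(subset=VARIANT_KEY),
                on=VARIANT_KEY, how="left",
            )
        a = in_sets.loc[in_sets["is_indel"], "BETA"].abs().dropna()
        b = in_sets.loc[~in_sets["is_indel"], "BETA"].abs().dropna()
        if len(a) and len(b):
            u, p = mann_whitney_u(a, b)
            tests["effect_size_mannwhitney"] = {"U": u, "p": p, "n_indel": len(a), "n_snp": len(b)}
    results["tests"] = tests

    results["stage_counts"]["analysis_variants"] = len(uniq)
    results["stage_counts"]["in_loci"] = int(partition["in_loci"].sum())
    results["stage_counts"]["rest_of_genome"] = int(partition["rest_of_genome"].sum())
    return results


def _fmt_lambda_row(name: str, fit, pct_in: float, n_in: int,
                    pct_out: float, n_out: int) -> str:
    lam = f"({fit.lambda_hat:.1f})" if fit.lambda_hat < -10 else f"{fit.lambda_hat:.2f}"
    return (
        f"{name}\t{pct_in:.1f}% ({n_in:,}) versus {pct_out:.1f}% ({n_out:,})"
        f"\t{lam} ({fit.p_value:.2g})"
    )


def report_tables(results: dict, outdir: str | Path) -> dict[str, Path]:
    """Write the report bundle (loci, credible sets, enrichment, contingency
    summaries, manifest) as TSV/JSON with fixed float formatting."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if "table1" in results:
        paths["table1"] = outdir / "class_by_coding.tsv"
        results["table1"].to_csv(paths["table1"], sep="\t", index=False, float_format="%.4f")
    if results.get("loci"):
        paths["loci"] = outdir / "loci.tsv"
        results["loci_table"].to_csv(paths["loci"], sep="\t", index=False, float_format="%.6g")
        paths["credible"] = outdir / "credible_sets.tsv"
        cols = ["locus_id"] + VARIANT_KEY + ["vclass", "CHI2", "posterior", "cumulative", "in_set"]
        pd.concat([cs.table for cs in results["credible_sets"]])[cols].to_csv(
            paths["credible"], sep="\t", index=False, float_format="%.6g"
        )
    if results.get("enrichment"):
        paths["enrichment"] = outdir / "enrichment.tsv"
        rows = []
        for name, fit in results["enrichment"].items():
            rows.append(
                {
                    "annotation": name,
                    "lambda": f"{fit.lambda_hat:.6g}",
                    "fold_enrichment": f"{fit.fold_enrichment:.6g}",
                    "lrt_stat": f"{fit.lrt_stat:.6g}",
                    "p": f"{fit.p_value:.6g}",
                    "iterations": fit.iterations,
                    "converged": fit.converged,
                    "boundary": fit.boundary,
                    "identifiable": fit.identifiable,
                }
            )
        pd.DataFrame(rows).to_csv(paths["enrichment"], sep="\t", index=False)

    manifest = {
        "config": results["config"],
        "stage_counts": results["stage_counts"],
        "n_loci": results.get("n_loci", 0),
        "credible_summary": {
            k: v for k, v in results.get("credible_summary", {}).items()
            if not isinstance(v, list)
        },
        "tests": {
            k: (
                {"statistic": round(v.statistic, 6), "p": v.p_display}
                if hasattr(v, "statistic") else v
            )
            for k, v in results.get("tests", {}).items()
        },
        "reference_absence": results.get("reference_absence"),
    }
    paths["manifest"] = outdir / "run_manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return paths
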