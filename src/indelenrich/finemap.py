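"""Single-causal-variant fine-mapping: Bayes factors, posterior
probabilities of causality, and 95% credible sets.

Under the assumption of exactly one causal variant per locus, the posterior
for variant i is

    P(i causal | data) = pi_i * BF_i / sum_j pi_j * BF_j,

with the asymptotic approximation log BF_i = chi2_i / 2 from the 1-df
association chi-square. With uniform priors this is a softmax of chi2/2.
A Wakefield-style approximate Bayes factor from (beta, se) is available as
an alternative. All normalisation is done in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp


def log_bayes_factor(chi2: np.ndarray | float) -> np.ndarray | float:
    """Asymptotic log Bayes factor chi2 / 2 (natural log)."""
    chi2 = np.asarray(chi2, dtype=float)
    if (chi2 < 0).any():
        raise ValueError("chi-square statistics must be nonnegative")
    out = chi2 / 2.0
    return float(out) if out.ndim == 0 else out

def wakefield_log_abf(beta, se, prior_variance: float = 0.04):
    """Wakefield approximate log Bayes factor from effect size and SE.

    log ABF = 0.5*log(se^2 / (se^2 + W)) + z^2/2 * W / (se^2 + W),
    with z = beta/se and prior effect variance W (default 0.04,
    i.e. prior SD 0.2 on the standardised effect).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    v = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + prior_variance)) + z2 / 2.0 * prior_variance / (v + prior_variance)


def locus_posteriors(log_bf: np.ndarray, prior: np.ndarray | None = None) -> np.ndarray:
    """Posterior probability of causality for each variant at one locus.

    ``prior`` defaults to uniform; it must be nonnegative and sum to 1
    (within 1e-9) when supplied. Computed via log-sum-exp for stability.
    """
    log_bf = np.asarray(log_bf, dtype=float)
    if log_bf.size == 0:
        raise ValueError("empty locus")
    if prior is None:
        log_prior = np.zeros_like(log_bf)  # uniform; constant cancels
    else:
        prior = np.asarray(prior, dtype=float)
        if (prior < 0).any() or prior.sum() <= 0:
            raise ValueError("prior weights must be nonnegative with positive sum")
        if abs(prior.sum() - 1.0) > 1e-9:
            raise ValueError("prior weights must sum to 1")
        with np.errstate(divide="ignore"):
            log_prior = np.log(prior)
    w = log_prior + log_bf
    return np.exp(w - logsumexp(w))


@dataclass
class CredibleSet:
    """Posterior-ranked variants at one locus with 95%-set membership.

    ``table`` is sorted by posterior descending (ties broken by larger
    chi-square then coordinate order) and carries columns ``posterior``,
    ``cumulative`` and ``in_set``; the set is the shortest prefix whose
    cumulative mass reaches the target.
    """

    locus_id: str
    mass: float
    table: pd.DataFrame = field(repr=False)

    @property
    def size(self) -> int:
        return int(self.table["in_set"].sum())

    @property
    def top(self) -> pd.Series:
        return self.table.iloc[0]


def credible_set(
    members: pd.DataFrame,
    posteriors: np.ndarray,
    mass: float = 0.95,
    locus_id: str = "",
) -> CredibleSet:
    """Form the smallest credible set of target ``mass`` from per-variant
    posteriors.

    Sorting descending by posterior and taking the shortest prefix with
    cumulative mass >= target yields a minimum-cardinality set.
    """
    if not 0 < mass <= 1:
        raise ValueError("mass must lie in (0, 1]")
    posteriors = np.asarray(posteriors, dtype=float)
    if len(posteriors) != len(members):
        raise ValueError("posterior vector length mismatch")
    tab = members.copy()
    tab["posterior"] = posteriors
    sort_cols = ["posterior"]
    ascending = [False]
    if "CHI2" in tab.columns:
        sort_cols.append("CHI2")
        ascending.append(False)
    sort_cols += ["CHROM", "POS"]
    ascending += [True, True]
    tab = tab.sort_values(sort_cols, ascending=ascending, kind="stable").reset_index(drop=True)
    tab["cumulative"] = tab["posterior"].cumsum()
    k = int(np.searchsorted(tab["cumulative"].to_numpy(), mass - 1e-12) + 1)
    k = min(k, len(tab))
    tab["in_set"] = np.arange(len(tab)) < k
    return CredibleSet(locus_id=locus_id, mass=mass, table=tab)


def summarize_sets(sets: list[CredibleSet], posterior_cutoff: float = 0.1) -> dict:
    """Aggregate credible sets across loci.

    Reports the SNP/indel composition of the union of 95% sets, the class
    split above the posterior cutoff, the number of loci whose
    top-posterior variant is an indel, and the 2x2 table
    (class x posterior >= cutoff) over credible-set variants for the
    downstream chi-square test.
    """
    n_snp = n_indel = hi_snp = hi_indel = top_indel = 0
    sizes = []
    for cs in sets:
        in_set = cs.table[cs.table["in_set"]]
        sizes.append(len(in_set))
        indel = in_set["is_indel"].to_numpy() if "is_indel" in in_set else np.zeros(len(in_set), bool)
        hi = in_set["posterior"].to_numpy() >= posterior_cutoff
        n_indel += int(indel.sum())
        n_snp += int((~indel).sum())
        hi_indel += int((indel & hi).sum())
        hi_snp += int((~indel & hi).sum())
        if len(in_set) and bool(cs.top.get("is_indel", False)):
            top_indel += 1
    return {
        "n_loci": len(sets),
        "snps_in_sets": n_snp,
        "indels_in_sets": n_indel,
        "snps_posterior_ge_cutoff": hi_snp,
        "indels_posterior_ge_cutoff": hi_indel,
        "loci_with_indel_top": top_indel,
        "mean_set_size": float(np.mean(sizes)) if sizes else float("nan"),
        "posterior_cutoff": posterior_cutoff,
        # rows: indel/SNP; cols: >= cutoff / below cutoff (credible-set variants)
        "class_by_cutoff_table": [
            [hi_indel, n_indel - hi_indel],
            [hi_snp, n_snp - hi_snp],
        ],
    }
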