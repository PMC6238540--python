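"""SNP-locus bias filtering and the gene/SNP read-sufficiency filter.

Two Fisher-exact screens remove SNP loci whose allelic read assignment is
distorted by mapping artifacts: (1) parental-strain reads versus the
mock-F1 allelic reads built from the same parental data; (2) allelic
ratios with versus without multi-mapped reads.  Each screen is a separate
hypothesis family (BH-adjusted independently); a locus is removed when it
is flagged in either.

The sufficiency filter then keeps genes with at least ``min_snps`` SNP
loci that are adequately covered in every replicate: total allelic reads
>= ``min_tp_total`` at every timepoint and each allele's sum across
timepoints >= ``min_allele_total``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneTimecourse

log = logging.getLogger(__name__)

BIAS_CONTEXTS = ("parental_mock", "unique_multi")


@dataclass(frozen=True)
class SnpBiasRecord:
    """One SNP locus's 2x2 table in one filter context, with its verdict."""

    snp_id: str
    ctx: str
    table: tuple
    p_raw: float
    p_adj: float
    flagged: bool


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums, over all tables with the same margins, the hypergeometric
    probabilities not exceeding that of the observed table.  Computed in
    exact integer arithmetic (probabilities share the common denominator
    C(n, a+c)), so tie handling needs no floating-point tolerance.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("at least one margin must be positive")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(lo, hi + 1):
        num_k = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num_k <= num_obs:
            total += num_k
    p = total / math.comb(n, c1)
    return min(p, 1.0)


def adjust_pvalues_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_biased_snps(records: pd.DataFrame, alpha: float = 0.05):
    """Apply the two Fisher-exact bias screens and remove flagged loci.

    ``records`` columns: snp_id, ctx in {parental_mock, unique_multi},
    a, b, c, d (the 2x2 table, rows = the two datasets of the context).
    BH adjustment is applied within each context; a SNP is removed when
    flagged in either.  Returns (retained snp list, verdicts table).
    """
    if len(records) == 0:
        log.warning("bias filter: empty record table, nothing to filter")
        return [], pd.DataFrame(columns=["snp_id", "ctx", "a", "b", "c", "d",
                                         "p_raw", "p_adj", "flagged", "reason"])
    records = records.copy()
    bad_ctx = set(records["ctx"]) - set(BIAS_CONTEXTS)
    if bad_ctx:
        raise ValueError(f"unknown bias filter context(s): {sorted(bad_ctx)}")
    records["p_raw"] = [
        fisher_exact_2x2(r.a, r.b, r.c, r.d) for r in records.itertuples()
    ]
    records["p_adj"] = np.nan
    for ctx, idx in records.groupby("ctx").groups.items():
        records.loc[idx, "p_adj"] = adjust_pvalues_bh(records.loc[idx, "p_raw"])
    records["flagged"] = records["p_adj"] < alpha
    records["reason"] = np.where(records["flagged"],
                                 "bias:" + records["ctx"].astype(str), "")
    flagged_snps = set(records.loc[records["flagged"], "snp_id"])
    retained = [s for s in records["snp_id"].unique() if s not in flagged_snps]
    log.info("bias filter: %d/%d SNP loci removed",
             len(flagged_snps), records["snp_id"].nunique())
    return retained, records


def sufficiency_filter(gene: GeneTimecourse, min_snps: int = 5,
                       min_tp_total: int = 10, min_allele_total: int = 15):
    """Gene-level read-sufficiency decision plus per-SNP pass flags.

    A SNP passes in a replicate when its two-allele total is at least
    ``min_tp_total`` at every timepoint and each allele's sum across
    timepoints is at least ``min_allele_total``; it must pass in every
    replicate to count.  The gene is retained when at least ``min_snps``
    SNPs pass.  Returns (retained, per-SNP boolean array).
    """
    counts = gene.counts  # (snp, rep, tp, allele)
    tp_total_ok = (counts.sum(axis=3) >= min_tp_total).all(axis=2)  # (snp, rep)
    allele_total_ok = (counts.sum(axis=2) >= min_allele_total).all(axis=2)  # (snp, rep)
    snp_pass = (tp_total_ok & allele_total_ok).all(axis=1)  # every replicate
    return bool(snp_pass.sum() >= min_snps), snp_pass
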