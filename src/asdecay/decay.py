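"""Allele-specific decay inference: GLM fit, SNP bootstrap, calls, FDR.

For each gene and replicate the decay-rate difference delta_lambda =
lambda1 - lambda2 is the negated time slope of a binomial logit-linear fit
pooling every (SNP, timepoint) cell (see :mod:`asdecay.glm`).  Uncertainty
comes from resampling the gene's SNP loci with replacement (default 5,000
lists) and re-fitting: the bootstrap mean and standard deviation give a
z-score and a normal two-sided p-value, BH-adjusted across genes within
each replicate.  A gene is called ASD when, in every replicate, adjusted
p < 0.05 and |delta_lambda| > 0.06 with a concordant sign.  The empirical
FDR of this dual-threshold rule is estimated by shuffling gene labels
between the replicates (which preserves each replicate's marginal
distribution while breaking cross-replicate concordance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .filtering import adjust_pvalues_bh, sufficiency_filter
from .glm import DecayFit, fit_binomial_logit, fit_binomial_logit_many
from .io import GeneTimecourse, iter_genes
from .simulate import derive_rng

log = logging.getLogger(__name__)

__all__ = [
    "DecayFit", "BootstrapSummary", "AsdCall", "fit_logit_decay",
    "bootstrap_statistic", "adjust_pvalues_bh", "call_asd",
    "permutation_fdr", "select_control_genes", "analyze_decay",
]


@dataclass
class BootstrapSummary:
    """Bootstrap-over-SNP-loci summary of one statistic for one replicate."""

    statistic: str
    n_boot: int
    boot_mean: float
    boot_sd: float
    z: float
    p_raw: float
    seed: int
    point_estimate: float
    n_dropped: int = 0
    p_adj: float = float("nan")


@dataclass
class AsdCall:
    """Joint (both-replicate) significance decision for one gene."""

    gene_id: str
    summaries: dict = field(default_factory=dict)   # replicate -> BootstrapSummary
    significant: bool = False
    direction: str = "none"                          # allele1_faster / allele2_faster
    combined: float = float("nan")                   # mean of replicate point estimates


def fit_logit_decay(gene: GeneTimecourse, replicate, snp_subset=None) -> DecayFit:
    """Point MLE of (alpha, beta) for one replicate; delta_lambda = -beta."""
    n1, ntot = gene.cells(replicate)
    if snp_subset is not None:
        idx = [gene.snp_ids.index(s) if isinstance(s, str) else int(s)
               for s in snp_subset]
        if len(idx) == 0:
            raise ValueError("snp_subset must be non-empty")
        n1, ntot = n1[idx], ntot[idx]
    return fit_binomial_logit(n1, ntot, gene.timepoints)


def _log2fc(n1: float, n2: float, pseudocount: float = 0.5) -> float:
    if n1 == 0 or n2 == 0:
        n1, n2 = n1 + pseudocount, n2 + pseudocount
    return float(np.log2(n1 / n2))


def bootstrap_statistic(gene: GeneTimecourse, replicate,
                        statistic: str = "delta_lambda",
                        n_boot: int = 5000, seed: int = 0) -> BootstrapSummary:
    """Resample the gene's SNP loci with replacement and recompute a statistic.

    ``delta_lambda`` re-fits the GLM on each resampled list; ``log2fc_t0``
    sums the resampled loci's t=0 counts per allele before taking the log2
    ratio (robust to low-count loci).  p_raw = 2*(1 - Phi(|z|)) with
    z = boot_mean / boot_sd; a degenerate boot_sd of 0 maps to p = 0 when
    the mean is nonzero and 1 otherwise.
    """
    n1, ntot = gene.cells(replicate)
    n = gene.n_snps
    if n < 1:
        raise ValueError("gene has no SNP loci")
    rng = derive_rng(seed, gene.gene_id, replicate, statistic, "boot")
    W = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)

    n_dropped = 0
    if statistic == "delta_lambda":
        fit = fit_binomial_logit(n1, ntot, gene.timepoints)
        point = fit.delta_lambda
        S, N = W @ n1, W @ ntot
        _, b, conv, _ = fit_binomial_logit_many(S, N, gene.timepoints)
        values = -b[conv]
        n_dropped = int(n_boot - conv.sum())
    elif statistic == "log2fc_t0":
        n2 = ntot - n1
        point = _log2fc(n1[:, 0].sum(), n2[:, 0].sum())
        s1, s2 = W @ n1[:, 0], W @ n2[:, 0]
        keep = (s1 + s2) > 0
        s1, s2 = s1[keep], s2[keep]
        zero = (s1 == 0) | (s2 == 0)
        values = np.log2((s1 + 0.5 * zero) / (s2 + 0.5 * zero))
        n_dropped = int(n_boot - keep.sum())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    if n_dropped > 0.01 * n_boot:
        log.warning("gene %s rep %s: %d/%d bootstrap resamples dropped",
                    gene.gene_id, replicate, n_dropped, n_boot)
    mean = float(values.mean()) if values.size else float("nan")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if sd > 0:
        z = mean / sd
        p_raw = float(2.0 * norm.sf(abs(z)))
    else:
        z = float("inf") if mean != 0 else 0.0
        p_raw = 0.0 if mean != 0 else 1.0
    return BootstrapSummary(statistic=statistic, n_boot=n_boot, boot_mean=mean,
                            boot_sd=sd, z=z, p_raw=p_raw, seed=seed,
                            point_estimate=float(point), n_dropped=n_dropped)


def _dual_call(summaries: dict, p_adj_threshold: float, min_abs: float,
               labels=("allele1_faster", "allele2_faster")) -> tuple[bool, str]:
    """Both-replicate dual-threshold rule with sign concordance."""
    if len(summaries) < 2:
        raise ValueError("calls require summaries for at least two replicates")
    stats = np.array([s.boot_mean for s in summaries.values()])
    padj = np.array([s.p_adj for s in summaries.values()])
    ok = (np.all(padj < p_adj_threshold)
          and np.all(np.abs(stats) > min_abs)
          and (np.all(stats > 0) or np.all(stats < 0)))
    if not ok:
        return False, "none"
    return True, labels[0] if stats[0] > 0 else labels[1]


def call_asd(summaries: dict, p_adj_threshold: float = 0.05,
             min_abs_dlambda: float = 0.06, gene_id: str = "") -> AsdCall:
    """ASD decision: adjusted p < threshold and |delta_lambda| > 0.06 in every
    replicate, biased toward the same allele.  Positive delta_lambda means
    allele 1 decays faster."""
    sig, direction = _dual_call(summaries, p_adj_threshold, min_abs_dlambda)
    combined = float(np.mean([s.point_estimate for s in summaries.values()]))
    return AsdCall(gene_id=gene_id, summaries=summaries, significant=sig,
                   direction=direction, combined=combined)


def analyze_decay(counts: pd.DataFrame, n_boot: int = 5000, seed: int = 0,
                  p_adj_threshold: float = 0.05, min_abs_dlambda: float = 0.06,
                  statistic: str = "delta_lambda", apply_sufficiency: bool = True,
                  min_snps: int = 5):
    """Full decay (or abundance) inference over a counts table.

    Returns (results frame, calls dict).  The results frame has one row per
    retained gene and replicate; BH adjustment is applied across genes
    within each replicate.
    """
    rows = []
    summaries: dict[str, dict] = {}
    n_insufficient = 0
    for gene in iter_genes(counts):
        if apply_sufficiency:
            ok, _ = sufficiency_filter(gene, min_snps=min_snps)
            if not ok:
                n_insufficient += 1
                continue
        summaries[gene.gene_id] = {}
        for rep in gene.replicates:
            summ = bootstrap_statistic(gene, rep, statistic=statistic,
                                       n_boot=n_boot, seed=seed)
            if statistic == "delta_lambda":
                fit = fit_logit_decay(gene, rep)
                alpha, beta = fit.alpha, fit.beta
            else:
                alpha = beta = float("nan")
            summaries[gene.gene_id][rep] = summ
            rows.append({"gene_id": gene.gene_id, "rep": rep,
                         "n_snps": gene.n_snps, "alpha": alpha, "beta": beta,
                         "statistic": statistic,
                         "point_estimate": summ.point_estimate,
                         "boot_mean": summ.boot_mean, "boot_sd": summ.boot_sd,
                         "z": summ.z, "p_raw": summ.p_raw})
    if n_insufficient:
        log.warning("sufficiency filter: %d gene(s) dropped", n_insufficient)
    results = pd.DataFrame(rows)
    if results.empty:
        return results, {}
    results["p_adj"] = np.nan
    for rep, idx in results.groupby("rep").groups.items():
        adj = adjust_pvalues_bh(results.loc[idx, "p_raw"])
        results.loc[idx, "p_adj"] = adj
        for gid, a in zip(results.loc[idx, "gene_id"], adj):
            summaries[gid][rep].p_adj = float(a)

    from .abundance import call_asa  # local: avoids import cycle

    caller = call_asd if statistic == "delta_lambda" else call_asa
    calls = {gid: caller(s, p_adj_threshold, min_abs_dlambda, gene_id=gid)
             for gid, s in summaries.items()}
    results["significant"] = results["gene_id"].map(
        lambda g: calls[g].significant)
    results["direction"] = results["gene_id"].map(lambda g: calls[g].direction)
    if statistic == "delta_lambda":
        results = results.rename(columns={"point_estimate": "delta_lambda"})
        results["asd_call"] = results.pop("significant")
    return results, calls


def _pivot(results: pd.DataFrame, value_col: str) -> pd.DataFrame:
    return results.pivot(index="gene_id", columns="rep", values=value_col)


def permutation_fdr(results: pd.DataFrame, thresholds, n_perm: int = 100,
                    seed: int = 0, p_adj_threshold: float = 0.05) -> pd.DataFrame:
    """Empirical FDR of the dual-threshold rule by cross-replicate shuffling.

    For each permutation, the gene labels of every replicate after the
    first are shuffled, breaking concordance while preserving each
    replicate's marginal (p_adj, statistic) distribution.  FDR(x) = mean
    permuted pass count / real pass count (NaN when no real gene passes x).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    value_col = "boot_mean"
    stats = _pivot(results, value_col).to_numpy()
    padj = _pivot(results, "p_adj").to_numpy()
    if stats.shape[1] < 2:
        raise ValueError("permutation FDR requires at least two replicates")
    thresholds = np.asarray(list(thresholds), dtype=float)

    def pass_count(st, pa, x):
        ok = (pa < p_adj_threshold).all(axis=1) & (np.abs(st) > x).all(axis=1)
        concordant = (st > 0).all(axis=1) | (st < 0).all(axis=1)
        return int((ok & concordant).sum())

    real = np.array([pass_count(stats, padj, x) for x in thresholds])
    rng = derive_rng(seed, "perm_fdr")
    perm_counts = np.zeros((n_perm, thresholds.size))
    n_genes = stats.shape[0]
    for i in range(n_perm):
        st = stats.copy()
        pa = padj.copy()
        for r in range(1, stats.shape[1]):
            order = rng.permutation(n_genes)
            st[:, r] = stats[order, r]
            pa[:, r] = padj[order, r]
        perm_counts[i] = [pass_count(st, pa, x) for x in thresholds]
    mean_perm = perm_counts.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(real > 0, mean_perm / np.maximum(real, 1), np.nan)
    return pd.DataFrame({"threshold": thresholds, "real_count": real,
                         "mean_perm_count": mean_perm, "fdr": fdr})


def select_control_genes(results: pd.DataFrame, p_threshold: float = 0.05,
                         max_abs_dlambda: float = 0.03,
                         max_boot_sd: float = 0.1) -> list:
    """Genes with no evidence of ASD in any replicate.

    Criteria (all replicates): raw bootstrap p > 0.05, |delta_lambda| <
    0.03, and bootstrap SD below min(0.1, the empirical 95% quantile of
    all genes' bootstrap SDs).
    """
    sd_cap = min(max_boot_sd, float(np.quantile(results["boot_sd"], 0.95)))
    ok = (results["p_raw"] > p_threshold) \
        & (results["boot_mean"].abs() < max_abs_dlambda) \
        & (results["boot_sd"] < sd_cap)
    per_gene = ok.groupby(results["gene_id"]).all()
    return sorted(per_gene.index[per_gene])
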