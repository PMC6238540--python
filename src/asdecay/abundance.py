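"""Steady-state allele-specific abundance (ASA) and joint ASD/ASA analysis.

ASA is estimated from the 0 h samples only (steady state, before
transcriptional arrest): the statistic is the log2 allelic fold change of
summed t=0 counts, bootstrapped over SNP loci exactly like the decay
statistic, with the dual thresholds adjusted p < 0.05 and a twofold
divergence (|log2FC| > 1) in both replicates with a concordant direction.

The joint classification crosses the two calls per gene.  A significant
decay difference without an abundance difference is the compensatory
configuration: at steady state N1/N2 = (k1/k2)/(lambda1/lambda2), so a
balanced abundance with unequal decay implies transcription favouring the
faster-decaying allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decay import AsdCall, BootstrapSummary, _dual_call, analyze_decay

__all__ = [
    "AsaCall", "GeneDecision", "log2_allelic_fc", "call_asa", "analyze_asa",
    "classify_joint", "classify_grid", "validation_asd", "compare_platforms",
]


@dataclass
class AsaCall:
    """Joint (both-replicate) abundance decision for one gene."""

    gene_id: str
    summaries: dict = field(default_factory=dict)
    significant: bool = False
    direction: str = "none"          # allele1_higher / allele2_higher
    combined: float = float("nan")   # mean of replicate log2FC point estimates


@dataclass
class GeneDecision:
    """Cross-classification of one gene by ASD and ASA."""

    gene_id: str
    asd: AsdCall
    asa: AsaCall
    category: str          # ASA_only / ASD_only / both / neither
    compensatory: bool


def log2_allelic_fc(n1_total, n2_total, pseudocount: float = 0.5) -> float:
    """log2((n1+d)/(n2+d)); the pseudocount is applied only when a total is 0."""
    if n1_total < 0 or n2_total < 0:
        raise ValueError("totals must be non-negative")
    if n1_total == 0 and n2_total == 0:
        raise ValueError("both allele totals are zero")
    if n1_total == 0 or n2_total == 0:
        n1_total, n2_total = n1_total + pseudocount, n2_total + pseudocount
    return float(np.log2(n1_total / n2_total))


def call_asa(summaries: dict, p_adj_threshold: float = 0.05,
             min_abs_log2fc: float = 1.0, gene_id: str = "") -> AsaCall:
    """ASA decision mirroring the ASD rule with the log2FC statistic."""
    sig, direction = _dual_call(summaries, p_adj_threshold, min_abs_log2fc,
                                labels=("allele1_higher", "allele2_higher"))
    combined = float(np.mean([s.point_estimate for s in summaries.values()]))
    return AsaCall(gene_id=gene_id, summaries=summaries, significant=sig,
                   direction=direction, combined=combined)


def analyze_asa(counts: pd.DataFrame, n_boot: int = 5000, seed: int = 0,
                p_adj_threshold: float = 0.05, min_abs_log2fc: float = 1.0,
                apply_sufficiency: bool = True, min_snps: int = 5):
    """Bootstrap ASA inference over a counts table; see :func:`analyze_decay`."""
    results, calls = analyze_decay(
        counts, n_boot=n_boot, seed=seed, p_adj_threshold=p_adj_threshold,
        min_abs_dlambda=min_abs_log2fc, statistic="log2fc_t0",
        apply_sufficiency=apply_sufficiency, min_snps=min_snps)
    if not results.empty:
        results = results.rename(columns={"point_estimate": "log2fc"})
        results["asa_call"] = results.pop("significant")
    return results, calls


def classify_joint(asd_calls: dict, asa_calls: dict):
    """Cross ASD and ASA calls gene by gene.

    Returns (decision frame, summary dict).  The summary reports the gene
    tallies per category plus the two headline fractions: ASA genes
    lacking ASD and ASD genes lacking ASA (the compensatory fraction).
    """
    if set(asd_calls) != set(asa_calls):
        raise ValueError("ASD and ASA calls cover different gene universes")
    rows, decisions = [], []
    for gid in sorted(asd_calls):
        asd, asa = asd_calls[gid], asa_calls[gid]
        if asd.significant and asa.significant:
            category = "both"
        elif asd.significant:
            category = "ASD_only"
        elif asa.significant:
            category = "ASA_only"
        else:
            category = "neither"
        compensatory = bool(asd.significant and not asa.significant
                            and asd.direction != "none")
        decisions.append(GeneDecision(gid, asd, asa, category, compensatory))
        rows.append({"gene_id": gid, "asd_significant": asd.significant,
                     "asa_significant": asa.significant,
                     "asd_direction": asd.direction,
                     "asa_direction": asa.direction,
                     "delta_lambda": asd.combined, "log2fc": asa.combined,
                     "category": category, "compensatory": compensatory})
    frame = pd.DataFrame(rows)
    n_asd = int(frame["asd_significant"].sum())
    n_asa = int(frame["asa_significant"].sum())
    n_both = int((frame["category"] == "both").sum())
    summary = {
        "n_genes": len(frame),
        "n_asd": n_asd,
        "n_asa": n_asa,
        "n_both": n_both,
        "frac_asa_without_asd": (n_asa - n_both) / n_asa if n_asa else float("nan"),
        "frac_asd_without_asa": (n_asd - n_both) / n_asd if n_asd else float("nan"),
    }
    return decisions, frame, summary


def _recall(summaries: dict, caller, p_thr: float, min_abs: float, gid: str):
    return caller(summaries, p_thr, min_abs, gene_id=gid)


def classify_grid(asd_calls: dict, asa_calls: dict, p_adj_grid,
                  min_abs_dlambda: float = 0.06, min_abs_log2fc: float = 1.0):
    """Sweep the adjusted-p threshold over a grid for both call sets.

    Re-applies the dual-threshold rules at every grid value (same
    magnitude thresholds) and tabulates the two headline fractions, the
    threshold-robustness view of the compensatory pattern.
    """
    from .decay import call_asd

    rows = []
    for p_thr in p_adj_grid:
        asd = {g: _recall(c.summaries, call_asd, p_thr, min_abs_dlambda, g)
               for g, c in asd_calls.items()}
        asa = {g: _recall(c.summaries, call_asa, p_thr, min_abs_log2fc, g)
               for g, c in asa_calls.items()}
        _, _, summary = classify_joint(asd, asa)
        rows.append({"p_adj_threshold": p_thr, **summary})
    return pd.DataFrame(rows)


def validation_asd(counts_t0, counts_t1) -> float:
    """Ratio-of-ratios decay readout from two deep-count timepoints.

    ``counts_t0`` and ``counts_t1`` are (allele1, allele2) totals at the
    early and late timepoint; returns
    log2((m1_late/m2_late) / (m1_early/m2_early)).  On noise-free model
    data this equals -delta_lambda * (t_late - t_early) / ln 2.
    """
    m0_1, m0_2 = counts_t0
    m1_1, m1_2 = counts_t1
    if min(m0_1, m0_2, m1_1, m1_2) <= 0:
        raise ValueError("validation counts must all be positive")
    return float(np.log2((m1_1 / m1_2) / (m0_1 / m0_2)))


def compare_platforms(dlambda_a, dlambda_b):
    """Pearson correlation between two technologies' delta-lambda estimates."""
    a = np.asarray(dlambda_a, dtype=float)
    b = np.asarray(dlambda_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be finite")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
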