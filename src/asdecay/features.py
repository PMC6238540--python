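"""Allele-level sequence features and stable-vs-unstable comparisons.

Features computed per allele pair: SNP density (SNPs per kb, whole
transcript or per region), canonical miRNA seed-site counts (8mer,
7mer-m8, 7mer-1A), windowed local secondary-structure differences (the
max |delta MFE| over windows centred on each variant), and the codon
adaptation index.  Group comparisons between genes with a significant
decay difference and density-matched controls use two-sided KS and
Mann-Whitney U tests.

The folding engine is pluggable: any callable mapping a sequence to an
MFE-like scalar.  ``nussinov_fold`` (negated maximum base-pair count,
AU/GC/GU pairs, hairpin loops >= 3) is the bundled deterministic engine;
an adapter for an external thermodynamic folder can be passed instead.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "AlleleSequencePair", "MirnaSeed", "snp_density", "count_mirna_sites",
    "site_difference_test", "mfe_windows", "nussinov_fold", "rnafold_engine",
    "cai", "compare_groups", "select_matched_controls",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlleleSequencePair:
    """Paired allele transcripts (5'->3'), substitution variants only.

    ``variant_positions`` are 1-based transcript coordinates;
    ``regions`` maps UTR5/CDS/UTR3 to 1-based inclusive (start, end) spans.
    """

    gene_id: str
    seq_allele1: str
    seq_allele2: str
    variant_positions: list
    regions: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.seq_allele1) != len(self.seq_allele2):
            raise ValueError("allele sequences must have equal length "
                             "(substitution variants only)")
        L = len(self.seq_allele1)
        if any(p < 1 or p > L for p in self.variant_positions):
            raise ValueError("variant positions must fall within the sequence")

    def region_of(self, pos: int) -> str:
        for name, (lo, hi) in self.regions.items():
            if lo <= pos <= hi:
                return name
        return "NA"


@dataclass
class MirnaSeed:
    """A miRNA and the target patterns derived from its seed region.

    Site types follow the canonical hierarchy: an 8mer is a perfect match
    to positions 2-8 followed by an A in the target; 7mer-m8 matches
    positions 2-8; 7mer-1A matches positions 2-7 followed by an A.
    """

    mirna_id: str
    sequence: str  # 5'->3'

    def __post_init__(self):
        self.sequence = _rna(self.sequence)
        if len(self.sequence) < 8:
            raise ValueError("miRNA sequence must be at least 8 nt")

    @property
    def core6(self) -> str:
        """Target-strand match to miRNA positions 2-7."""
        return _revcomp(self.sequence[1:7])

    @property
    def m8_char(self) -> str:
        """Target base pairing miRNA position 8 (immediately 5' of the core)."""
        return _revcomp(self.sequence[7])


def snp_density(variant_positions, span_length_nt: float,
                region_span: tuple | None = None) -> float:
    """SNPs per kb over the whole transcript or a (start, end) region span."""
    if region_span is not None:
        lo, hi = region_span
        length = hi - lo + 1
        count = sum(1 for p in variant_positions if lo <= p <= hi)
    else:
        length = span_length_nt
        count = len(list(variant_positions))
    if length <= 0:
        raise ValueError("zero-length span")
    return 1000.0 * count / length


def count_mirna_sites(seq: str, seeds, top_k: int | None = None) -> int:
    """Total canonical seed-site count for a target sequence.

    ``seeds`` are :class:`MirnaSeed` objects ordered by expression rank
    (most expressed first); ``top_k`` restricts to the first k.  Each
    occurrence of a seed's 6mer core is classified once by its best
    supported type (8mer > 7mer-m8 > 7mer-1A) and counted if it reaches at
    least a 7mer.
    """
    target = _rna(seq)
    if top_k is not None:
        seeds = list(seeds)[:top_k]
    total = 0
    for seed in seeds:
        core = seed.core6
        m8 = seed.m8_char
        start = target.find(core)
        while start != -1:
            has_m8 = start >= 1 and target[start - 1] == m8
            has_a1 = start + 6 < len(target) and target[start + 6] == "A"
            if has_m8 or has_a1:  # 8mer, 7mer-m8 or 7mer-1A
                total += 1
            start = target.find(core, start + 1)
    return total


def site_difference_test(site_counts: pd.DataFrame, min_total: int = 10,
                         min_diff: int = 1) -> dict:
    """Stable-minus-unstable site-count differences, ASD versus control.

    ``site_counts`` columns: gene_id, group ('ASD' or 'control'),
    stable_sites, unstable_sites.  For the ASD group the stable allele is
    the slower-decaying one; for controls it is a seeded random label.
    Genes are kept when the two alleles carry >= ``min_total`` sites
    combined and differ by >= ``min_diff``.  Returns the two filtered
    difference samples, a two-sided Mann-Whitney U p-value between them,
    and per-group sign-test diagnostics against a zero median.
    """
    df = site_counts.copy()
    df["total"] = df["stable_sites"] + df["unstable_sites"]
    df["difference"] = df["stable_sites"] - df["unstable_sites"]
    kept = df[(df["total"] >= min_total) & (df["difference"].abs() >= min_diff)]
    out = {"n_asd": int((kept["group"] == "ASD").sum()),
           "n_control": int((kept["group"] == "control").sum()),
           "differences": kept[["gene_id", "group", "difference"]]}
    for grp in ("ASD", "control"):
        d = kept.loc[kept["group"] == grp, "difference"].to_numpy()
        out[f"median_{grp.lower()}"] = float(np.median(d)) if d.size else float("nan")
        nz = d[d != 0]
        if nz.size:
            out[f"sign_p_{grp.lower()}"] = float(
                sps.binomtest((nz > 0).sum(), nz.size, 0.5).pvalue)
        else:
            out[f"sign_p_{grp.lower()}"] = float("nan")
    if out["n_asd"] < 5 or out["n_control"] < 5:
        log.warning("site-difference test: post-filter group below 5 genes; "
                    "p-value reported as NA")
        out["p_mwu"] = float("nan")
    else:
        a = kept.loc[kept["group"] == "ASD", "difference"]
        c = kept.loc[kept["group"] == "control", "difference"]
        out["p_mwu"] = float(sps.mannwhitneyu(a, c, alternative="two-sided").pvalue)
    return out


def _window_span(pos: int, length: int, window: int) -> tuple[int, int]:
    """1-based inclusive window around a variant, shifted at transcript ends."""
    half = (window - 1) // 2
    if length < window:
        return 1, length
    start = pos - half
    start = max(1, min(start, length - window + 1))
    return start, start + window - 1


def mfe_windows(pair: AlleleSequencePair, window: int = 41, engine=None,
                positions=None) -> pd.DataFrame:
    """Per-variant windowed MFE difference between the alleles.

    For each variant a ``window``-nt segment centred on it is extracted
    from both alleles (shifted to abut the transcript end when the variant
    is closer than (window-1)/2 to an end; the whole transcript is used,
    flagged, when it is shorter than the window) and folded with
    ``engine``.  delta_mfe = MFE(allele1) - MFE(allele2).  Columns:
    pos, region, start, end, mfe1, mfe2, delta_mfe, truncated.
    """
    if window % 2 == 0:
        raise ValueError("window length must be odd")
    engine = engine or nussinov_fold
    L = len(pair.seq_allele1)
    rows = []
    for pos in (positions if positions is not None else pair.variant_positions):
        start, end = _window_span(pos, L, window)
        w1 = pair.seq_allele1[start - 1:end]
        w2 = pair.seq_allele2[start - 1:end]
        if len(w1) < window:
            log.warning("gene %s: transcript (%d nt) shorter than window %d; "
                        "whole transcript folded", pair.gene_id, L, window)
        mfe1 = float(engine(w1))
        mfe2 = float(engine(w2))
        rows.append({"pos": pos, "region": pair.region_of(pos), "start": start,
                     "end": end, "mfe1": mfe1, "mfe2": mfe2,
                     "delta_mfe": mfe1 - mfe2, "truncated": len(w1) < window})
    return pd.DataFrame(rows)


def max_abs_delta_mfe(per_variant: pd.DataFrame, by_region: bool = False):
    """Per-gene (or per-region) summary: the maximum |delta MFE| over variants."""
    if per_variant.empty:
        return float("nan") if not by_region else {}
    if by_region:
        return {region: float(g["delta_mfe"].abs().max())
                for region, g in per_variant.groupby("region")}
    return float(per_variant["delta_mfe"].abs().max())


def nussinov_fold(seq: str, min_loop: int = 3) -> float:
    """Base-pair-maximisation proxy MFE: minus the maximum number of
    nested AU/GC/GU pairs with hairpin loops of at least ``min_loop``.

    Deterministic O(n^3) dynamic programme; the bundled engine for the
    windowed structure comparison (a thermodynamic folder can be plugged
    in through the ``engine`` argument of :func:`mfe_windows`).
    """
    s = _rna(seq)
    n = len(s)
    if n == 0:
        return 0.0
    pairable = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if (s[i], s[j]) in _PAIRABLE:
                pairable[i, j] = 1
    M = np.zeros((n + 1, n + 1), dtype=np.int64)  # M[i, j] over s[i:j], half-open
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # exclusive
            best = M[i + 1, j]  # i unpaired
            ks = np.nonzero(pairable[i, i:j])[0] + i
            if ks.size:
                cand = 1 + M[i + 1, ks] + M[ks + 1, j]
                best = max(best, int(cand.max()))
            M[i, j] = best
    return -float(M[0, n])


def rnafold_engine(executable: str = "RNAfold"):
    """Adapter folding sequences with an external thermodynamic folder.

    Returns a callable seq -> MFE (kcal/mol) that shells out to the given
    RNAfold-compatible executable.
    """
    if shutil.which(executable) is None:
        raise FileNotFoundError(f"{executable} not found on PATH")

    def fold(seq: str) -> float:
        out = subprocess.run([executable, "--noPS"], input=_rna(seq) + "\n",
                             capture_output=True, text=True, check=True).stdout
        last = out.strip().splitlines()[-1]
        return float(last[last.rindex("(") + 1:last.rindex(")")])

    return fold


_STOP_CODONS = {"UAA", "UAG", "UGA"}
_SINGLE_CODON = {"AUG", "UGG"}  # Met, Trp: no synonymous choice


def cai(cds_seq: str, weight_table: dict) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness
    weights over the CDS, excluding stop codons and the single-codon amino
    acids Met and Trp.  ``weight_table`` maps codons to w in (0, 1]."""
    s = _rna(cds_seq)
    if len(s) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    weights = {_rna(k): float(v) for k, v in weight_table.items()}
    logs = []
    codons = [s[i:i + 3] for i in range(0, len(s), 3)]
    for i, codon in enumerate(codons):
        if codon in _STOP_CODONS:
            if i < len(codons) - 1:
                log.warning("internal stop codon %s at codon %d skipped", codon, i + 1)
            continue
        if codon in _SINGLE_CODON:
            continue
        w = weights.get(codon)
        if w is None or not 0 < w <= 1:
            raise ValueError(f"missing or invalid weight for codon {codon}")
        logs.append(np.log(w))
    if not logs:
        raise ValueError("no weighted codons in CDS")
    return float(np.exp(np.mean(logs)))


def compare_groups(values_asd, values_control, test: str = "KS_two_sided"):
    """Two-sided KS or Mann-Whitney U comparison between the ASD and
    control feature distributions.  MWU uses exact enumeration when both
    samples have at most 8 values, otherwise the tie-corrected normal
    approximation."""
    a = np.asarray(values_asd, dtype=float)
    c = np.asarray(values_control, dtype=float)
    if a.size < 2 or c.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if test == "KS_two_sided":
        res = sps.ks_2samp(a, c, alternative="two-sided", method="asymp")
        return float(res.statistic), float(res.pvalue)
    if test == "MWU_two_sided":
        method = "exact" if (a.size <= 8 and c.size <= 8) else "asymptotic"
        res = sps.mannwhitneyu(a, c, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def select_matched_controls(control_pool: pd.Series, asd_densities,
                            n_bins: int = 10, seed: int = 0,
                            strict: bool = False) -> list:
    """Control genes matched to the ASD variant-density distribution.

    Bins the ASD densities into ``n_bins`` quantile bins and samples, per
    bin and without replacement, the same number of control genes from
    ``control_pool`` (a Series indexed by gene id).  Under-filled bins
    borrow the nearest pool genes by density (with a warning) unless
    ``strict``, in which case they raise.
    """
    from .simulate import derive_rng

    asd = np.asarray(asd_densities, dtype=float)
    pool = control_pool.astype(float)
    edges = np.quantile(asd, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    # right-closed bins: bin k covers (edges[k], edges[k+1]]
    asd_bin = np.searchsorted(edges[1:-1], asd, side="left")
    pool_bin = pd.Series(np.searchsorted(edges[1:-1], pool.to_numpy(), side="left"),
                         index=pool.index)
    rng = derive_rng(seed, "density_match")
    chosen: list = []
    available = pool.copy()
    for k in range(n_bins):
        need = int((asd_bin == k).sum())
        in_bin = available[pool_bin.reindex(available.index) == k]
        take = min(need, len(in_bin))
        if take:
            picked = rng.choice(in_bin.index, size=take, replace=False)
            chosen.extend(picked)
            available = available.drop(picked)
        short = need - take
        if short:
            if strict:
                raise ValueError(f"density bin {k} under-filled by {short}")
            log.warning("density bin %d under-filled; borrowing %d nearest genes",
                        k, short)
            centre = 0.5 * (max(edges[k], available.min() if len(available) else 0)
                            + min(edges[k + 1], available.max() if len(available) else 0))
            nearest = (available - centre).abs().nsmallest(short).index
            chosen.extend(nearest)
            available = available.drop(nearest)
    return sorted(chosen)
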