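"""Synthetic allelic decay data with full ground truth.

The generator draws from exactly the probability model the inference
assumes: per-allele transcript pools decay exponentially from N_i(0) at
rates lambda_i, and the allele-assignable read count at SNP locus s,
replicate r, timepoint t is

    count_i ~ Poisson( w_s * f(t) * N_i(0) * exp(-lambda_i * t) )

with per-SNP weights w_s emulating uneven SNP coverage and a capture
fraction f(t) shared by both alleles (f cancels in the conditional
binomial, so it defaults to 1).  Replicates are independent re-draws from
the same truth.

Counts are realised as a Poisson total split binomially between the
alleles, with the binomial applied to a canonically ordered allele; this
is distributionally identical to two independent Poissons but makes the
generator exactly label-symmetric: swapping the two alleles' parameters in
the truth swaps the count columns bit for bit under the same seed.

Randomness: one global seed; each gene consumes an independent stream
derived by stable hashing of (seed, gene_id), so any subset of genes is
reproducible in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import COUNTS_COLUMNS, GeneTimecourse


def derive_rng(seed: int, *tokens) -> np.random.Generator:
    """Independent generator for (seed, tokens), stable across runs."""
    digest = hashlib.sha256("\x1f".join(str(t) for t in tokens).encode()).digest()
    sub = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**63, sub]))


@dataclass
class SimTruth:
    """Planted parameters for one gene (the recovery-test oracle)."""

    gene_id: str
    N1_0: float
    N2_0: float
    lambda1: float
    lambda2: float
    capture_fractions: dict | None = None  # timepoint -> f(t); None = 1 everywhere
    snp_weights: np.ndarray = field(default_factory=lambda: np.ones(5))
    seed: int = 0

    def __post_init__(self):
        self.snp_weights = np.asarray(self.snp_weights, dtype=float)
        if self.N1_0 <= 0 or self.N2_0 <= 0:
            raise ValueError("initial copy numbers must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("decay rates must be non-negative")
        if (self.snp_weights <= 0).any():
            raise ValueError("SNP weights must be positive")
        if self.capture_fractions is not None:
            f = np.array(list(self.capture_fractions.values()), dtype=float)
            if ((f <= 0) | (f > 1)).any():
                raise ValueError("capture fractions must lie in (0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.snp_weights)

    @property
    def delta_lambda_true(self) -> float:
        return self.lambda1 - self.lambda2

    def capture(self, t: float) -> float:
        if self.capture_fractions is None:
            return 1.0
        return float(self.capture_fractions[t])


def simulate_gene_counts(truth: SimTruth, timepoints=(0.0, 0.5, 1.5),
                         n_replicates: int = 2) -> GeneTimecourse:
    """Draw one gene's allelic count grid from its planted truth."""
    tps = np.asarray(timepoints, dtype=float)
    if tps.size == 0 or not np.all(np.diff(tps) > 0):
        raise ValueError("timepoints must be strictly increasing")
    f = np.array([truth.capture(t) for t in tps])
    w = truth.snp_weights
    # mean[s, t, allele]
    mean1 = w[:, None] * f[None, :] * truth.N1_0 * np.exp(-truth.lambda1 * tps)[None, :]
    mean2 = w[:, None] * f[None, :] * truth.N2_0 * np.exp(-truth.lambda2 * tps)[None, :]
    mtot = mean1 + mean2
    if mtot.sum() <= 0:
        raise ValueError("zero total expected reads")

    # canonical allele ordering makes label swap exact (see module docstring)
    canon_first = (truth.lambda1, truth.N1_0) <= (truth.lambda2, truth.N2_0)
    p_canon = (mean1 if canon_first else mean2) / mtot

    rng = derive_rng(truth.seed, truth.gene_id, "counts")
    shape = (truth.n_snps, n_replicates, tps.size)
    tot = rng.poisson(np.broadcast_to(mtot[:, None, :], shape))
    n_canon = rng.binomial(tot, np.broadcast_to(p_canon[:, None, :], shape))
    counts = np.empty(shape + (2,), dtype=np.int64)
    counts[..., 0 if canon_first else 1] = n_canon
    counts[..., 1 if canon_first else 0] = tot - n_canon

    snp_ids = [f"{truth.gene_id}_s{i+1}" for i in range(truth.n_snps)]
    return GeneTimecourse(gene_id=truth.gene_id, timepoints=tps,
                          replicates=list(range(1, n_replicates + 1)),
                          snp_ids=snp_ids, counts=counts, truth=truth)


@dataclass
class SimCohortConfig:
    """Study design of a simulated cohort.

    Defaults mirror the inference's assumed design: timepoints 0/0.5/1.5 h
    after transcriptional arrest, two replicates, eight SNP loci per gene
    and ~200 expected allele-assignable reads per SNP at t=0.  Planted
    effect genes are chosen deterministically by count (first floor(f*n)
    ids after a seeded shuffle), so the cohort composition is exact.
    """

    n_genes: int = 100
    fraction_asd: float = 0.0
    delta_lambda_values: tuple = (0.3, -0.3)
    fraction_asa: float = 0.0
    asa_log2fc_values: tuple = (2.0, -2.0)
    depth_per_snp: float = 200.0
    timepoints: tuple = (0.0, 0.5, 1.5)
    n_replicates: int = 2
    snps_per_gene: int | tuple = 8
    base_decay_rate: float = 0.5
    snp_weight_sigma: float = 0.5
    capture_fractions: dict | None = None
    transcript_length: int = 2000
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_asd", "fraction_asa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fraction_asd + self.fraction_asa > 1.0 + 1e-12:
            raise ValueError("fraction_asd + fraction_asa must not exceed 1")
        tps = np.asarray(self.timepoints, dtype=float)
        if tps[0] != 0.0 or not np.all(np.diff(tps) > 0):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.depth_per_snp <= 0:
            raise ValueError("depth_per_snp must be positive")
        if self.fraction_asd > 0 and len(self.delta_lambda_values) == 0:
            raise ValueError("fraction_asd > 0 requires delta_lambda_values")
        if min(self.base_decay_rate - max(map(abs, self.delta_lambda_values or (0,))) / 2, 0) < 0:
            raise ValueError("base_decay_rate too small for delta_lambda_values")


def _region_of(pos: int, length: int) -> str:
    utr5_end = max(1, int(round(length * 0.1)))
    cds_end = max(utr5_end + 1, int(round(length * 0.75)))
    if pos <= utr5_end:
        return "UTR5"
    if pos <= cds_end:
        return "CDS"
    return "UTR3"


def simulate_cohort(config: SimCohortConfig):
    """Generate a cohort; returns (counts table, list of SimTruth).

    ASD genes carry a decay-rate difference with equal initial abundance
    (the compensatory configuration: steady state hides the divergence);
    ASA genes carry a log2 initial-abundance offset with equal decay.
    """
    n = config.n_genes
    width = max(4, len(str(n)))
    ids = [f"g{str(i + 1).zfill(width)}" for i in range(n)]
    shuffled = list(derive_rng(config.seed, "plant").permutation(ids))
    n_asd = int(np.floor(config.fraction_asd * n))
    n_asa = int(np.floor(config.fraction_asa * n))
    asd_ids = set(shuffled[:n_asd])
    asa_ids = set(shuffled[n_asd:n_asd + n_asa])

    truths, frames = [], []
    f0 = 1.0 if config.capture_fractions is None else config.capture_fractions[config.timepoints[0]]
    for gene_id in ids:
        rng = derive_rng(config.seed, gene_id, "params")
        delta = rng.choice(config.delta_lambda_values) if gene_id in asd_ids else 0.0
        offset = rng.choice(config.asa_log2fc_values) if gene_id in asa_ids else 0.0
        lam1 = config.base_decay_rate + delta / 2.0
        lam2 = config.base_decay_rate - delta / 2.0
        ratio = 2.0 ** offset
        n_total0 = config.depth_per_snp / f0
        N1_0 = n_total0 * ratio / (1.0 + ratio)
        N2_0 = n_total0 / (1.0 + ratio)
        if isinstance(config.snps_per_gene, tuple):
            lo, hi = config.snps_per_gene
            n_snps = int(rng.integers(lo, hi + 1))
        else:
            n_snps = int(config.snps_per_gene)
        weights = rng.lognormal(0.0, config.snp_weight_sigma, size=n_snps)
        weights /= weights.mean()
        truth = SimTruth(gene_id=gene_id, N1_0=N1_0, N2_0=N2_0,
                         lambda1=lam1, lambda2=lam2,
                         capture_fractions=config.capture_fractions,
                         snp_weights=weights, seed=config.seed)
        gene = simulate_gene_counts(truth, config.timepoints, config.n_replicates)
        pos = np.sort(rng.choice(np.arange(1, config.transcript_length + 1),
                                 size=n_snps, replace=False))
        gene.pos = pos
        gene.region = np.array([_region_of(int(p), config.transcript_length) for p in pos])
        truths.append(truth)
        frames.append(gene.to_frame())
    table = pd.concat(frames, ignore_index=True)[COUNTS_COLUMNS]
    return table, truths


def simulate_mock_hybrid(n_loci: int, biased_fraction: float, depth: float,
                         seed: int = 0, shift: float = 0.2,
                         base_proportion: float = 0.5):
    """Mock-F1 dataset for the mapping-bias filter, with truth flags.

    Unbiased loci draw parental and mock-allelic counts from the same
    binomial proportion; biased loci draw the mock-allelic counts from a
    proportion shifted by ``shift``.  Returns (parental table, mock table,
    flags) where flags marks the planted biased loci.
    """
    if not 0.0 <= biased_fraction <= 1.0:
        raise ValueError("biased_fraction must lie in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = derive_rng(seed, "mock_hybrid")
    ids = [f"snp{str(i + 1).zfill(len(str(n_loci)))}" for i in range(n_loci)]
    order = rng.permutation(n_loci)
    biased = np.zeros(n_loci, dtype=bool)
    biased[order[:int(np.floor(biased_fraction * n_loci))]] = True

    p = np.full(n_loci, base_proportion)
    p_mock = np.clip(np.where(biased, p + shift, p), 0.0, 1.0)
    tot_par = rng.poisson(depth, size=n_loci)
    a = rng.binomial(tot_par, p)
    tot_mock = rng.poisson(depth, size=n_loci)
    c = rng.binomial(tot_mock, p_mock)
    parental = pd.DataFrame({"snp_id": ids, "n_strain1": a, "n_strain2": tot_par - a})
    mock = pd.DataFrame({"snp_id": ids, "n_allele1": c, "n_allele2": tot_mock - c})
    flags = pd.Series(biased, index=pd.Index(ids, name="snp_id"), name="biased")
    return parental, mock, flags


def bias_records(parental: pd.DataFrame, mock: pd.DataFrame,
                 ctx: str = "parental_mock") -> pd.DataFrame:
    """Assemble the bias-filter record table (snp_id, ctx, a, b, c, d)."""
    m = parental.merge(mock, on="snp_id")
    return pd.DataFrame({
        "snp_id": m["snp_id"], "ctx": ctx,
        "a": m.iloc[:, 1], "b": m.iloc[:, 2],
        "c": m.iloc[:, 3], "d": m.iloc[:, 4],
    })


_BASES = np.array(list("ACGT"))


def simulate_allele_sequences(length: int, snp_positions, seed: int = 0,
                              region_map: dict | None = None,
                              gene_id: str = "gene"):
    """Paired allele sequences differing only at the given 1-based positions.

    Returns (AlleleSequencePair, variants frame, regions frame); the
    regions frame is in BED convention (0-based half-open).
    """
    from .features import AlleleSequencePair

    positions = [int(p) for p in snp_positions]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate SNP positions")
    if any(p < 1 or p > length for p in positions):
        raise ValueError("SNP positions must lie within [1, length]")
    rng = derive_rng(seed, gene_id, "sequence")
    seq1 = rng.choice(_BASES, size=length)
    seq2 = seq1.copy()
    refs, alts = [], []
    for p in sorted(positions):
        ref = seq1[p - 1]
        alt = rng.choice([b for b in _BASES if b != ref])
        seq2[p - 1] = alt
        refs.append(ref)
        alts.append(alt)
    if region_map is None:
        utr5_end = max(1, int(round(length * 0.1)))
        cds_len = 3 * ((max(utr5_end + 3, int(round(length * 0.75))) - utr5_end) // 3)
        region_map = {"UTR5": (1, utr5_end),
                      "CDS": (utr5_end + 1, utr5_end + cds_len),
                      "UTR3": (utr5_end + cds_len + 1, length)}
    pair = AlleleSequencePair(gene_id=gene_id, seq_allele1="".join(seq1),
                              seq_allele2="".join(seq2),
                              variant_positions=sorted(positions),
                              regions=region_map)
    variants = pd.DataFrame({"chrom": gene_id, "pos": sorted(positions),
                             "ref": refs, "alt": alts})
    regions = pd.DataFrame(
        [(gene_id, lo - 1, hi, name) for name, (lo, hi) in region_map.items()],
        columns=["chrom", "start", "end", "name"])
    return pair, variants, regions
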