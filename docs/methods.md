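# Methods

## The model

`asdecay` estimates allele-specific differences in mRNA decay (ASD) from an
F1-hybrid time course following transcriptional arrest. Each allele's
transcript pool is assumed to decay exponentially,

    N_i(t) = N_i(0) · exp(−λ_i t),      i = 1, 2,

and the allele-assignable read count at a SNP locus is Poisson with mean
proportional to the pool, `n_i(t) ~ Poisson(w_s · f(t) · N_i(t))`, where
`f(t)` is a capture fraction shared by both alleles (library size,
efficiency) and `w_s` a locus-specific coverage weight. Conditioning on the
locus total makes the allele-1 count binomial with

    logit p(t) = log(N1(0)/N2(0)) − (λ1 − λ2)·t = α + β·t,

so `f(t)` and `w_s` cancel and the slope of a two-parameter logistic
regression on time identifies Δλ = λ1 − λ2 = −β. Only the *difference* of
decay rates is identified; absolute half-lives are not. We report Δλ with
the convention that Δλ > 0 means allele 1 (the reference/maternal strain)
decays faster, and expose the raw β alongside. `exp(β)` is the hourly
fold-change in the odds of sampling an allele-1 read.

### Fitting

All (SNP, timepoint) cells of one replicate are pooled as independent
binomial observations. Because every cell shares one of a handful of
timepoints, the likelihood depends on the data only through per-timepoint
sums of allele-1 counts and totals; the solver aggregates first and then
runs a damped Newton/IRLS iteration (max 50 steps, absolute log-likelihood
tolerance 1e-10, step halving). The iteration is vectorised across many
independent fits, which is what makes bootstrap resampling affordable.
Separation is handled by clipping coefficients at |50| and flagging the fit
non-converged rather than raising. No overdispersion correction is applied
at the cell level: between-locus variance is absorbed by the bootstrap
layer.

### Uncertainty: bootstrap over SNP loci

For a gene with n loci, `n_boot` (default 5,000; the bundled studies use
1,000) resampled lists of n loci are drawn with replacement and the GLM is
re-fit on each. The bootstrap mean and SD give `z = mean/sd` and a normal
two-sided p-value, BH-adjusted across genes within each replicate
(replicates are processed independently throughout). A degenerate
`sd = 0` (all loci identical) maps to p = 0 for a nonzero mean and p = 1
otherwise. Resamples whose fit does not converge are dropped and counted;
more than 1% dropped triggers a warning.

A gene is called ASD when every replicate has adjusted p < 0.05 and
|Δλ| > 0.06/h with a concordant sign (thresholds configurable). The
steady-state abundance call (ASA) mirrors this with the log2 allelic fold
change of summed t = 0 counts (resampled loci are summed *before* forming
the ratio, which keeps low-count loci from dominating), with a twofold
magnitude threshold. Thresholds are applied to the bootstrap mean — the
quantity the scatter diagnostics plot — with the plain point estimate
carried alongside; the combined per-gene Δλ is the unweighted mean of
replicate point estimates.

### Permutation FDR

The empirical FDR of the dual-threshold rule is estimated by shuffling the
gene labels of every replicate after the first (100 permutations by
default). This preserves each replicate's marginal (p_adj, Δλ)
distribution while breaking cross-replicate concordance, which is the
thing the dual-replicate rule exploits. FDR(x) = mean permuted pass count
/ real pass count, reported as NA when no real gene passes x.

A caveat worth knowing: when true effects are strong and not rare, most
permuted "false positives" are cross-pairings of two *true* effects with
coincident sign, so the estimator is an upper bound on the realized FDR —
in planted simulations where the realized false-call fraction is ~0 the
permutation estimate still sits near `fraction_true² / fraction_called / 2`.
The calibration acceptance test records this gap rather than hiding it.

### Control genes and density matching

Genes with no evidence of ASD (raw bootstrap p > 0.05, |Δλ| < 0.03 and
bootstrap SD < min(0.1, the empirical 95% quantile) in every replicate)
form the control pool for sequence-feature comparisons. Because ASD genes
are variant-rich by construction of the assay, feature comparisons use a
control subset matched to the ASD variant-density distribution by
quantile-bin sampling (10 bins, seeded, without replacement; under-filled
bins borrow nearest-density genes with a warning, or raise in strict
mode).

## SNP filtering

Two Fisher-exact screens remove loci with allelic mapping/assignment bias:
parental-strain reads versus mock-F1 allelic reads, and allelic ratios
with versus without multi-mapped reads. The two screens are separate
hypothesis families (BH-adjusted independently, union removal). The
two-sided Fisher p-value is computed by exact integer enumeration of the
hypergeometric distribution (probabilities compared on their integer
numerators over the common denominator), so tie handling involves no
floating-point tolerance.

The sufficiency filter retains genes with ≥ 5 SNP loci that, in *every*
replicate, have a two-allele total ≥ 10 at each timepoint and per-allele
sums ≥ 15 across timepoints. Applying the per-allele threshold per
replicate (rather than pooled) is the stricter of the two readings and the
one implemented.

## Sequence features

* **SNP density**: 1000 × count/span, per transcript or per annotated
  region (5′UTR/CDS/3′UTR, longest isoform).
* **miRNA seed sites**: canonical site types against a supplied
  expression-ranked miRNA list (default top 50). Each occurrence of the
  6mer core (reverse complement of miRNA positions 2–7) is classified once
  by its best supported type — 8mer (m8 match + downstream A) >
  7mer-m8 > 7mer-1A — and bare 6mers are not counted. The
  stable-vs-unstable comparison keeps genes with ≥ 10 sites over both
  alleles and ≥ 1 allelic difference, labels the slower-decaying allele
  "stable" from the sign of the combined Δλ (ties excluded; controls get a
  seeded random label), and tests ASD against control differences with a
  two-sided Mann–Whitney U plus per-group sign diagnostics.
* **Local structure**: for each variant, a w-nt window (w ∈ {21, 41, 61,
  81, 101}) centred on the variant — shifted to abut the transcript end
  when the variant is closer than (w−1)/2 to an end, whole transcript used
  and flagged when shorter than w — is folded for both alleles; ΔMFE =
  MFE₁ − MFE₂, summarised per gene/region as max |ΔMFE|. The folding
  engine is a pluggable callable. The bundled `nussinov_fold` is a
  deterministic base-pair-maximisation dynamic programme (AU/GC/GU pairs,
  hairpin loops ≥ 3 nt, proxy MFE = −max pairs); `rnafold_engine()`
  adapts an external thermodynamic folder when one is configured. Signed
  ΔMFE is available but only |ΔMFE| feeds the headline comparison.
* **CAI**: geometric mean of relative-adaptiveness weights over the CDS,
  excluding stop codons and the single-codon amino acids Met/Trp; internal
  stops are skipped with a warning.
* **Group tests**: two-sided KS (asymptotic p) for density-style features;
  Mann–Whitney U (exact when both n ≤ 8, tie-corrected normal otherwise).

## Synthetic data

The generator draws from exactly the model above, with full ground truth
returned for recovery testing. Defaults encode the assumed study design:
timepoints {0, 0.5, 1.5} h, two replicates (independent re-draws, no batch
effects), 8 SNP loci per gene, ~200 expected allele-assignable reads per
locus at t = 0, base decay rate 0.5/h (half-life ≈ 1.4 h, a typical
fibroblast mRNA scale). Locus weights are i.i.d. LogNormal(0, 0.5²)
normalised to mean 1, mimicking uneven SNP coverage and deliberately
stressing the bootstrap; the per-locus depth distribution of real data is
not claimed, only its unevenness. `f(t)` defaults to 1 (it cancels in the
conditional model) and is configurable for robustness checks. Planted-gene
selection is deterministic by count (first ⌊fraction·n⌋ ids after a seeded
shuffle) so cohort composition is exact. ASD genes are planted with equal
initial abundance (λ split symmetrically around the base rate), i.e. in
the compensatory configuration; ASA genes with a log2 offset in N_i(0) and
equal decay. Counts are realised as a Poisson total split binomially on a
canonically ordered allele, which is distributionally identical to two
independent Poissons but makes allele-label swaps in the truth swap count
columns bit-exactly under the same seed. One global seed; per-gene streams
are derived by stable hashing of (seed, gene_id), so any subset is
reproducible. What the generator does *not* emulate: read-level artifacts
(mapping bias beyond the mock-hybrid module, GC/length effects), replicate
batch effects, overdispersion beyond Poisson, or indels — so passing
recovery tests demonstrates correctness of the inference under its own
assumptions, not robustness to misspecified noise.

The mock-hybrid generator draws parental and mock-allelic counts from the
same binomial proportion at unbiased loci and shifts the mock proportion
(default +0.2) at planted biased loci, giving truth flags for filter
power/specificity studies.

## Problem sizes and numerical choices

The bundled studies run at desk scale by design: recovery uses 200 genes
per planted Δλ ∈ {0, ±0.1, ±0.3}/h with 1,000 bootstrap lists (scaled
from the 5,000 default — the bootstrap SD estimate is stable well below
that); calibration uses 500-gene cohorts and 100 permutations; the
structure-engine equivalence check enumerates all RNA strings to length 7
exhaustively plus a seeded 5,000-string sample of lengths 8–10. Fisher
enumeration is exact-integer; BH is delegated to statsmodels and
cross-checked against the direct step-up formula; KS/MWU/Pearson come from
scipy. Tie-breaks and degenerate cases (zero totals, separation, sd = 0,
empty bins) follow the conventions stated above, each of which is
unit-tested.

## Known limitations

* Interval coverage of the bootstrap-z 95% interval is ≈ 90% rather than
  95% at 8 loci per gene: with few resampling units the bootstrap SD
  underestimates the sampling SD (≈ √((n−1)/n), further reduced by weight
  heterogeneity), and the normal quantile ignores the SD's own noise. This
  is a property of the published two-layer design, visible in the
  acceptance measurements, not corrected for.
* The permutation FDR is an upper bound when effects are common and strong
  (see above).
* Only substitution variants are supported in the sequence layer;
  coordinate harmonisation of indels is upstream of this package.
* The Nussinov engine is a structural proxy, not a thermodynamic energy
  model; conclusions about ΔMFE magnitudes require an external folder.
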