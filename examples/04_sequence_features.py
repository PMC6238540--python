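"""Allele-level sequence features around transcript variants.

Builds a pair of allele sequences differing at three positions, then
computes SNP density, canonical miRNA seed sites (8mer / 7mer-m8 /
7mer-1A) per allele, and the windowed secondary-structure difference
(max |delta MFE| over 41-nt windows centred on each variant, folded with
the bundled base-pair-maximisation engine).
"""

from asdecay import (MirnaSeed, count_mirna_sites, mfe_windows,
                     simulate_allele_sequences, snp_density)
from asdecay.features import max_abs_delta_mfe

pair, variants, regions = simulate_allele_sequences(
    length=900, snp_positions=[40, 450, 700], seed=5, gene_id="demo")

print(f"transcript length: {len(pair.seq_allele1)} nt, "
      f"variants at {pair.variant_positions}")
print(f"SNP density: {snp_density(pair.variant_positions, 900):.2f} per kb")

mir = MirnaSeed("mir-demo", "UGGAAUGUAAAGAAGUAUGUAU")
utr3 = pair.regions["UTR3"]
t1 = pair.seq_allele1[utr3[0] - 1:utr3[1]]
t2 = pair.seq_allele2[utr3[0] - 1:utr3[1]]
# plant an 8mer site (perfect match to seed positions 2-8 plus an A) in
# allele 2's 3'UTR, as a variant creating a target site would
t2 = t2[:30] + "ACAUUCCA" + t2[38:]
print(f"3'UTR seed sites for {mir.mirna_id}: "
      f"allele1={count_mirna_sites(t1, [mir])}, "
      f"allele2={count_mirna_sites(t2, [mir])} "
      "(extra site on allele 2 would mark it for faster decay)")

per_variant = mfe_windows(pair, window=41)
print(per_variant[["pos", "region", "start", "end", "delta_mfe"]].to_string(
    index=False))
print(f"max |delta MFE|: {max_abs_delta_mfe(per_variant):.1f} "
      "(pair-count units; a nonzero value means the variant changes how "
      "stably the surrounding window can fold)")
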