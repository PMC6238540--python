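"""Tables and file formats used across the pipeline.

The central exchange format is the allelic counts table (TSV): one row per
(gene, SNP, replicate, timepoint) with read counts for the two alleles.
Allele 1 is the reference/maternal strain by convention.  Sequence-side
inputs are plain FASTA (paired allele records), VCF v4.2 (variants in
transcript coordinates, CHROM = gene id) and BED (0-based half-open region
spans for 5'UTR/CDS/3'UTR).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COUNTS_COLUMNS = [
    "gene_id", "snp_id", "chrom", "pos", "region",
    "replicate", "time_h", "n_allele1", "n_allele2",
]
REGIONS = ("UTR5", "CDS", "UTR3", "NA")


class SchemaError(ValueError):
    """A table does not conform to the documented column schema."""


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"counts table missing column(s): {', '.join(missing)}")
    for col in ("n_allele1", "n_allele2"):
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise SchemaError(f"{col} must be integer counts")
            df[col] = np.round(vals).astype(np.int64)
        if (df[col] < 0).any():
            raise SchemaError(f"{col} contains negative counts")
    bad = set(df["region"].astype(str)) - set(REGIONS)
    if bad:
        raise SchemaError(f"unknown region label(s): {sorted(bad)}")
    return df


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "snp_id": str, "chrom": str})
    return validate_counts(df)


def write_counts(df: pd.DataFrame, path) -> None:
    validate_counts(df.copy())
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclasses.dataclass
class GeneTimecourse:
    """One gene's allelic counts on the (SNP, replicate, timepoint) grid.

    ``counts`` has shape (n_snps, n_replicates, n_timepoints, 2); the last
    axis is (allele1, allele2).  This is the unit of model fitting and of
    the SNP-level bootstrap.
    """

    gene_id: str
    timepoints: np.ndarray
    replicates: list
    snp_ids: list
    counts: np.ndarray
    pos: np.ndarray | None = None
    region: np.ndarray | None = None
    truth: object = None  # SimTruth when simulated

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.snp_ids), len(self.replicates),
                                 len(self.timepoints), 2):
            raise ValueError("counts shape inconsistent with grid")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not np.all(np.diff(self.timepoints) > 0):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def cells(self, replicate) -> tuple[np.ndarray, np.ndarray]:
        """(n1, ntot) arrays of shape (n_snps, n_timepoints) for one replicate."""
        r = self.replicates.index(replicate)
        n1 = self.counts[:, r, :, 0].astype(float)
        ntot = self.counts[:, r, :, :].sum(axis=2).astype(float)
        return n1, ntot

    def swap_alleles(self) -> "GeneTimecourse":
        return dataclasses.replace(self, counts=self.counts[..., ::-1].copy())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, snp in enumerate(self.snp_ids):
            pos = int(self.pos[s]) if self.pos is not None else s + 1
            region = str(self.region[s]) if self.region is not None else "NA"
            for r, rep in enumerate(self.replicates):
                for k, t in enumerate(self.timepoints):
                    rows.append((self.gene_id, snp, self.gene_id, pos, region,
                                 rep, t, int(self.counts[s, r, k, 0]),
                                 int(self.counts[s, r, k, 1])))
        return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def iter_genes(df: pd.DataFrame) -> Iterator[GeneTimecourse]:
    """Yield one :class:`GeneTimecourse` per gene from a validated counts table.

    Raises :class:`SchemaError` when a gene's (SNP, replicate, timepoint)
    grid is incomplete.
    """
    validate_counts(df)
    for gene_id, g in df.groupby("gene_id", sort=True):
        snps = sorted(g["snp_id"].unique())
        reps = sorted(g["replicate"].unique())
        tps = np.array(sorted(g["time_h"].unique()))
        idx = {(row.snp_id, row.replicate, row.time_h): (row.n_allele1, row.n_allele2)
               for row in g.itertuples()}
        counts = np.zeros((len(snps), len(reps), len(tps), 2), dtype=np.int64)
        for s, snp in enumerate(snps):
            for r, rep in enumerate(reps):
                for k, t in enumerate(tps):
                    key = (snp, rep, t)
                    if key not in idx:
                        raise SchemaError(
                            f"gene {gene_id}: missing counts for SNP {snp}, "
                            f"replicate {rep}, time {t} h")
                    counts[s, r, k] = idx[key]
        meta = g.drop_duplicates("snp_id").set_index("snp_id")
        pos = np.array([meta.loc[s, "pos"] for s in snps])
        region = np.array([str(meta.loc[s, "region"]) for s in snps])
        yield GeneTimecourse(gene_id=str(gene_id), timepoints=tps, replicates=reps,
                             snp_ids=snps, counts=counts, pos=pos, region=region)


# ---------------------------------------------------------------------------
# sequence-side formats

def write_allele_fasta(pairs, path) -> None:
    """Write paired allele sequences; record ids '<gene>|allele1' / '|allele2'."""
    records = []
    for p in pairs:
        records.append(SeqRecord(Seq(p.seq_allele1), id=f"{p.gene_id}|allele1", description=""))
        records.append(SeqRecord(Seq(p.seq_allele2), id=f"{p.gene_id}|allele2", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_allele_fasta(path) -> dict:
    """Return {gene_id: (seq_allele1, seq_allele2)}."""
    seqs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, allele = rec.id.partition("|")
        seqs.setdefault(gene, {})[allele] = str(rec.seq)
    out = {}
    for gene, d in seqs.items():
        if set(d) != {"allele1", "allele2"}:
            raise SchemaError(f"gene {gene}: expected records '|allele1' and '|allele2'")
        out[gene] = (d["allele1"], d["allele2"])
    return out


def write_vcf(variants: pd.DataFrame, path, contig_lengths: dict | None = None) -> None:
    """Write variants (columns chrom, pos, ref, alt; pos 1-based) as VCF v4.2."""
    lines = ["##fileformat=VCFv4.2", "##source=asdecay"]
    for chrom in variants["chrom"].unique():
        length = (contig_lengths or {}).get(chrom)
        if length:
            lines.append(f"##contig=<ID={chrom},length={length}>")
        else:
            lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for row in variants.itertuples():
        lines.append(f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into a (chrom, pos, ref, alt) frame via cyvcf2."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0] if v.ALT else "."))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def write_bed(regions: pd.DataFrame, path) -> None:
    """Write region spans (chrom, start, end, name; 0-based half-open) as BED."""
    regions.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "name"])


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"],
                     dtype={0: str, 3: str})
    return df
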