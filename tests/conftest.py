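import numpy as np
import pytest

from asdecay.io import GeneTimecourse


def make_exact_gene(delta_lambda=0.3, log_ratio=0.0, totals=1_000_000,
                    timepoints=(0.0, 0.5, 1.5), n_snps=5, n_replicates=2,
                    gene_id="gene_exact"):
    """Gene whose counts sit exactly on the binomial decay model.

    p(t) = R e^(-delta*t) / (R e^(-delta*t) + 1) with R = exp(log_ratio);
    counts are the expected values rounded to integers at large totals, so
    fitted (alpha, beta) recover (log_ratio, -delta) to rounding error.
    """
    tps = np.asarray(timepoints, dtype=float)
    p = np.exp(log_ratio - delta_lambda * tps)
    p = p / (p + 1.0)
    counts = np.zeros((n_snps, n_replicates, tps.size, 2), dtype=np.int64)
    counts[..., 0] = np.round(totals * p)
    counts[..., 1] = totals - counts[..., 0]
    return GeneTimecourse(gene_id=gene_id, timepoints=tps,
                          replicates=list(range(1, n_replicates + 1)),
                          snp_ids=[f"s{i}" for i in range(n_snps)],
                          counts=counts)


@pytest.fixture
def exact_gene():
    return make_exact_gene()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
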