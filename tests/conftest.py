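import numpy as np
import pandas as pd
import pytest

from methyldmr.io import (FeatureSet, Gene, GenomicInterval,
                          MethylomeSample, TransposableElement)


def make_sample(rows, genotype="wild-type", replicate="R1", genome=None):
    """Build a MethylomeSample from (chrom, pos, strand, m, u, context)
    tuples; trinucleotides filled with a context-consistent default."""
    tri = {"CG": "CGA", "CHG": "CAG", "CHH": "CTT"}
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count_meth",
                                     "count_unmeth", "context"])
    df["trinucleotide"] = df["context"].map(tri)
    return MethylomeSample(genotype=genotype, replicate=replicate,
                           sites=df, genome=genome or {})


def random_sample(rng, n=200, chrom_len=10_000, genotype="wild-type",
                  replicate="R1", level=0.3, coverage=20):
    """Random sorted sample with unique (pos, strand) sites."""
    slots = np.sort(rng.choice(2 * chrom_len, size=n, replace=False))
    pos = slots // 2 + 1
    strand = np.where(slots % 2 == 0, "+", "-")
    context = rng.choice(["CG", "CHG", "CHH"], size=n)
    cov = rng.poisson(coverage, size=n)
    meth = rng.binomial(cov, level)
    rows = list(zip(["chr1"] * n, pos.tolist(), strand.tolist(),
                    meth.tolist(), (cov - meth).tolist(), context.tolist()))
    return make_sample(rows, genotype, replicate,
                       genome={"chr1": chrom_len})


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_features():
    """Two genes and three TEs on a 20 kb chromosome."""
    genes = [
        Gene("At1g00010", GenomicInterval("chr1", 1000, 3000, "+"), "+"),
        Gene("At1g00020", GenomicInterval("chr1", 8000, 10000, "-"), "-"),
    ]
    tes = [
        TransposableElement("AT1TE00010", "GYPSYF1", "LTR/Gypsy",
                            GenomicInterval("chr1", 4000, 4600, "+")),
        TransposableElement("AT1TE00020", "GYPSYF1", "LTR/Gypsy",
                            GenomicInterval("chr1", 12000, 15500, "-")),
        TransposableElement("AT1TE00030", "MUDRF1", "DNA/MuDR",
                            GenomicInterval("chr1", 16000, 16500, "+")),
    ]
    return FeatureSet(genes=genes, tes=tes, genome={"chr1": 20_000})
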