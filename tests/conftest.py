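import numpy as np
import pandas as pd
import pytest

from confeti import ExpressionMatrix, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_expression(values: np.ndarray, chrom=None, start=None, prefix="gene") -> ExpressionMatrix:
    n, g = values.shape
    genes = [f"{prefix}{i}" for i in range(g)]
    ann = pd.DataFrame(
        {
            "chromosome": chrom if chrom is not None else ["chr1"] * g,
            "start": start if start is not None else np.arange(1, g + 1) * 1000,
        },
        index=genes,
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=[f"s{i}" for i in range(n)], columns=genes),
        gene_annotation=ann,
    )


def make_genotypes(values: np.ndarray, chrom=None, pos=None, ploidy=2) -> GenotypeMatrix:
    n, s = values.shape
    snps = [f"snp{i}" for i in range(s)]
    ann = pd.DataFrame(
        {
            "chromosome": chrom if chrom is not None else ["chr1"] * s,
            "position": pos if pos is not None else np.arange(1, s + 1) * 1000,
        },
        index=snps,
    )
    return GenotypeMatrix(
        values=pd.DataFrame(
            values.astype(float), index=[f"s{i}" for i in range(n)], columns=snps
        ),
        snp_annotation=ann,
        ploidy=ploidy,
    )
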