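import numpy as np
import pandas as pd
import pytest

from admetagrs.geno_io import GenotypeMatrix, SummaryStats


def make_geno(dosages, snps=None, chrom=None, pos=None, a1=None, a2=None, sample_cols=None):
    """Build a GenotypeMatrix from a raw dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "snp": snps if snps is not None else [f"rs{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else 1000 * (np.arange(m) + 1),
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
        }
    )
    samples = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)], "sex": 1})
    if sample_cols:
        for k, v in sample_cols.items():
            samples[k] = v
    return GenotypeMatrix(dosages, variants, samples)


def make_sumstats(beta, p, snps=None, chrom=None, pos=None, a1=None, a2=None, eaf=None, trait="AD"):
    beta = np.asarray(beta, dtype=float)
    m = beta.size
    tbl = pd.DataFrame(
        {
            "SNP": snps if snps is not None else [f"rs{j}" for j in range(m)],
            "CHR": chrom if chrom is not None else np.ones(m, dtype=int),
            "BP": pos if pos is not None else 1000 * (np.arange(m) + 1),
            "A1": a1 if a1 is not None else ["A"] * m,
            "A2": a2 if a2 is not None else ["G"] * m,
            "BETA": beta,
            "SE": np.full(m, 0.1),
            "P": np.asarray(p, dtype=float),
        }
    )
    if eaf is not None:
        tbl["EAF"] = np.asarray(eaf, dtype=float)
    return SummaryStats(tbl, trait=trait)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
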