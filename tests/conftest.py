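import numpy as np
import pytest

from omiqtl import (
    CNA,
    METHYLATION,
    MIRNA,
    ExpressionTraits,
    MultiOmicsDataset,
    OmicsBlock,
    zscore_normalize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def standardized_matrix(rng, n, j):
    """Random Gaussian design, columns standardized (population sd)."""
    x = rng.standard_normal((n, j))
    return (x - x.mean(axis=0)) / x.std(axis=0)


@pytest.fixture
def make_design(rng):
    def _make(n=50, j=10, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return standardized_matrix(r, n, j)

    return _make


def tiny_dataset(seed=0, n=80, j_cna=4, j_meth=10, j_mirna=6, traits=None):
    """Hand-built normalized dataset with controllable traits.

    ``traits`` maps gene id -> N-vector; defaults to two noise genes.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n)]

    def block(label, j, prefix):
        raw = rng.standard_normal((n, j))
        b = OmicsBlock(
            type_label=label,
            feature_ids=[f"{prefix}{k}" for k in range(j)],
            sample_ids=samples,
            values=raw,
            normalized=True,  # skip the categorical check for this synthetic CNA
        )
        return zscore_normalize(b)

    blocks = {
        CNA: block(CNA, j_cna, "c"),
        METHYLATION: block(METHYLATION, j_meth, "m"),
        MIRNA: block(MIRNA, j_mirna, "r"),
    }
    if traits is None:
        traits = {
            "gA": rng.standard_normal(n),
            "gB": rng.standard_normal(n),
        }
    expr = ExpressionTraits(
        gene_ids=list(traits),
        sample_ids=samples,
        values=np.vstack([traits[g] for g in traits]),
    )
    return MultiOmicsDataset(blocks=blocks, expression=expr)
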