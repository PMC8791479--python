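import numpy as np
import pytest

from addontag.core import HaplotypePanel, VariantKey


def build_panel(
    mat,
    chrom: str = "1",
    start: int = 1000,
    spacing: int = 100,
    ref: str = "A",
    alt: str = "G",
    sample_prefix: str = "s",
) -> HaplotypePanel:
    """Panel from a literal (n_variants x n_haplotypes) 0/1/-1 matrix."""
    mat = np.asarray(mat, dtype=np.int8)
    n_var, n_hap = mat.shape
    assert n_hap % 2 == 0
    variants = [VariantKey(chrom, start + i * spacing, ref, alt) for i in range(n_var)]
    samples = [f"{sample_prefix}{i}" for i in range(n_hap // 2)]
    return HaplotypePanel(variants, mat, samples)


@pytest.fixture
def panel_factory():
    return build_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
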