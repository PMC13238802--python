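import numpy as np
import pandas as pd
import pytest

from sweepsignal import GenotypeMatrix, HaplotypeMatrix


def make_gm(calls, positions=None, chrom="1", populations=None, phased=False,
            spacing=10_000):
    """GenotypeMatrix from a samples x variants call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = [f"S{i:02d}" for i in range(n)]
    if populations is None:
        populations = {s: "pop1" for s in samples}
    elif isinstance(populations, (list, tuple)):
        populations = dict(zip(samples, populations))
    if positions is None:
        positions = np.arange(1, m + 1) * spacing
    variants = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "id": [f"snp{j}" for j in range(m)], "ref": "A", "alt": "G",
    })
    return GenotypeMatrix(samples, populations, variants, calls, phased=phased)


def make_hm(haps, positions=None, chrom="1", populations=None, spacing=10_000):
    """HaplotypeMatrix from a 2N x variants binary array."""
    haps = np.asarray(haps, dtype=np.uint8)
    n2, m = haps.shape
    assert n2 % 2 == 0
    samples = [f"S{i:02d}" for i in range(n2 // 2)]
    if populations is None:
        populations = {s: "pop1" for s in samples}
    elif isinstance(populations, (list, tuple)):
        populations = dict(zip(samples, populations))
    if positions is None:
        positions = np.arange(1, m + 1) * spacing
    variants = pd.DataFrame({"chrom": chrom,
                             "pos": np.asarray(positions, dtype=np.int64)})
    return HaplotypeMatrix(samples, populations, variants, haps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
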