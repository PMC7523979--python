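import numpy as np
import pandas as pd
import pytest

from lownsel import SimConfig, simulate_genotypes, simulate_phenotypes
from lownsel.genio import GenotypeMatrix


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_snps=120, missing_rate=0.05, seed=42)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    """A 64-line x 120-marker simulated panel with planted loci and truth."""
    return simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def clean_panel():
    """Missing-free panel whose truth NFA is exactly recomputable."""
    cfg = SimConfig(n_snps=150, missing_rate=0.0, seed=7)
    geno, truth = simulate_genotypes(cfg)
    return geno, truth, cfg


@pytest.fixture
def make_geno():
    """Factory for small hand-specified genotype matrices."""

    def _make(calls, chrom=None, pos=None, ref=None, alt=None):
        calls = np.asarray(calls, dtype=np.int8)
        n, m = calls.shape
        chrom = chrom if chrom is not None else ["1"] * m
        pos = pos if pos is not None else list(range(1, m + 1))
        ref = ref if ref is not None else ["A"] * m
        alt = alt if alt is not None else ["G"] * m
        mids = [f"M{j + 1}" for j in range(m)]
        mm = pd.DataFrame(
            {"chrom": [str(c) for c in chrom], "pos": pos, "ref": ref, "alt": alt},
            index=mids,
        )
        return GenotypeMatrix([f"L{i + 1}" for i in range(n)], mids, calls, mm)

    return _make
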