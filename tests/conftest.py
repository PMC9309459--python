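import numpy as np
import pandas as pd
import pytest

from sweepscan.sim import SimParams, simulate_neutral
from sweepscan.variantio import GenotypeMatrix, PopulationMap


@pytest.fixture(scope="session")
def small_sim():
    """Two populations, 1 chromosome, modest drift — shared read-only."""
    params = SimParams(
        n_pops=2, n_per_pop=50, seq_len=1_000_000, snp_density=1e-3,
        drift_var=0.2, seed=11,
    )
    gm, popmap = simulate_neutral(params)
    return params, gm, popmap


@pytest.fixture()
def tiny_gm():
    """Hand-built 4-SNP x 6-sample matrix (two 3-sample populations)."""
    gm = GenotypeMatrix(
        chrom=np.array(["chr1"] * 4, dtype=object),
        pos=np.array([100, 500, 900, 1500]),
        ref=np.array(["A", "C", "G", "T"], dtype=object),
        alt=np.array(["G", "T", "A", "C"], dtype=object),
        geno=np.array(
            [
                [0, 1, 2, 0, 1, 2],
                [2, 2, 2, 0, 0, 0],
                [0, 0, -1, 1, 1, 1],
                [1, 1, 1, 1, 1, 1],
            ],
            dtype=np.int8,
        ),
        samples=["a1", "a2", "a3", "b1", "b2", "b3"],
    )
    popmap = PopulationMap({s: ("A" if s.startswith("a") else "B") for s in gm.samples})
    return gm, popmap


def track_from_scores(scores, chrom="chr1", window=100_000, step=10_000):
    """Build a score-track DataFrame on the regular grid from raw scores."""
    starts = np.arange(len(scores)) * step
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window,
            "focal_bp": starts + window // 2,
            "n_snps": 10,
            "score": scores,
            "sigma_hat": 0.01,
            "partial": False,
        }
    )
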