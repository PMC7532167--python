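import numpy as np
import pandas as pd
import pytest

import landhap as lh


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study reused across read-only tests."""
    cfg = lh.SimConfig(
        seed=42, dh_per_landrace=60, n_breeding=30, snps_per_chromosome=120,
        n_chromosomes=2, n_environments=4,
    )
    panel, truth, pheno = lh.simulate_study(cfg)
    return cfg, panel, truth, pheno


@pytest.fixture(scope="session")
def small_haplotypes(small_study):
    _, panel, _, _ = small_study
    windows = lh.build_windows(panel.marker_map)
    catalog, matrix = lh.call_haplotypes(panel, windows)
    return windows, catalog, matrix


@pytest.fixture()
def tiny_panel():
    """Five hand-written homozygous lines on one chromosome."""
    geno = np.array(
        [
            [0, 0, 0, 0, 0, 0],
            [2, 0, 0, 0, 0, 0],
            [2, 2, 0, 0, 2, 0],
            [0, 0, 2, 2, 2, 2],
            [2, 2, 2, 2, 2, 2],
        ],
        dtype=np.int8,
    )
    mm = lh.MarkerMap(
        pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(6)],
                "chrom": ["chr1"] * 6,
                "pos_bp": [100, 200, 300, 400, 500, 600],
                "pos_cM": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            }
        )
    )
    return lh.GenotypePanel(
        [f"L{i}" for i in range(5)],
        ["A", "A", "A", "B", "B"],
        geno,
        mm,
    )
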