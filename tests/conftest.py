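import numpy as np
import pytest

import swinecnv as sc


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale config: 1 chromosome x 2 Mb, fast enough for unit tests."""
    return sc.SimulationConfig(
        seed=11,
        n_chrom=1,
        chrom_length_bp=2_000_000,
        n_cnv_loci=8,
        n_genes=60,
        n_qtl=60,
    )


@pytest.fixture(scope="session")
def small_run(small_cfg):
    """Simulated tracks -> CN matrix -> segments -> catalog on the small genome."""
    tracks, truth = sc.simulate_depth(small_cfg)
    matrix = sc.build_cn_matrix(tracks)
    segments = sc.segment_all(matrix)
    catalog = sc.build_cnvrs(segments, matrix)
    return {
        "cfg": small_cfg,
        "tracks": tracks,
        "truth": truth,
        "matrix": matrix,
        "segments": segments,
        "catalog": catalog,
    }


@pytest.fixture(scope="session")
def default_run():
    """The default study-scale simulation: 2 x 10 Mb, 12 LW + 11 MZ, ~12.89x."""
    cfg = sc.SimulationConfig(seed=1)
    tracks, truth = sc.simulate_depth(cfg)
    matrix = sc.build_cn_matrix(tracks)
    segments = sc.segment_all(matrix)
    catalog = sc.build_cnvrs(segments, matrix)
    return {
        "cfg": cfg,
        "truth": truth,
        "matrix": matrix,
        "segments": segments,
        "catalog": catalog,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
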