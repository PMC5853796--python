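import numpy as np
import pytest

from cishex.io import DatasetDEG, PromoterRecord
from cishex.simulate import PlantedMotif, SimConfig, simulate


@pytest.fixture(scope="session")
def planted_sim():
    """Small planted-motif scenario shared by association/permutation/pipeline tests."""
    cfg = SimConfig(
        n_genes=400,
        window_len=300,
        n_datasets=3,
        frac_up=0.15,
        frac_down=0.1,
        planted_motifs=(PlantedMotif("TGTCTC", "up", p_fg=0.9, p_bg=0.05),),
        seed=42,
    )
    return simulate(cfg)


@pytest.fixture()
def toy_promoters():
    return [
        PromoterRecord(gene_id="g1", seq="TGTCTC" + "A" * 24),
        PromoterRecord(gene_id="g2", seq="C" * 30),
        PromoterRecord(gene_id="g3", seq="CACGTG" + "G" * 24),
    ]


@pytest.fixture()
def two_datasets():
    universe = {f"g{i}" for i in range(1, 9)}
    d1 = DatasetDEG(
        "d1",
        {"g1": "up", "g2": "up", "g3": "down", "g4": "none"},
        set(universe),
        timepoint_h=1.0,
    )
    d2 = DatasetDEG(
        "d2",
        {"g1": "up", "g5": "down", "g6": "none"},
        set(universe),
        timepoint_h=4.0,
    )
    return [d1, d2]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
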