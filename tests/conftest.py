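import numpy as np
import pandas as pd
import pytest

from closcreen import (
    CountMatrix,
    GuideLibrary,
    SimulationConfig,
    simulate_screen,
)


def make_library(n_genes=2, guides_per_gene=10, n_nt=3, n_st=3, spacers=False):
    rows = []
    for g in range(1, n_genes + 1):
        gene = f"GENE{g:04d}"
        for i in range(1, guides_per_gene + 1):
            rows.append((f"{gene}_g{i}", "targeting", gene))
    for i in range(1, n_nt + 1):
        rows.append((f"nt_{i:03d}", "non_targeting", ""))
    for i in range(1, n_st + 1):
        rows.append((f"st_{i:03d}", "safe_targeting", ""))
    df = pd.DataFrame(rows, columns=["guide_id", "category", "gene"]).set_index(
        "guide_id"
    )
    if spacers:
        rng = np.random.default_rng(0)
        df["spacer"] = [
            "".join(rng.choice(list("ACGT"), size=20)) for _ in range(len(df))
        ]
    return GuideLibrary(df)


@pytest.fixture
def tiny_library():
    return make_library()


@pytest.fixture
def tiny_counts(tiny_library):
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(
        rng.poisson(100, size=(len(tiny_library), 2)),
        index=tiny_library.guide_ids,
        columns=["low", "high"],
    )
    return CountMatrix(counts)


@pytest.fixture(scope="session")
def null_screen():
    """All-null two-sample screen at desk scale."""
    cfg = SimulationConfig(
        n_genes=100,
        n_nontargeting=800,
        n_safetargeting=800,
        reads_per_guide=300,
        seed=11,
    )
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def planted_screen():
    """Two-sample screen with ten planted basal genes (±1.5 latent SD)."""
    genes = [f"GENE{i:04d}" for i in range(1, 11)]
    effect = pd.DataFrame(
        {"basal_shift": [1.5] * 5 + [-1.5] * 5, "stim_shift": [0.0] * 10},
        index=genes,
    )
    cfg = SimulationConfig(
        n_genes=100,
        n_nontargeting=800,
        n_safetargeting=800,
        reads_per_guide=300,
        effect_table=effect,
        seed=5,
    )
    return simulate_screen(cfg)
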