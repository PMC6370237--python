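import numpy as np
import pandas as pd
import pytest

from lethalmap.pedkin import validate_pedigree
from lethalmap.popsim import SimConfig, SnpPanelConfig, simulate_population


@pytest.fixture(scope="session")
def sim_pop():
    """One default-scale simulated population shared across tests."""
    return simulate_population(SimConfig(seed=11))


@pytest.fixture(scope="session")
def artifact_dir(sim_pop, tmp_path_factory):
    from lethalmap.io import emit_artifacts

    outdir = tmp_path_factory.mktemp("artifacts")
    paths = emit_artifacts(sim_pop, outdir, seed=11)
    return outdir, paths


@pytest.fixture(scope="session")
def small_sim_config():
    """Fast configuration: tiny marker panel, short pedigree."""
    return SimConfig(
        n_founders=60,
        n_generations=3,
        n_sires=8,
        n_dams=20,
        litter_mean=6.0,
        snp_panel=SnpPanelConfig(n_snps=24, chrom_lengths_bp=(80_000_000,)),
        causal_chrom=1,
        causal_pos_bp=40_000_000,
        seed=5,
    )


def random_pedigree(n: int, seed: int, p_founder: float = 0.3) -> pd.DataFrame:
    """Random valid pedigree frame: parents always precede offspring."""
    rng = np.random.default_rng(seed)
    rows = []
    males, females = [], []
    for i in range(1, n + 1):
        if not males or not females or rng.random() < p_founder:
            s = d = 0
        else:
            s = int(rng.choice(males))
            d = int(rng.choice(females))
        sex = "M" if rng.random() < 0.5 else "F"
        (males if sex == "M" else females).append(i)
        rows.append(dict(id=i, sire=s, dam=d, sex=sex, litter=i // 4, generation=0))
    return pd.DataFrame(rows)


@pytest.fixture
def trio_pedigree():
    return validate_pedigree(
        pd.DataFrame(
            {
                "id": [3, 1, 2],  # deliberately unordered
                "sire": [1, 0, 0],
                "dam": [2, 0, 0],
                "sex": ["M", "M", "F"],
                "litter": [1, 0, 0],
                "generation": [1, 0, 0],
            }
        )
    )
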