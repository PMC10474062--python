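import numpy as np
import pandas as pd
import pytest

import statemi as sm


@pytest.fixture(scope="session")
def default_dataset() -> sm.SimulatedDataset:
    """One dataset at the default study design (2000 genes, 4 x 5 samples)."""
    return sm.generate_counts(sm.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset() -> sm.SimulatedDataset:
    """A reduced design for fast structural tests."""
    cfg = sm.SimulationConfig(
        n_genes=300,
        planted_set_size=80,
        n_leukemic_responsive=60,
        n_genotype_responsive=30,
        seed=7,
    )
    return sm.generate_counts(cfg)


@pytest.fixture(scope="session")
def small_norm(small_dataset) -> sm.NormalizedMatrix:
    return sm.mean_center(sm.normalize_log(small_dataset.counts))


def null_config(n_genes: int, seed: int, **kw) -> sm.SimulationConfig:
    """A no-signal configuration: every effect size zero."""
    defaults = dict(
        n_genes=n_genes,
        planted_set_size=min(150, n_genes // 2),
        leukemic_lfc=0.0,
        genotype_lfc=0.0,
        n_leukemic_responsive=0,
        n_genotype_responsive=0,
        planted_set_responsive_frac=0.0,
        seed=seed,
    )
    defaults.update(kw)
    return sm.SimulationConfig(**defaults)


def random_annotation(samples, rng=None) -> pd.DataFrame:
    """Balanced 2x2 factorial annotation over an even sample list."""
    n = len(samples)
    per = n // 4
    conds = np.repeat(["wt", "KO", "CP", "BC"], per)
    leuk = np.where(np.isin(conds, ["CP", "BC"]), "CML", "non-CML")
    geno = np.where(np.isin(conds, ["KO", "BC"]), "KO", "wt")
    return pd.DataFrame(
        {"leukemic": leuk, "genotype": geno, "condition": conds}, index=samples
    )
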