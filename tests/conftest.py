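import numpy as np
import pandas as pd
import pytest

from phoskin.maxquant_io import GLOBAL_PST, SiteMatrix
from phoskin.synthetic_data import SimulationConfig, simulate_cohort


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down cohort (fewer kinases/sites, same statistical structure)
    used where a test only needs the structure, not the full size."""
    base = dict(
        n_samples=42,
        n_kinases=6,
        n_sites_global=120,
        n_sites_py=40,
        edges_per_kinase=6,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """One default-size simulated cohort, shared across read-only tests."""
    cfg = SimulationConfig(seed=11)
    truth, sites_g, sites_y, evidence, clinical = simulate_cohort(cfg)
    return {
        "cfg": cfg,
        "truth": truth,
        "sites_global": sites_g,
        "sites_py": sites_y,
        "evidence": evidence,
        "clinical": clinical,
    }


def make_site_matrix(values, channel=GLOBAL_PST, loc_prob=None, windows=None,
                     reverse=None, contaminant=None, proteins=None, positions=None,
                     residues=None):
    """Hand-built SiteMatrix for unit tests: ``values`` is a feature-key ->
    {sample: value} mapping (NaN allowed)."""
    data = pd.DataFrame(values).T
    n = len(data)
    keys = list(data.index)
    meta = pd.DataFrame(
        {
            "protein": proteins or [k.split("|")[0] for k in keys],
            "gene": [f"G{i}" for i in range(n)],
            "position": positions or [int(k.split("|")[1]) for k in keys],
            "residue": residues or ["S"] * n,
            "window": windows or ["AAAAAAASAAAAAAA"] * n,
            "localization_probability": loc_prob if loc_prob is not None else [0.99] * n,
            "multiplicity": [1] * n,
            "reverse": reverse if reverse is not None else [False] * n,
            "contaminant": contaminant if contaminant is not None else [False] * n,
        },
        index=keys,
    )
    return SiteMatrix(data, meta, channel)
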