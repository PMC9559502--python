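import numpy as np
import pandas as pd
import pytest

from herdlink.pedigree import Pedigree
from herdlink.varcomp import VarianceComponents


@pytest.fixture
def trio_pedigree() -> Pedigree:
    """Sire (1), dam (2), offspring (3)."""
    return Pedigree.from_frame(pd.DataFrame({
        "animal": [1, 2, 3],
        "sire": [0, 0, 1],
        "dam": [0, 0, 2],
        "herd": ["A", "A", "A"],
        "birth_year": [2000, 2000, 2001],
        "sex": ["M", "F", "F"],
        "breed": ["L", "L", "L"],
    }))


@pytest.fixture
def fullsib_mating_pedigree() -> Pedigree:
    """Founders 1,2; full sibs 3,4; inbred offspring 5 = 3 x 4."""
    return Pedigree.from_frame(pd.DataFrame({
        "animal": [1, 2, 3, 4, 5],
        "sire": [0, 0, 1, 1, 3],
        "dam": [0, 0, 2, 2, 4],
        "herd": "A",
        "birth_year": [2000, 2000, 2001, 2001, 2002],
        "sex": ["M", "F", "M", "F", "F"],
        "breed": "L",
    }))


@pytest.fixture
def table_vc() -> VarianceComponents:
    """Merged purebred-analysis variance components used across tests."""
    return VarianceComponents(sigma2_a=0.825, sigma2_p=1.171,
                              sigma2_l=0.189, sigma2_e=10.324)


def tiny_phenotypes(n_sows=4, parities=2, seed=0, herds=("A",)) -> pd.DataFrame:
    """Small balanced phenotype table resolvable against its own pedigree."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_sows):
        sow = 10 + k
        for p in range(1, parities + 1):
            rows.append({
                "sow": sow, "parity": p, "year": 2010 + p, "month": 3,
                "genotype": "L" if k % 2 == 0 else "LW",
                "litter_sire": 1 + (k % 2),
                "herd": herds[k % len(herds)],
                "age_days": 360 + 180 * p + int(rng.integers(0, 30)),
                "wci_days": np.nan if p == 1 else float(rng.integers(3, 30)),
                "prev_lact_days": np.nan if p == 1 else float(rng.integers(20, 35)),
                "birth_litter": f"L{k // 2}",
                "nba": float(rng.normal(16, 3)),
            })
    return pd.DataFrame(rows)


def tiny_pedigree_for(phen: pd.DataFrame) -> Pedigree:
    """Pedigree containing the sows of `tiny_phenotypes` plus their sires."""
    sows = sorted(phen["sow"].unique())
    rows = [{"animal": s, "sire": 0, "dam": 0, "herd": "A", "birth_year": 2008,
             "sex": "M", "breed": "L"} for s in (1, 2)]
    rows += [{"animal": s, "sire": 0, "dam": 0,
              "herd": phen[phen.sow == s].herd.iloc[0], "birth_year": 2009,
              "sex": "F", "breed": "L"} for s in sows]
    return Pedigree.from_frame(pd.DataFrame(rows))
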