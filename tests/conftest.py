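import numpy as np
import pandas as pd
import pytest

from rtbridge.io import ChromSystem, GradientSegment, RetentionTable
from rtbridge.simulate import SimulationConfig, simulate_study


def make_table(rt: dict, roles: dict) -> RetentionTable:
    """Build a RetentionTable from {cs_id: {compound: rt}} and
    {compound: role}."""
    ids = sorted(roles)
    meta = pd.DataFrame(
        {"role": [roles[c] for c in ids], "smiles": "", "inchikey": ""},
        index=pd.Index(ids, name="compound_id"),
    )
    frame = pd.DataFrame(
        {cs: [rt[cs].get(c, np.nan) for c in ids] for cs in rt},
        index=meta.index, dtype=float,
    )
    return RetentionTable(meta, frame)


def linear_system(cs_id: str, run_time: float = 20.0,
                  additive: str = "formic_acid",
                  mechanism: str = "RP") -> ChromSystem:
    return ChromSystem(
        cs_id=cs_id, mechanism=mechanism, column_chemistry="C18",
        additive_class=additive, run_time=run_time,
        gradient_segments=(GradientSegment(0.0, run_time, 0.05, 0.95),),
    )


@pytest.fixture(scope="session")
def small_study():
    """Deterministic 6-system synthetic study used across modules."""
    cfg = SimulationConfig(n_systems=6, seed=11)
    table, systems, truth = simulate_study(cfg)
    return cfg, table, systems, truth
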