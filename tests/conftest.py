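import numpy as np
import pandas as pd
import pytest

from egowave.model import FLAGS
from egowave.simulate import SimConfig, generate_cohort, generate_dataset


@pytest.fixture(scope="session")
def default_tables():
    """One default-condition cohort (~49 egos, nonresponse applied)."""
    return generate_dataset(SimConfig(), seed=20_001)


@pytest.fixture(scope="session")
def big_tables():
    """A larger cohort (400 egos, no nonresponse) for distributional checks."""
    cfg = SimConfig(n_randomized=400, nonresponse_rate=0.0)
    return generate_cohort(cfg, seed=20_002)


@pytest.fixture()
def tiny_tables():
    """Hand-built 3-ego tables exercising every ingest feature."""
    ego = pd.DataFrame(
        {
            "ego_id": ["e1", "e2", "e3"],
            "site": ["primary_site", "primary_site", "secondary_site"],
            "arm": ["intervention", "control", "control"],
            "gender": ["male", "female", "male"],
            "age": [50, 41, 63],
            "race": ["white", "other", "white"],
            "education": ["hs_or_less", "more_than_hs", "hs_or_less"],
            "married": ["never_married"] * 3,
            "n_children": [0, 2, 1],
            "income": [400.0, 900.0, 250.0],
            "audit_c": [5, 3, 0],
            "dast": [0, 0, 4],
            "readiness_to_change": [5, 7, 2],
        }
    )

    def alter(ego_id, wave, label, **flags):
        row = {"ego_id": ego_id, "wave": wave, "alter_label": label}
        row.update({f: int(flags.get(f, 0)) for f in FLAGS})
        return row

    alters = pd.DataFrame(
        [
            alter("e1", "baseline", "Al", drink_ever=1, drink_recent=1, emo_ever=1),
            alter("e1", "baseline", "Bea", drug_ever=1, info_ever=1, info_recent=1),
            alter("e1", "baseline", "Cy"),
            alter("e1", "followup", "Al", drink_ever=1, emo_ever=1, emo_recent=1),
            alter("e1", "followup", "Dee", influence_ever=1, influence_recent=1),
            alter("e2", "baseline", "Al", tang_ever=1),
            alter("e2", "baseline", "Eve", drink_ever=1),
            alter("e2", "followup", "Al", tang_ever=1, tang_recent=1),
            alter("e2", "followup", "Eve", drink_ever=1, drink_recent=1),
            alter("e3", "baseline", "Flo", drug_ever=1, drug_recent=1),
        ]
    )
    ties = pd.DataFrame(
        [
            {"ego_id": "e1", "wave": "baseline", "alter_a": "Al", "alter_b": "Bea", "knows": 1},
            {"ego_id": "e1", "wave": "followup", "alter_a": "Al", "alter_b": "Dee", "knows": 1},
            {"ego_id": "e2", "wave": "baseline", "alter_a": "Al", "alter_b": "Eve", "knows": 0},
        ]
    )
    return ego, alters, ties


def random_alter_frame(rng: np.random.Generator, n_alters: int, ego_id="e", wave="baseline"):
    """Random flag table respecting recent => ever (used by oracle tests)."""
    rows = []
    for i in range(n_alters):
        row = {"ego_id": ego_id, "wave": wave, "alter_label": f"a{i:02d}"}
        for fam in ("drink", "drug", "influence", "emo", "info", "tang"):
            ever = rng.random() < 0.5
            recent = ever and rng.random() < 0.6
            row[f"{fam}_ever"] = ever
            row[f"{fam}_recent"] = recent
        rows.append(row)
    return pd.DataFrame(rows)
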