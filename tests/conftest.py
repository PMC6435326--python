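import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_records(rows):
    """Build a PSM record table from (protein, pos, residue, glycoform,
    medium, light) tuples; light=None marks a singleton."""
    out = []
    for pid, pos, res, gf, medium, light in rows:
        out.append(
            {
                "protein_id": pid,
                "peptide": "SAMPLEPK",
                "site_position": pos,
                "residue": res,
                "glycoform": gf,
                "intensity_medium": medium,
                "intensity_light": np.nan if light is None else light,
                "paired": light is not None,
            }
        )
    return pd.DataFrame(out)


@pytest.fixture
def records_small():
    return make_records(
        [
            ("P1", 10, "T", "Tn", 100.0, 100.0),
            ("P1", 10, "T", "T", 100.0, 10.0),
            ("P1", 50, "S", "Tn", 200.0, 100.0),
            ("P2", 5, "T", "Tn", 100.0, None),
        ]
    )
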