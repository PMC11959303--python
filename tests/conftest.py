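import numpy as np
import pandas as pd
import pytest

from clonoscreen import ScreenGenConfig, simulate_screen


@pytest.fixture
def default_screen():
    """One simulated plate under the default (independent, f=1) generator."""
    records, truth = simulate_screen(ScreenGenConfig(seed=0))
    return records, truth


def make_well_table(counts_by_condition: dict, plate_id: str = "P1",
                    drug_id: str = "d1") -> pd.DataFrame:
    """Build a long-format well table from explicit replicate counts.

    ``counts_by_condition`` maps keys like ``('control',)``, ``('ir',)``,
    ``('drug', conc)`` and ``('combo', conc)`` to lists of colony counts.
    """
    rows = []
    for key, counts in counts_by_condition.items():
        kind = key[0]
        conc = key[1] if len(key) > 1 else np.nan
        dose = 2.0 if kind in ("ir", "combo") else 0.0
        c = conc if kind in ("drug", "combo") else np.nan
        for rep, n in enumerate(counts):
            rows.append({"plate_id": plate_id, "well": f"W{len(rows)}",
                         "drug_id": drug_id if kind in ("drug", "combo")
                         else "", "concentration": c, "radiation_dose": dose,
                         "replicate": rep, "colony_count": n})
    return pd.DataFrame(rows)
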