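import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from diseasome_kit import PanelScenario, generate_panel


@pytest.fixture(scope="session")
def overlap_scenario() -> PanelScenario:
    """A three-disease panel with a planted cross-disease overlap plan in a
    high-power regime (large effect, modest noise, 10v10)."""
    return PanelScenario(
        n_genes=1500,
        diseases=("T2D", "AD", "MS"),
        n_case=10,
        n_control=10,
        de_fraction=0.10,
        effect_size=3.0,
        noise_sd=0.4,
        overlap_plan={("T2D", "AD"): (6, 4), ("T2D", "MS"): (12, 9)},
        seed=11,
    )


@pytest.fixture(scope="session")
def overlap_panel(overlap_scenario):
    return generate_panel(overlap_scenario)
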