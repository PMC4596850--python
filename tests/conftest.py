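import json
from importlib import resources

import numpy as np
import pytest

from venomest import cysteine, simulate


@pytest.fixture(scope="session")
def pattern_data() -> dict:
    path = resources.files("venomest.data") / "family_patterns.json"
    return json.loads(path.read_text())


@pytest.fixture(scope="session")
def family_patterns(pattern_data) -> dict:
    """Family label -> parsed CysteinePattern for the eight family strings."""
    return {
        name: cysteine.parse_pattern_string(s)
        for name, s in pattern_data["families"].items()
    }


@pytest.fixture(scope="session")
def extra_skeleton_patterns(pattern_data) -> list:
    return [
        cysteine.parse_pattern_string(s)
        for s in pattern_data["mizhoanus_specific_skeletons"]
    ]


@pytest.fixture(scope="session")
def templates() -> list:
    return simulate.default_templates()


@pytest.fixture(scope="session")
def small_library(templates):
    """Deterministic ~120-EST noise-free library shared across tests."""
    config = simulate.LibraryConfig(
        family_sizes={t.name: 3 for t in templates},
        category_mix={"toxin": 90, "cellular": 21, "unknown": 6},
        substitution_rate=0.0,
        seed=2024,
    )
    records, truths = simulate.generate_library(config, templates)
    return config, records, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
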