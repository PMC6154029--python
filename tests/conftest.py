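import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from saltqtl.simulate import SimGenomeSpec, simulate_dh_population

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def small_population():
    """A compact DH population: two linkage groups, 10 cM spacing, 200 lines."""
    spec = SimGenomeSpec(
        linkage_groups=(("2B", 60.0), ("7A", 60.0)),
        marker_spacing_cm=10.0,
        n_lines=200,
        seed=11,
    )
    return simulate_dh_population(spec)


@pytest.fixture(scope="session")
def default_population():
    """The default emulation scale: 212 lines, five 120 cM groups, 5 cM spacing."""
    return simulate_dh_population(SimGenomeSpec(seed=20))


@pytest.fixture()
def tiny_map():
    return pd.DataFrame(
        {
            "marker": ["m1", "m2", "m3"],
            "group": ["7A", "7A", "7A"],
            "pos_cm": [0.0, 10.0, 20.0],
        }
    )


def make_geno(calls: dict[str, list[str | None]], lines=None) -> pd.DataFrame:
    """Build a genotype frame from marker -> per-line call lists (None = missing)."""
    n = len(next(iter(calls.values())))
    lines = lines or [f"L{i:03d}" for i in range(n)]
    data = {
        m: [np.nan if c is None else c for c in col] for m, col in calls.items()
    }
    return pd.DataFrame(data, index=lines, dtype=object)
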