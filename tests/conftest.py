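import numpy as np
import pandas as pd
import pytest

from gelheterosis.simulate import SyntheticSpec, generate_triads


@pytest.fixture
def small_triad():
    """Tiny noiseless triad table (one spot per pattern class) + labels."""
    spec = SyntheticSpec(
        n_spots_per_class={p: 1 for p in ("A", "+", "-", "++", "--", "+-")},
        cv=0.0,
        stages=("D10",),
        seed=7,
    )
    return generate_triads(spec)


@pytest.fixture
def complete_spot_table():
    """Deterministic complete 3-genotype x 2-stage x 3-replicate table, 2 spots."""
    rows = []
    rng = np.random.default_rng(11)
    for spot in ("s1", "s2"):
        for geno in ("P1", "P2", "F1"):
            for stage in ("D6", "D8"):
                for rep in (1, 2, 3):
                    rows.append((spot, geno, stage, rep, float(rng.uniform(50, 150))))
    return pd.DataFrame(
        rows, columns=["spot_id", "genotype", "stage", "replicate", "intensity"]
    )
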