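import numpy as np
import pandas as pd
import pytest

from paleorange import occurrences as occ
from paleorange import pipeline_cli as pc
from paleorange import synthetic_data as sd

DATA_DIR = __import__("pathlib").Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def table2():
    return pd.read_csv(DATA_DIR / "table2_fixture.csv")


@pytest.fixture(scope="session")
def table4():
    return pd.read_csv(DATA_DIR / "table4_fixture.csv")


def make_occurrence_frame(rows):
    """Occurrence table from (species, lng, lat, min_ma, max_ma) tuples."""
    return pd.DataFrame(
        [
            {
                "species": sp,
                "genus": sp.split()[0],
                "clade": "TestClade",
                "paleo_lng": lng,
                "paleo_lat": lat,
                "min_ma": lo,
                "max_ma": hi,
            }
            for sp, lng, lat, lo, hi in rows
        ]
    )


@pytest.fixture
def small_dataset():
    """Nine species x 3 occurrences spread over three 5-Myr bins."""
    rows = []
    for b, mid in enumerate((12.5, 7.5, 2.5)):
        for s in range(3):
            name = f"Acme b{b}s{s}"
            for k in range(3):
                rows.append((name, float(10 * s + k), float(5 * b + k), mid - 1, mid + 1))
    return occ.dataset_from_frame(make_occurrence_frame(rows), planar=True)


def fast_config(seed=0, **overrides):
    """Pipeline settings scaled for test runtimes; fixed 2.5-Myr bins."""
    defaults = dict(
        planar=True,
        seed=seed,
        n_rand=499,
        candidate_bin_lengths=[2.5],
        mcmc_iterations=6000,
        mcmc_burnin=1500,
        mcmc_thin=45,
        covariate_iterations=20000,
        covariate_thin=20,
        covariate_burnin_samples=100,
    )
    defaults.update(overrides)
    return pc.RunConfig(**defaults)


@pytest.fixture(scope="session")
def late_phase_result():
    """One full pipeline run on a late-phase clade, shared across tests."""
    occ_df, history = sd.end_to_end_case("late-phase-specialisation", seed=3)
    ds = occ.dataset_from_frame(occ_df, planar=True)
    result = pc.analyze_clade(ds, fast_config(seed=3))
    return {"occ_df": occ_df, "history": history, "result": result}
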