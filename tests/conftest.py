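import numpy as np
import pandas as pd
import pytest

import bayesrr as br

#: master seed used for every stochastic test in the suite
SEED = 1234

CSV_HEADER = (
    "age_years,sex,sofa,cfs,niv,mech_vent,vasoactive,rrt,"
    "withhold,withdraw,admission_dx,elective_surgery,mortality_30d"
)


def make_csv(tmp_path, rows, name="cohort.csv"):
    path = tmp_path / name
    path.write_text(CSV_HEADER + "\n" + "\n".join(rows) + "\n")
    return path


def full_row(age=85, sex="male", sofa=7, cfs=4, niv=0, mech_vent=1, vasoactive=1,
             rrt=0, withhold=0, withdraw=0, dx="dx1", elective=0, died=1):
    return (
        f"{age},{sex},{sofa},{cfs},{niv},{mech_vent},{vasoactive},{rrt},"
        f"{withhold},{withdraw},{dx},{elective},{died}"
    )


@pytest.fixture(scope="session")
def fixture_table() -> br.TwoByTwoTable:
    """The published 2x2 mortality counts."""
    return br.fixture_two_by_two()


def random_cohort(rng: np.random.Generator, n: int = 50) -> br.CohortTable:
    """A small random cohort with both age groups guaranteed present."""
    age = rng.integers(80, 100, size=n)
    age[0], age[1] = 85, 92
    df = pd.DataFrame(
        {
            "age_years": pd.array(age, dtype="Int64"),
            "sex": rng.choice(["male", "female"], size=n),
            "sofa": pd.array(rng.integers(0, 25, size=n), dtype="Int64"),
            "cfs": pd.array(rng.integers(1, 10, size=n), dtype="Int64"),
            "admission_dx": rng.choice(["dx1", "dx2", "dx3"], size=n),
            "elective_surgery": pd.array(np.zeros(n, bool), dtype="boolean"),
            "mortality_30d": pd.array(rng.random(n) < 0.4, dtype="boolean"),
        }
    )
    for col in ("niv", "mech_vent", "vasoactive", "rrt", "withhold", "withdraw"):
        df[col] = pd.array(rng.random(n) < 0.3, dtype="boolean")
    from bayesrr.cohort import SCHEMA, cohort_from_frame

    return cohort_from_frame(df[list(SCHEMA)], provenance="random test cohort")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
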