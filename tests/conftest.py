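import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ch4herd import simdata
from ch4herd.legendre_rr import LegendreBasis


@pytest.fixture(scope="session")
def trio_pedigree():
    """Two founders and their single offspring."""
    return simdata.simulate_pedigree(2, 1, 1, 1, seed=0)


@pytest.fixture(scope="session")
def small_herd():
    """A deterministic small herd: pedigree, genotypes, effects, records."""
    ped = simdata.simulate_pedigree(20, 2, 20, 2, seed=7, n_sires_per_generation=4)
    geno = simdata.simulate_genotypes(ped, 400, 5, seed=8)
    K_a = np.array([[8.0, 1.0, 0.0], [1.0, 1.5, 0.3], [0.0, 0.3, 0.5]])
    K_p = np.diag([10.0, 1.5, 0.5])
    eff = simdata.simulate_true_effects(ped, geno, K_a, K_p, seed=9)
    basis = LegendreBasis(2, 5, 305)
    rec = simdata.simulate_records(
        ped, eff,
        fixed_spec=simdata.FixedSpec(
            curve_coeffs=(-4.0, 1.5, -0.6, 0.2), fyw_sd=3.0, lac2_effect=2.5
        ),
        schedule_spec=simdata.ScheduleSpec(n_days_per_cow=10, mean_visits_per_day=2.0),
        sigma_e=4.0, seed=10, basis=basis,
    )
    return {"ped": ped, "geno": geno, "eff": eff, "records": rec,
            "K_a": K_a, "K_p": K_p, "basis": basis}


@pytest.fixture()
def gas_records():
    """Hand-built raw gas records for phenotype-construction tests."""
    rows = []
    for t, v in [(0.0, 400.0), (12.0, 600.0)]:
        rows.append((1, "farm1", pd.Timestamp("2015-03-02").date(), t, 1, 20,
                     v, v / 0.1, 30.0, 550.0, 0))
    rows.append((2, "farm2", pd.Timestamp("2016-02-10").date(), 6.0, 3, 5,
                 500.0, 5000.0, 35.0, 650.0, 0))
    return pd.DataFrame(
        rows,
        columns=["cow_id", "farm", "date", "time_h", "lactation", "dim",
                 "ch4_ppm", "co2_ppm", "milk_kg_day", "live_weight_kg",
                 "pregnancy_day"],
    )
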