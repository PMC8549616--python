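import numpy as np
import pandas as pd
import pytest

from multistress import dataio, synthdata


def make_records(cells, censor_day=40.0):
    """Build a minimal valid record table from explicit cell specs.

    ``cells`` is an iterable of (population, arm_code, genotype, values)
    where ``values`` is a list of trait dicts (one per replicate row).
    """
    rows = []
    for pop, arm_code, genotype, values in cells:
        arm = dataio.ARMS[arm_code]
        for i, vals in enumerate(values, start=1):
            rows.append({
                "population": pop, "genotype": genotype, "batch": "B1",
                "algae_level": arm.algae_level,
                "insecticide_level": arm.insecticide_level,
                "replicate": i,
                "fecundity": vals.get("fecundity", np.nan),
                "size_mm": vals.get("size_mm", np.nan),
                "age_days": vals.get("age_days", np.nan),
                "death_day": vals.get("death_day", censor_day),
                "event": vals.get("event", False),
            })
    return pd.DataFrame(rows, columns=list(dataio.CSV_COLUMNS))


@pytest.fixture(scope="session")
def demo_config():
    """Moderate-size config exercising every downstream stage."""
    singles = {
        "HA": {"fecundity": 1.0, "size_mm": 0.2, "age_days": -0.5},
        "LA": {"fecundity": -3.0, "size_mm": -0.5, "age_days": 1.5},
        "HI": {"fecundity": -2.0, "size_mm": -0.3, "age_days": 1.0},
        "LI": {"fecundity": -1.0, "size_mm": -0.1, "age_days": 0.5},
    }
    return synthdata.SyntheticConfig(
        n_replicates=4,
        population_effects={"PP": {"fecundity": 2.0, "size_mm": 0.3},
                            "CWP": {"size_mm": -0.2}},
        treatment_effects=synthdata.additive_treatment_effects(singles),
        stressor_interaction={"LAHI": {"fecundity": -2.0}},
        sd_genotype=0.4, sd_batch=0.2, sd_residual=1.0,
        hazard=synthdata.WeibullHazard(
            scale=120.0, shape=1.0, log_hazard_arm={"LAHI": 0.8, "LALI": 0.5}
        ),
        seed=20240901,
    )


@pytest.fixture(scope="session")
def demo_records(demo_config):
    records, _ = synthdata.generate_experiment(demo_config)
    return records


@pytest.fixture(scope="session")
def demo_truth(demo_config):
    _, truth = synthdata.generate_experiment(demo_config)
    return truth
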