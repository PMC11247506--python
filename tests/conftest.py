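import pytest

from cnatriage import synthetic_data as sd


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return sd.simulate_cohort(sd.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_screen():
    """Synthetic screen table + line truth for the default cohort's genes."""
    cohort = sd.simulate_cohort(sd.SimulationConfig(seed=7))
    genes = cohort.truth.gene_truth[
        cohort.truth.gene_truth["role"].isin(["driver", "passenger"])
    ].copy()
    genes = genes.groupby("region_id", sort=True).head(3)  # a few lines per region
    genes["group"] = "G1I"
    table, line_truth = sd.simulate_screen(
        sd.SimulationConfig(seed=7), genes[["symbol", "group", "direction", "is_driver"]]
    )
    return table, line_truth
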