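import dataclasses

import numpy as np
import pytest

from smokeburden import indicators, synth
from smokeburden.models import add_age_band
from smokeburden.tcs import aggregate_tcs


@pytest.fixture(scope="session")
def small_scenario():
    """Six-country scenario, reduced sample: fast but structurally complete."""
    return dataclasses.replace(
        synth.SyntheticConfig(),
        countries=synth.DEFAULT_COUNTRIES[:6],
        n_per_country=500,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_microdata(small_scenario):
    return synth.generate(small_scenario)


@pytest.fixture(scope="session")
def small_indicators(small_scenario, small_microdata):
    valid, _ = indicators.validate_frame(small_microdata)
    ind = indicators.compute_indicators(valid)
    ind = add_age_band(ind)
    tcs_table = aggregate_tcs(synth.tcs_long_table(small_scenario))
    return ind.merge(tcs_table[["country", "tcs_category"]], on="country", how="left")


def random_valid_records(rng, n):
    """Hand-rolled random valid smoking records (independent of the package's
    generator) for formula checks."""
    records = []
    for i in range(n):
        status = rng.choice(["current", "former", "never"])
        age = int(rng.integers(15, 91))
        start = quit = cpd = None
        if status != "never":
            start = int(rng.integers(12, age + 1))
            cpd = float(np.round(rng.uniform(0, 60), 1))
            if status == "former":
                quit = int(rng.integers(start, age + 1))
        records.append(
            indicators.SmokingRecord(
                respondent_id=str(i),
                country="AT",
                weight=float(rng.uniform(0.2, 3.0)),
                age=age,
                sex="male",
                education_end="le15",
                paying_bills="most_of_time",
                residence="rural",
                occupation="employed",
                marital="single_no_child",
                smoking_status=status,
                start_age=start,
                quit_age=quit,
                cigs_per_day=cpd,
            )
        )
    return records
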