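"""Shared fixtures: one default synthetic cohort reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from covrare.cohortsim import SimConfig, simulate_cohort

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def sim():
    """Default synthetic cohort (110 samples, ~3,000 variants, all plants)."""
    return simulate_cohort(SimConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def sexes(sim):
    """True sex per sample (the generator's ground truth)."""
    return dict(zip(sim.truth.samples.sample_id, sim.truth.samples.true_sex))


@pytest.fixture(scope="session")
def reported_sexes(sim):
    return {s.sample_id: s.reported_sex for s in sim.samples}


def table1_sheet() -> pd.DataFrame:
    """A sample sheet carrying exactly the modelled study's printed category
    counts (N = 110): 82/28 male/female; ages 17/25/38/30 in the decade bins;
    BMI 27/43/23 (+17 NA); smoking 95/5 (+10 NA); vaccination 91/10 (+9 NA);
    WHO 1 dead / 23 severe / 86 moderate."""
    rows = []

    def add(n, **kw):
        for _ in range(n):
            rows.append(dict(kw))

    sex = ["male"] * 82 + ["female"] * 28
    age = [20] * 17 + [35] * 25 + [45] * 38 + [55] * 30
    bmi = [22.0] * 27 + [27.0] * 43 + [33.0] * 23 + [None] * 17
    smoking = ["no"] * 95 + ["yes"] * 5 + [None] * 10
    vacc = ["no"] * 91 + ["yes"] * 10 + [None] * 9
    who = [10] * 1 + [7] * 23 + [4] * 86
    for i in range(110):
        rows.append({
            "sample_id": f"T{i:03d}", "reported_sex": sex[i], "age": age[i],
            "bmi": bmi[i], "smoking": smoking[i], "vaccinated": vacc[i],
            "who_score": who[i],
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def printed_counts_sheet():
    return table1_sheet()


def subseed(base: int, k: int) -> int:
    """Derive a stream-specific 31-bit seed."""
    return int(np.random.SeedSequence([base, k]).generate_state(1)[0] % (2**31))
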