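import numpy as np
import pytest

from nmjscreen import synthetic_data as syn
from nmjscreen.screen_data import (
    DrugRecord,
    FishObservation,
    Group,
    ScreenTable,
    WellAddress,
)


@pytest.fixture
def controls_table() -> ScreenTable:
    """One plate, one WT well and one MO well, 4 fish each, no drugs."""
    obs = []
    wt_addr = WellAddress(1, "A", 1)
    mo_addr = WellAddress(1, "A", 12)
    for fi, d in enumerate([0.8, 1.0, 1.2, 1.0], start=1):
        obs.append(FishObservation(wt_addr, fi, Group.WT_CONTROL, None, True, d))
    for fi, d in enumerate([0.0, 0.0, 0.15, 0.0], start=1):
        obs.append(FishObservation(mo_addr, fi, Group.MO_CONTROL, None, True, d))
    return ScreenTable(observations=obs)


@pytest.fixture
def one_drug_table(controls_table) -> ScreenTable:
    addr = WellAddress(1, "B", 5)
    obs = list(controls_table.observations)
    for fi, d in enumerate([0.9, 1.1, 1.0, 0.95], start=1):
        obs.append(FishObservation(addr, fi, Group.TREATED, "D1", True, d))
    return ScreenTable(observations=obs, drugs=[DrugRecord(drug_id="D1")])


@pytest.fixture
def small_cohort() -> syn.CohortParams:
    return syn.CohortParams(n_drugs=10, seed=42)


@pytest.fixture
def noise_free_truth() -> syn.ImageTruth:
    return syn.make_image_truth(
        n_spots=12, axon_length_um=120, on_axon_fraction=1.0, noise_sd=(0.0, 0.0), seed=7
    )
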