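import numpy as np
import pytest

from oatimpact import (
    EntrySchedule,
    ParameterSet,
    SyntheticCohortConfig,
    nsw_entry_schedule,
    reference_parameters,
)
from oatimpact.model import (
    COMPARTMENTS,
    N_COMPARTMENTS,
    Compartment,
    EngagementClass,
    IncarcerationStratum,
    UseStage,
    index_of,
)


@pytest.fixture(scope="session")
def ref_params() -> ParameterSet:
    return reference_parameters()


@pytest.fixture(scope="session")
def nsw_schedule(ref_params) -> EntrySchedule:
    return nsw_entry_schedule(SyntheticCohortConfig(), ref_params)


@pytest.fixture()
def inert_params() -> ParameterSet:
    """No transitions, no deaths: every compartment is frozen."""
    p = reference_parameters()
    flat = p.to_flat()
    for k, v in flat.items():
        if k == "trend_form":
            continue
        if k.startswith("rr_") or k.startswith("prison_mort"):
            flat[k] = 1.0
        elif k == "p_stable":
            flat[k] = 0.5
        else:
            flat[k] = 0.0
    return ParameterSet.from_flat(flat)


@pytest.fixture()
def single_mass_schedule():
    """Factory: schedule with no entries, all initial mass in one compartment."""

    def make(compartment: Compartment, amount: float = 1000.0) -> EntrySchedule:
        pop = np.zeros(N_COMPARTMENTS)
        pop[index_of(compartment)] = amount
        years = np.arange(2001, 2021)
        return EntrySchedule(
            years=years,
            entries=np.zeros(years.size),
            stratum_fracs=np.tile([1.0, 0.0, 0.0, 0.0], (years.size, 1)),
            initial_population=pop,
        )

    return make


@pytest.fixture()
def off_rest_comm() -> Compartment:
    return Compartment(
        UseStage.OFF_REST, EngagementClass.STABLE, IncarcerationStratum.COMM
    )
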