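import pandas as pd
import pytest

from csrpath.io import ExperimentTable
from csrpath.network import (
    ExtendedNetwork,
    NonCanonicalEdge,
    Reaction,
    Role,
    Species,
    TreatmentCondition,
)


def make_table(conditions, signals=None, responses=None):
    """ExperimentTable from dicts of {readout: [values per condition]}."""
    ids = [c.id for c in conditions]
    sig = pd.DataFrame(signals or {}, index=ids, dtype=float)
    res = pd.DataFrame(responses or {}, index=ids, dtype=float)
    return ExperimentTable(conditions=conditions, signals=sig, responses=res)


@pytest.fixture
def two_path_net():
    """Mirror-symmetric parallel paths S -> A -> T and S -> B -> T."""
    species = [
        Species("S", Role.STIMULUS),
        Species("A", Role.INTERMEDIATE),
        Species("B", Role.INTERMEDIATE),
        Species("T", Role.MEASURED_SIGNAL),
    ]
    reactions = [
        Reaction("r1", ["S"], [], "A"),
        Reaction("r2", ["A"], [], "T"),
        Reaction("r3", ["S"], [], "B"),
        Reaction("r4", ["B"], [], "T"),
    ]
    return ExtendedNetwork(species, reactions)


@pytest.fixture
def two_path_data(two_path_net):
    cond = TreatmentCondition("k1", stimuli_on=["S"])
    return make_table([cond], signals={"T": [1.0]})


@pytest.fixture
def response_net():
    """One canonical step S -> G plus a single non-canonical edge G -> Q."""
    species = [
        Species("S", Role.STIMULUS),
        Species("G", Role.MEASURED_SIGNAL),
        Species("Q", Role.RESPONSE),
    ]
    reactions = [Reaction("r1", ["S"], [], "G")]
    edges = [NonCanonicalEdge("e1", "G", "Q", 0.7)]
    return ExtendedNetwork(species, reactions, edges)
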