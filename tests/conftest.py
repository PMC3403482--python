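import pytest

from cocktailnet.atc import DrugRecord
from cocktailnet.network import CombinationRecord, build_network


def make_drug(drug_id, codes, targets=(), name=""):
    return DrugRecord(
        drug_id=drug_id,
        name=name or drug_id,
        atc_codes=frozenset(codes),
        targets=frozenset(targets),
    )


@pytest.fixture
def drug_factory():
    return make_drug


@pytest.fixture
def toy_dataset():
    """Five drugs in two therapeutic families plus one outsider.

    a, b, c share the C03A family (high TS); d is a distant C-class
    drug; e is from an unrelated class.  Combinations link a-b, a-c,
    b-c and a-d, so a, b, c are star drugs and every a/b/c pair is both
    similar and combined.
    """
    drugs = {
        "a": make_drug("a", ["C03AA03"]),
        "b": make_drug("b", ["C03AA01"]),
        "c": make_drug("c", ["C03AB02"]),
        "d": make_drug("d", ["C09XX01"]),
        "e": make_drug("e", ["N02BA01"]),
    }
    combos = [
        CombinationRecord("k1", ("a", "b")),
        CombinationRecord("k2", ("a", "c")),
        CombinationRecord("k3", ("b", "c")),
        CombinationRecord("k4", ("a", "d")),
        CombinationRecord("k5", ("d", "e")),
    ]
    net = build_network(combos, drugs)
    return drugs, combos, net
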