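import pytest

from huttrial import FateCounts, HutNightRecord
from huttrial.inference import PairwiseResult
from huttrial.simulate import source_trial_arms, source_trial_design, source_trial_params


@pytest.fixture(scope="session")
def five_arms():
    return source_trial_arms()


@pytest.fixture(scope="session")
def small_trial_design():
    return source_trial_design(n_nights=12, seed=3)


@pytest.fixture(scope="session")
def source_params():
    return source_trial_params(seed=0)


def _rec(night, hut, arm, trapped, dead, delayed, survived,
         species="an_gambiae", sleeper=None):
    return HutNightRecord(
        night=night,
        hut=hut,
        sleeper=hut if sleeper is None else sleeper,
        arm=arm,
        species_group=species,
        counts=FateCounts(trapped, dead, delayed, survived),
    )


@pytest.fixture
def hand_records():
    """Three-arm, two-night fixture with hand-checkable totals.

    T-LLIN:    entries 7 + 4 = 11, kills 6 + 3 = 9, trapped 5
    PN2.0:     entries 6 + 5 = 11, kills 4 + 2 = 6
    untreated: entries 5 + 5 = 10, kills 1 + 1 = 2
    """
    return [
        _rec(1, 1, "T-LLIN", 3, 2, 1, 1),
        _rec(2, 1, "T-LLIN", 2, 1, 0, 1),
        _rec(1, 2, "PN2.0", 0, 3, 1, 2),
        _rec(2, 2, "PN2.0", 0, 2, 0, 3),
        _rec(1, 3, "untreated", 0, 1, 0, 4),
        _rec(2, 3, "untreated", 0, 0, 1, 4),
    ]


def make_pairwise(groups, significant_pairs):
    """PairwiseResult list from an explicit set of significant pairs."""
    sig = {frozenset(p) for p in significant_pairs}
    out = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            is_sig = frozenset((a, b)) in sig
            p = 0.001 if is_sig else 0.5
            out.append(
                PairwiseResult(
                    group_a=a,
                    group_b=b,
                    statistic=0.0,
                    p_value=p,
                    p_adjusted=p,
                    significant=is_sig,
                )
            )
    return out
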