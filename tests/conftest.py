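import pytest
from hypothesis import HealthCheck, settings

from cycleont import CycleType, build_sequence

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Hand-checked 16-cycle duration sequence with a net shortening trend.
#: Independent adjacent-pair tally: 3 duration increases totalling 3,
#: decreases totalling 7, absolute change 10 — closer to accelerating
#: than to even beating.
MIXED_TREND_DURATIONS = (5, 5, 4, 4, 5, 3, 3, 2, 2, 2, 3, 2, 1, 2, 1, 1)

AF = CycleType.ATRIAL_FIBRILLATION
SA = CycleType.SA_NODE


@pytest.fixture
def mixed_trend_durations():
    return MIXED_TREND_DURATIONS


def typed_sequence(type_list, duration=1.0):
    """Unit-duration sequence with the given cycle types."""
    return build_sequence([duration] * len(type_list), types=list(type_list))
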