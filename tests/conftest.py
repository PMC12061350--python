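import datetime as dt

import pytest

from ambient_phenotype.events import HomeLayout, SensorEvent, SensorType

NIGHT = dt.date(2020, 3, 1)  # arbitrary reference night/day used by rule tests


@pytest.fixture
def layout() -> HomeLayout:
    """Four-area toy home: bedroom, kitchen, living, entry (with the front door)."""
    return HomeLayout(
        areas={
            "mb": "bedroom",
            "mk": "kitchen",
            "ml": "living",
            "me": "entry",
        },
        bedroom_areas=frozenset({"bedroom"}),
        external_doors=frozenset({"dd"}),
        door_areas=frozenset({"entry"}),
    )


def at(day_offset: int, hh: int, mm: int, ss: int = 0) -> dt.datetime:
    """Timestamp relative to the reference night's date."""
    return dt.datetime.combine(NIGHT, dt.time(0, 0)) + dt.timedelta(
        days=day_offset, hours=hh, minutes=mm, seconds=ss
    )


def motion(t: dt.datetime, sensor: str) -> SensorEvent:
    return SensorEvent(t, sensor, SensorType.MOTION, "ON")


def door(t: dt.datetime, value: str = "OPEN", sensor: str = "dd") -> SensorEvent:
    return SensorEvent(t, sensor, SensorType.DOOR, value)
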