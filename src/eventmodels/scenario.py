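"""Observation streams with known ground truth.

Provides the canned worked-example fixtures (patrol, two-location goal,
office day) plus a seeded random stream generator, together with the JSONL
stream dialect used by the command line tools.  Every other module is tested
against streams produced here, so the generator also records the
ground-truth event intervals implied by each stream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

CHANNELS = ("goal", "location", "person", "object")
POLARITIES = ("onset", "offset")

#: Channels on which several entities may be active at once.  Location is
#: single-valued: the onset of a new location implies the offset of the
#: previous one at the same instant.
MULTI_VALUED_CHANNELS = frozenset({"goal", "person", "object"})


class StreamParseError(ValueError):
    """A JSONL observation line failed to parse; carries the line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


@dataclass(frozen=True, order=True)
class Observation:
    """One timestamped symbolic report: an entity appears on or leaves a channel."""

    time: float
    channel: str
    entity: str
    polarity: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ValueError(f"observation time must be finite and non-negative, got {self.time}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}; expected one of {POLARITIES}")
        if not self.entity:
            raise ValueError("entity label must be non-empty")


@dataclass(frozen=True)
class GroundTruthEvent:
    """An interval (or open interval) an ideal observer would recover."""

    label: str
    channel: str
    start: float
    end: Optional[float]  # None = still ongoing at the end of the stream

    def __post_init__(self) -> None:
        if self.end is not None and self.start > self.end:
            raise ValueError(f"ground-truth event {self.label!r}: start {self.start} > end {self.end}")


@dataclass
class Scenario:
    """A named, time-ordered observation stream plus its ground truth."""

    name: str
    observations: list[Observation] = field(default_factory=list)
    ground_truth_events: list[GroundTruthEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [o.time for o in self.observations]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"scenario {self.name!r}: observations must be sorted by time")


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------

def patrol_fixture() -> Scenario:
    """An agent patrols through three locations and encounters Bob.

    Eight change-points at unit spacing: the patrol goal begins, three
    successive locations are entered, Bob arrives and departs, the goal is
    satisfied, and finally a post-goal location change occurs.
    """
    obs = [
        Observation(1.0, "goal", "patrol", "onset"),
        Observation(2.0, "location", "location-a", "onset"),
        Observation(3.0, "location", "location-b", "onset"),
        Observation(4.0, "location", "location-c", "onset"),
        Observation(5.0, "person", "Bob", "onset"),
        Observation(6.0, "person", "Bob", "offset"),
        Observation(7.0, "goal", "patrol", "offset"),
        Observation(8.0, "location", "location-d", "onset"),
    ]
    truth = [
        GroundTruthEvent("patrol", "goal", 1.0, 7.0),
        GroundTruthEvent("location-a", "location", 2.0, 3.0),
        GroundTruthEvent("location-b", "location", 3.0, 4.0),
        GroundTruthEvent("location-c", "location", 4.0, 8.0),
        GroundTruthEvent("Bob", "person", 5.0, 6.0),
        GroundTruthEvent("location-d", "location", 8.0, None),
    ]
    return Scenario("patrol", obs, truth)


def two_location_goal_fixture() -> Scenario:
    """A goal during which two locations are visited in turn.

    Four change-points: goal onset, location-1 onset, location-2 onset, and
    goal satisfaction.  Leaving location-2 coincides with satisfying the
    goal, so the final instant carries two simultaneous changes collapsed
    into a single marker, and the goal offset is the last observation.
    """
    obs = [
        Observation(1.0, "goal", "goal", "onset"),
        Observation(2.0, "location", "location-1", "onset"),
        Observation(3.0, "location", "location-2", "onset"),
        Observation(4.0, "location", "location-2", "offset"),
        Observation(4.0, "goal", "goal", "offset"),
    ]
    truth = [
        GroundTruthEvent("goal", "goal", 1.0, 4.0),
        GroundTruthEvent("location-1", "location", 2.0, 3.0),
        GroundTruthEvent("location-2", "location", 3.0, 4.0),
    ]
    return Scenario("two-location-goal", obs, truth)


def office_day_fixture() -> Scenario:
    """A day containing a meeting, then an evening with a punctate dinner.

    Seven distinct change-point timestamps (1..7); dinner's onset and offset
    coincide at t=5, making it punctate.
    """
    obs = [
        Observation(1.0, "goal", "day", "onset"),
        Observation(2.0, "goal", "meeting", "onset"),
        Observation(3.0, "goal", "meeting", "offset"),
        Observation(4.0, "goal", "evening", "onset"),
        Observation(5.0, "goal", "dinner", "onset"),
        Observation(5.0, "goal", "dinner", "offset"),
        Observation(6.0, "goal", "evening", "offset"),
        Observation(7.0, "goal", "day", "offset"),
    ]
    truth = [
        GroundTruthEvent("day", "goal", 1.0, 7.0),
        GroundTruthEvent("meeting", "goal", 2.0, 3.0),
        GroundTruthEvent("evening", "goal", 4.0, 6.0),
        GroundTruthEvent("dinner", "goal", 5.0, 5.0),
    ]
    return Scenario("office-day", obs, truth)


FIXTURES = {
    "patrol": patrol_fixture,
    "two-location-goal": two_location_goal_fixture,
    "office-day": office_day_fixture,
}


# ---------------------------------------------------------------------------
# Seeded random scenarios
# ---------------------------------------------------------------------------

def _disambiguated_labels(intervals_per_entity: dict[tuple[str, str], list[tuple[float, Optional[float]]]]
                          ) -> list[GroundTruthEvent]:
    """Label each interval; repeated activations of one entity get @k suffixes."""
    truth = []
    for (channel, entity), intervals in intervals_per_entity.items():
        if len(intervals) == 1:
            start, end = intervals[0]
            truth.append(GroundTruthEvent(entity, channel, start, end))
        else:
            for k, (start, end) in enumerate(intervals, start=1):
                truth.append(GroundTruthEvent(f"{entity}@{k}", channel, start, end))
    truth.sort(key=lambda e: (e.start, e.channel, e.label))
    return truth


def random_scenario(seed: int,
                    n_channels_active: int = 2,
                    duration: float = 50.0,
                    change_rate_per_channel: float = 0.2) -> Scenario:
    """Generate a seeded stream with Poisson-like change-point placement.

    Each active channel receives change points at the given rate; entities on
    multi-valued channels alternate onset/offset, while the location channel
    hops between locations (each hop implicitly ending the previous stay).
    The same seed always yields the identical scenario.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if change_rate_per_channel <= 0:
        raise ValueError(f"change_rate_per_channel must be positive, got {change_rate_per_channel}")
    if change_rate_per_channel * duration < 1:
        raise ValueError("change_rate_per_channel x duration must be >= 1")
    if not 1 <= n_channels_active <= len(CHANNELS):
        raise ValueError(f"n_channels_active must be in 1..{len(CHANNELS)}")

    rng = np.random.default_rng(seed)
    channels = CHANNELS[:n_channels_active]
    observations: list[Observation] = []
    intervals: dict[tuple[str, str], list[tuple[float, Optional[float]]]] = {}

    for channel in channels:
        n_pts = int(rng.poisson(change_rate_per_channel * duration))
        times = np.sort(rng.uniform(0.0, duration, size=n_pts))
        pool = [f"{channel}-{i}" for i in range(1, 4)]
        if channel == "location":
            current: Optional[str] = None
            current_start = 0.0
            for t in times:
                t = float(t)
                choices = [e for e in pool if e != current]
                entity = choices[int(rng.integers(len(choices)))]
                if current is not None:
                    intervals.setdefault((channel, current), []).append((current_start, t))
                observations.append(Observation(t, channel, entity, "onset"))
                current, current_start = entity, t
            if current is not None:
                intervals.setdefault((channel, current), []).append((current_start, None))
        else:
            active: dict[str, float] = {}
            for t in times:
                t = float(t)
                inactive = [e for e in pool if e not in active]
                if active and (not inactive or rng.random() < 0.5):
                    entity = sorted(active)[int(rng.integers(len(active)))]
                    intervals.setdefault((channel, entity), []).append((active.pop(entity), t))
                    observations.append(Observation(t, channel, entity, "offset"))
                else:
                    entity = inactive[int(rng.integers(len(inactive)))]
                    active[entity] = t
                    observations.append(Observation(t, channel, entity, "onset"))
            for entity, start in sorted(active.items()):
                intervals.setdefault((channel, entity), []).append((start, None))

    if not observations:  # precondition floor: never emit an empty stream
        t = float(duration / 2)
        observations.append(Observation(t, channels[0], f"{channels[0]}-1", "onset"))
        intervals[(channels[0], f"{channels[0]}-1")] = [(t, None)]

    observations.sort(key=lambda o: o.time)
    return Scenario(f"random-{seed}", observations, _disambiguated_labels(intervals))


# ---------------------------------------------------------------------------
# Stream I/O (JSONL dialect) and YAML parameter files
# ---------------------------------------------------------------------------

def observation_to_json(obs: Observation) -> str:
    return json.dumps({"t": obs.time, "ch": obs.channel, "entity": obs.entity, "pol": obs.polarity})


def write_stream(observations: Iterable[Observation], path) -> None:
    with open(path, "w") as fh:
        for obs in observations:
            fh.write(observation_to_json(obs) + "\n")


def read_stream(path) -> list[Observation]:
    """Read a JSONL observation stream; parse errors name the offending line."""
    observations = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                observations.append(
                    Observation(float(rec["t"]), rec["ch"], rec["entity"], rec["pol"])
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise StreamParseError(line_no, str(exc)) from exc
    return observations


def scenario_from_yaml(path) -> Scenario:
    """Build a random scenario from a YAML file of random_scenario parameters."""
    with open(path) as fh:
        params = yaml.safe_load(fh) or {}
    if not isinstance(params, dict):
        raise ValueError("scenario config must be a mapping of random_scenario parameters")
    allowed = {"seed", "n_channels_active", "duration", "change_rate_per_channel"}
    unknown = set(params) - allowed
    if unknown:
        raise ValueError(f"unknown scenario config keys: {sorted(unknown)}")
    return random_scenario(**params)
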