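"""Online encoding of episodic markers from an observation stream.

Segmentation is automatic and strictly forward: every instant at which at
least one change is detected yields exactly one marker, all simultaneous
changes collapse into that marker, and markers are chained to their
predecessor.  Markers encode the changes symbolically plus the goal active
at encoding time; their initial encoding strength grows with the number of
changes encoded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from eventmodels.scenario import MULTI_VALUED_CHANNELS, Observation, Scenario

logger = logging.getLogger(__name__)


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class Change:
    """One detected change: an entity appearing on or leaving a channel.

    ``prior_content`` records what the entity replaces (e.g. the previous
    location for a location onset); it is None when nothing is replaced.
    """

    channel: str
    entity: str
    polarity: str
    prior_content: Optional[str] = None

    def __post_init__(self) -> None:
        if self.prior_content is not None and self.prior_content == self.entity:
            raise ValueError("prior_content must differ from entity")


@dataclass(frozen=True)
class EpisodicMarker:
    """A punctate episodic chunk encoding all changes detected at one instant."""

    id: str
    index: int
    time: float
    changes: frozenset[Change]
    prior_marker: Optional[str]
    goal_context: Optional[str]
    encoding_strength: float

    def __post_init__(self) -> None:
        if not self.changes:
            raise ValueError("a marker must encode at least one change")

    @property
    def channels(self) -> frozenset[str]:
        return frozenset(c.channel for c in self.changes)


class WorldState:
    """Per-channel sets of currently active entities.

    Location is single-valued (a new location displaces the old one); the
    goal channel additionally keeps a stack so the most recently adopted
    goal provides the current context.
    """

    def __init__(self) -> None:
        self.active: dict[str, set[str]] = {ch: set() for ch in ("goal", "location", "person", "object")}
        self.goal_stack: list[str] = []

    @property
    def current_location(self) -> Optional[str]:
        return next(iter(self.active["location"]), None)

    @property
    def current_goal(self) -> Optional[str]:
        return self.goal_stack[-1] if self.goal_stack else None


def detect_changes(state: WorldState, obs: Observation, strict: bool = False) -> set[Change]:
    """Return the change set implied by ``obs`` and update the world state.

    Re-observing an already-active entity yields no change.  A location onset
    carries the displaced location as prior content.  An offset of an entity
    that is not active is a contract violation in strict mode; in tolerant
    mode it is logged and recorded with no prior content.
    """
    changes: set[Change] = set()
    active = state.active[obs.channel]
    if obs.polarity == "onset":
        if obs.entity in active:
            return changes
        prior = None
        if obs.channel not in MULTI_VALUED_CHANNELS:  # location displaces
            prior = state.current_location
            active.clear()
        active.add(obs.entity)
        if obs.channel == "goal":
            state.goal_stack.append(obs.entity)
        changes.add(Change(obs.channel, obs.entity, "onset", prior))
    else:
        if obs.entity not in active:
            msg = f"offset of inactive entity {obs.entity!r} on channel {obs.channel!r} at t={obs.time}"
            if strict:
                raise SegmentationError(msg)
            logger.warning("%s (tolerated)", msg)
            changes.add(Change(obs.channel, obs.entity, "offset", None))
            return changes
        active.discard(obs.entity)
        if obs.channel == "goal" and obs.entity in state.goal_stack:
            state.goal_stack.remove(obs.entity)
        changes.add(Change(obs.channel, obs.entity, "offset", None))
    return changes


def encode_marker(changes: set[Change],
                  time: float,
                  prior_marker: Optional[str],
                  active_goal: Optional[str],
                  index: int = 1,
                  beta: float = 1.0) -> EpisodicMarker:
    """Encode one marker for all changes detected at ``time``."""
    if not changes:
        raise SegmentationError("cannot encode a marker with no changes")
    return EpisodicMarker(
        id=f"Ep-{index}",
        index=index,
        time=time,
        changes=frozenset(changes),
        prior_marker=prior_marker,
        goal_context=active_goal,
        encoding_strength=beta * len(changes),
    )


def segment_stream(source: Union[Scenario, Iterable[Observation]],
                   strict: bool = False,
                   beta: float = 1.0) -> list[EpisodicMarker]:
    """Segment an observation stream into a chained sequence of markers.

    One marker per timestamp with >=1 detected change; simultaneous changes
    collapse.  A marker's goal context is the goal active at that instant;
    a marker encoding a goal offset carries the ending goal as its context.
    """
    observations = list(source.observations if isinstance(source, Scenario) else source)
    times = [o.time for o in observations]
    if any(b < a for a, b in zip(times, times[1:])):
        raise SegmentationError("observations must be sorted by time")

    state = WorldState()
    markers: list[EpisodicMarker] = []
    i = 0
    while i < len(observations):
        t = observations[i].time
        changes: set[Change] = set()
        while i < len(observations) and observations[i].time == t:
            changes |= detect_changes(state, observations[i], strict=strict)
            i += 1
        if not changes:
            continue
        ended_goals = [c.entity for c in changes if c.channel == "goal" and c.polarity == "offset"]
        context = state.current_goal
        if context is None and ended_goals:
            context = ended_goals[0]
        elif ended_goals and state.current_goal not in ended_goals:
            # a nested goal ended while an outer one persists: the ending
            # goal is still the context of its own boundary marker
            context = ended_goals[0]
        marker = encode_marker(changes, t, markers[-1].id if markers else None,
                               context, index=len(markers) + 1, beta=beta)
        logger.debug("encoded %s at t=%s: %d change(s), context=%s",
                     marker.id, t, len(changes), context)
        markers.append(marker)
    return markers


def markers_to_jsonl(markers: Iterable[EpisodicMarker]) -> str:
    import json

    lines = []
    for m in markers:
        lines.append(json.dumps({
            "id": m.id,
            "t": m.time,
            "changes": sorted(
                ({"ch": c.channel, "entity": c.entity, "pol": c.polarity, "prior": c.prior_content}
                 for c in m.changes),
                key=lambda d: (d["ch"], d["entity"], d["pol"]),
            ),
            "prior": m.prior_marker,
            "goal_context": m.goal_context,
            "strength": m.encoding_strength,
        }))
    return "\n".join(lines) + ("\n" if lines else "")


def markers_from_jsonl(text: str) -> list[EpisodicMarker]:
    import json

    markers = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            rec = json.loads(line)
            changes = frozenset(
                Change(c["ch"], c["entity"], c["pol"], c.get("prior")) for c in rec["changes"]
            )
            markers.append(EpisodicMarker(
                id=rec["id"], index=int(rec["id"].split("-")[1]), time=float(rec["t"]),
                changes=changes, prior_marker=rec.get("prior"),
                goal_context=rec.get("goal_context"),
                encoding_strength=float(rec.get("strength", len(changes))),
            ))
        except (json.JSONDecodeError, KeyError, IndexError, TypeError, ValueError) as exc:
            raise SegmentationError(f"marker line {line_no}: {exc}") from exc
    return markers
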