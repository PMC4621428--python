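"""Retrospective construction of event models from episodic markers.

A sweep over retrieved markers opens a provisional event at each onset and
closes it at the first compatible marker (same channel and entity); a single
marker may close one event and open another, as with location transitions.
Veridical mode commits every marker pair; prioritized mode commits an event
only if it is of the highest-priority channel present or falls within the
bounds of a committed higher-priority event.  Committed events are arranged
on an ordinal timeline with no metric spacing and nested into a bounded
partonomy by interval containment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from eventmodels.scenario import MULTI_VALUED_CHANNELS
from eventmodels.segmentation import EpisodicMarker

logger = logging.getLogger(__name__)

DEFAULT_PRIORITY: tuple[str, ...] = ("goal", "location", "person", "object")


class ModelError(ValueError):
    pass


@dataclass
class Event:
    """A durational or punctate unit bounded by a start and an end marker.

    ``end_time``/``end_marker`` of None mark an open (ongoing) event, which
    participates in relations as a right-unbounded interval.  Premise-derived
    events carry no markers and no trigger channel.
    """

    label: str
    trigger_channel: Optional[str]
    entity: Optional[str]
    start_marker: Optional[str]
    end_marker: Optional[str]
    start_time: float
    end_time: Optional[float]
    punctate: bool = False
    parent: Optional[str] = None
    children: list[str] = field(default_factory=list)

    @property
    def open(self) -> bool:
        return self.end_time is None

    def layout_end(self) -> float:
        return math.inf if self.end_time is None else self.end_time


@dataclass
class EventModel:
    """An iconic, ordinal-position arrangement of events (the partonomy)."""

    events: list[Event] = field(default_factory=list)
    positions: dict[float, int] = field(default_factory=dict)
    mode: str = "veridical"
    priority_order: tuple[str, ...] = DEFAULT_PRIORITY
    max_depth: int = 4

    def by_label(self, label: str) -> Event:
        for e in self.events:
            if e.label == label:
                return e
        raise KeyError(f"unknown event label {label!r}")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    def ordinal_extent(self, label: str) -> tuple[int, float, bool]:
        """(start ordinal, end ordinal or +inf when open, punctate flag)."""
        e = self.by_label(label)
        start = self.positions[e.start_time]
        end = math.inf if e.end_time is None else self.positions[e.end_time]
        return start, end, e.punctate

    def depth(self, label: str) -> int:
        d, e = 1, self.by_label(label)
        while e.parent is not None:
            d, e = d + 1, self.by_label(e.parent)
        return d

    def top_level(self) -> list[Event]:
        return [e for e in self.events if e.parent is None]

    @property
    def n_ordinals(self) -> int:
        return len(self.positions)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "priority_order": list(self.priority_order),
            "max_depth": self.max_depth,
            "positions": sorted(self.positions.items()),
            "events": [
                {
                    "label": e.label,
                    "channel": e.trigger_channel,
                    "entity": e.entity,
                    "start_marker": e.start_marker,
                    "end_marker": e.end_marker,
                    "start": e.start_time,
                    "end": e.end_time,
                    "punctate": e.punctate,
                    "parent": e.parent,
                    "children": list(e.children),
                }
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventModel":
        events = [
            Event(r["label"], r["channel"], r["entity"], r["start_marker"], r["end_marker"],
                  float(r["start"]), None if r["end"] is None else float(r["end"]),
                  bool(r["punctate"]), r.get("parent"), list(r.get("children", [])))
            for r in d["events"]
        ]
        positions = {float(t): int(o) for t, o in d["positions"]}
        return cls(events, positions, d.get("mode", "veridical"),
                   tuple(d.get("priority_order", DEFAULT_PRIORITY)), int(d.get("max_depth", 4)))


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _channel_rank(channel: Optional[str], priority_order: Sequence[str]) -> int:
    if channel in priority_order:
        return priority_order.index(channel)
    return len(priority_order)


def _contains(outer: Event, inner: Event) -> bool:
    """Inclusive interval containment (open end = +inf)."""
    return outer.start_time <= inner.start_time and inner.layout_end() <= outer.layout_end()


def _properly_contains(outer: Event, inner: Event) -> bool:
    return _contains(outer, inner) and (
        outer.start_time < inner.start_time or inner.layout_end() < outer.layout_end()
    )


def _sweep(markers: Sequence[EpisodicMarker]) -> list[Event]:
    """Open/close provisional events across the marker sequence."""
    provisional: dict[tuple[str, str], tuple[str, float]] = {}
    events: list[Event] = []

    def close(key: tuple[str, str], marker: EpisodicMarker) -> None:
        start_marker, start_time = provisional.pop(key)
        channel, entity = key
        events.append(Event(
            label=entity, trigger_channel=channel, entity=entity,
            start_marker=start_marker, end_marker=marker.id,
            start_time=start_time, end_time=marker.time,
            punctate=start_marker == marker.id,
        ))

    for m in markers:
        onsets = sorted((c for c in m.changes if c.polarity == "onset"),
                        key=lambda c: (c.channel, c.entity))
        offsets = sorted((c for c in m.changes if c.polarity == "offset"),
                         key=lambda c: (c.channel, c.entity))
        deferred = []
        for c in offsets:
            if (c.channel, c.entity) in provisional:
                close((c.channel, c.entity), m)
            else:
                deferred.append(c)
        for c in onsets:  # location transitions close the displaced stay
            if (c.channel not in MULTI_VALUED_CHANNELS and c.prior_content is not None
                    and (c.channel, c.prior_content) in provisional):
                close((c.channel, c.prior_content), m)
        for c in onsets:
            provisional.setdefault((c.channel, c.entity), (m.id, m.time))
        for c in deferred:  # entity opened and closed by this very marker: punctate
            if (c.channel, c.entity) in provisional:
                close((c.channel, c.entity), m)
            else:
                logger.warning("dangling offset of %s/%s at %s ignored in reconstruction",
                               c.channel, c.entity, m.id)

    for (channel, entity), (start_marker, start_time) in provisional.items():
        events.append(Event(label=entity, trigger_channel=channel, entity=entity,
                            start_marker=start_marker, end_marker=None,
                            start_time=start_time, end_time=None))
    return events


def _disambiguate_labels(events: list[Event]) -> None:
    counts: dict[tuple[Optional[str], Optional[str]], int] = {}
    for e in events:
        counts[(e.trigger_channel, e.entity)] = counts.get((e.trigger_channel, e.entity), 0) + 1
    seen: dict[tuple[Optional[str], Optional[str]], int] = {}
    for e in events:
        key = (e.trigger_channel, e.entity)
        if counts[key] > 1:
            seen[key] = seen.get(key, 0) + 1
            e.label = f"{e.entity}@{seen[key]}"


def _prioritized_subset(events: list[Event], priority_order: Sequence[str]) -> list[Event]:
    if not events:
        return []
    ranks = {e.label: _channel_rank(e.trigger_channel, priority_order) for e in events}
    top_rank = min(ranks.values())
    kept: list[Event] = []
    for e in sorted(events, key=lambda e: ranks[e.label]):
        if ranks[e.label] == top_rank:
            kept.append(e)
        elif any(ranks[k.label] < ranks[e.label] and _contains(k, e) for k in kept):
            kept.append(e)
    order = {id(e): i for i, e in enumerate(events)}
    kept.sort(key=lambda e: order[id(e)])
    return kept


def _assign_partonomy(events: list[Event], priority_order: Sequence[str], max_depth: int) -> None:
    """Nest events by containment (deepest container wins) within the depth bound."""
    by_label = {e.label: e for e in events}
    for e in events:
        e.parent, e.children = None, []
    for e in events:
        rank_e = _channel_rank(e.trigger_channel, priority_order)
        cands = [c for c in events
                 if c is not e and _properly_contains(c, e)
                 and _channel_rank(c.trigger_channel, priority_order) <= rank_e]
        if not cands:
            continue
        def depth_key(c: Event) -> tuple:
            inside = sum(1 for other in cands if other is not c and _properly_contains(other, c))
            return (-inside, c.start_time, c.label)
        e.parent = min(cands, key=depth_key).label

    def depth(e: Event) -> int:
        d = 1
        while e.parent is not None:
            d, e = d + 1, by_label[e.parent]
        return d

    # flatten chains that exceed the bound: reparent to the deepest allowed ancestor
    if max_depth == 1:
        for e in events:
            e.parent = None
    else:
        for e in sorted(events, key=depth):
            if depth(e) > max_depth:
                anc = by_label[e.parent]
                while depth(anc) > max_depth - 1:
                    anc = by_label[anc.parent]
                e.parent = anc.label

    for e in events:
        e.children = [c.label for c in sorted(events, key=lambda c: (c.start_time, c.label))
                      if c.parent == e.label]


def construct_model(markers: Sequence[EpisodicMarker],
                    mode: str = "veridical",
                    priority_order: Sequence[str] = DEFAULT_PRIORITY,
                    max_depth: int = 4) -> EventModel:
    """Sweep markers earliest-to-latest into a committed event model.

    In veridical mode events and marker pairs map one-to-one; in prioritized
    mode lower-priority events are committed only within the bounds of
    committed higher-priority events.  Unclosed provisional events are
    committed as open.
    """
    if mode not in ("veridical", "prioritized"):
        raise ModelError(f"unknown mode {mode!r}")
    if max_depth < 1:
        raise ModelError("max_depth must be >= 1")
    markers = list(markers)
    if any(b.time < a.time for a, b in zip(markers, markers[1:])):
        raise ModelError("markers must be time-ordered")

    events = _sweep(markers)
    events.sort(key=lambda e: (e.start_time, _channel_rank(e.trigger_channel, priority_order),
                               e.layout_end(), e.entity or ""))
    _disambiguate_labels(events)
    if mode == "prioritized":
        events = _prioritized_subset(events, priority_order)
    _assign_partonomy(events, priority_order, max_depth)

    boundaries = sorted({e.start_time for e in events}
                        | {e.end_time for e in events if e.end_time is not None})
    positions = {t: i + 1 for i, t in enumerate(boundaries)}
    for e in events:
        logger.info("committed %s event %r [%s, %s]%s", mode, e.label, e.start_time,
                    "open" if e.end_time is None else e.end_time,
                    f" within {e.parent!r}" if e.parent else "")
    return EventModel(events, positions, mode, tuple(priority_order), max_depth)


def positions_of(model: EventModel) -> dict[tuple[str, str], int]:
    """Map each event boundary (label, 'start'|'end') to its ordinal."""
    out: dict[tuple[str, str], int] = {}
    for e in model.events:
        out[(e.label, "start")] = model.positions[e.start_time]
        if e.end_time is not None:
            out[(e.label, "end")] = model.positions[e.end_time]
    return out


# ---------------------------------------------------------------------------
# ASCII rendering and parsing
# ---------------------------------------------------------------------------

OPEN_SUFFIX = "..."


def _column_width(model: EventModel) -> int:
    longest = max((len(e.label) for e in model.events), default=1)
    return longest + 4


def render(model: EventModel) -> str:
    """One line per non-overlapping group of events, ordinal ruler at bottom.

    Durational events are bracketed across their extent, punctate events are
    bare tokens, open events trail '...'.  parse_diagram() recovers the
    ordinal structure exactly.
    """
    if not model.events:
        return "(empty model)\n"
    w = _column_width(model)
    k = model.n_ordinals

    def extent(e: Event) -> tuple[int, int]:
        s, end, _ = model.ordinal_extent(e.label)
        return s, k if end is math.inf else int(end)

    ordered = sorted(model.events,
                     key=lambda e: (model.depth(e.label), extent(e)[0], extent(e)[1], e.label))
    lines: list[dict] = []  # {"depth": int, "spans": [(s,e)], "buf": list[str]}
    placements: list[tuple[dict, Event]] = []
    for e in ordered:
        s, end = extent(e)
        d = model.depth(e.label)
        target = None
        for line in lines:
            if line["depth"] != d:
                continue
            if all(end < a or b < s for a, b in line["spans"]):
                target = line
                break
        if target is None:
            target = {"depth": d, "spans": [], "buf": [" "] * (k * w + w)}
            lines.append(target)
        target["spans"].append((s, end))
        placements.append((target, e))

    for line, e in placements:
        s, end = extent(e)
        buf = line["buf"]
        col = (s - 1) * w
        if e.punctate:
            text = e.label
        else:
            text = "[" + e.label + (OPEN_SUFFIX if e.open else "")
            if not e.open:
                buf[(end - 1) * w] = "]"
        for i, ch in enumerate(text):
            buf[col + i] = ch

    ruler = [" "] * (k * w)
    for i in range(k):
        for j, ch in enumerate(str(i + 1)):
            ruler[i * w + j] = ch

    body = ["".join(line["buf"]).rstrip() for line in lines]
    return "\n".join(body + ["".join(ruler).rstrip()]) + "\n"


def parse_diagram(text: str) -> list[tuple[str, int, Optional[int], bool]]:
    """Recover (label, start ordinal, end ordinal or None, punctate) rows."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[-1].startswith("(empty"):
        return []
    ruler = lines[-1]
    cols = []
    i = 0
    while i < len(ruler):
        if ruler[i] != " ":
            j = i
            while j < len(ruler) and ruler[j] != " ":
                j += 1
            cols.append(i)
            i = j
        else:
            i += 1
    w = cols[1] - cols[0] if len(cols) > 1 else len(ruler) + 1

    rows: list[tuple[str, int, Optional[int], bool]] = []
    for line in lines[:-1]:
        i = 0
        while i < len(line):
            ch = line[i]
            if ch == " ":
                i += 1
            elif ch == "[":
                start = i // w + 1
                j = i + 1
                label_chars = []
                end: Optional[int] = None
                while j < len(line):
                    if line[j] == "]":
                        end = j // w + 1
                        j += 1
                        break
                    label_chars.append(line[j])
                    j += 1
                label = "".join(label_chars).strip()
                if label.endswith(OPEN_SUFFIX):
                    label, end = label[: -len(OPEN_SUFFIX)], None
                rows.append((label, start, end, False))
                i = j
            else:
                j = i
                while j < len(line) and line[j] != " ":
                    j += 1
                rows.append((line[i:j], i // w + 1, i // w + 1, True))
                i = j
    return rows


def model_signature(model: EventModel) -> frozenset:
    """Ordinal structure of a model, for round-trip and equality checks."""
    sig = set()
    for e in model.events:
        s, end, punct = model.ordinal_extent(e.label)
        sig.add((e.label, s, None if end is math.inf else int(end), punct))
    return frozenset(sig)
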