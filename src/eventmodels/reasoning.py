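"""Mental-model temporal inference.

Premises ("A before B", "A while B", ...) are turned into ordinal event
models by enumerating the arrangements of event boundaries consistent with
all premises; the first (initial) model follows the premises' mention order.
Queries scan each model's ordinals and classify a relation as necessary
(holds in every model), impossible (holds in none), or merely possible.
Models can also be revised counterfactually by repositioning an event.

Distinct events occupy distinct ordinal positions unless a "when" premise
forces co-position; this keeps e.g. the classic two-premise / two-model
problems at exactly two alternatives.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence, Union

from eventmodels.event_model import Event, EventModel, ModelError, _assign_partonomy

RELATIONS = ("before", "after", "while", "when", "during")

INCONSISTENT = "inconsistent-premises"


@dataclass(frozen=True)
class TemporalAssertion:
    """A relation between two named events, with optional aspect hints."""

    subject: str
    relation: str
    object: str
    subject_durational: Optional[bool] = None
    object_durational: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}; expected one of {RELATIONS}")

    def normalized(self) -> "TemporalAssertion":
        """Canonical direction: after(a, b) becomes before(b, a)."""
        if self.relation == "after":
            return TemporalAssertion(self.object, "before", self.subject,
                                     self.object_durational, self.subject_durational)
        return self


def parse_assertion(text: str) -> TemporalAssertion:
    """Parse '<label> (before|after|while|when|during) <label>'."""
    parts = text.split()
    if len(parts) != 3:
        raise ValueError(f"cannot parse assertion {text!r}: expected '<label> <relation> <label>'")
    return TemporalAssertion(parts[0], parts[1], parts[2])


@dataclass
class Verdict:
    """Modal status of an assertion across the enumerated models."""

    status: str
    witness_models: list[EventModel] = field(default_factory=list)
    model_count: int = 0
    bounded: bool = False  # enumeration hit max_models: necessity is up-to-bound


@dataclass
class ModelSet:
    """The models consistent with a premise set, initial model first."""

    models: list[EventModel]
    total_count: int
    inconsistent: bool = False
    truncated: bool = False

    def __iter__(self):
        return iter(self.models)

    def __len__(self):
        return len(self.models)


# ---------------------------------------------------------------------------
# Relation semantics over ordinal extents
# ---------------------------------------------------------------------------

def relation_holds(relation: str,
                   a: tuple[int, float, bool],
                   b: tuple[int, float, bool],
                   weak_before: bool = False) -> bool:
    """Evaluate a relation between two (start, end-or-inf, punctate) extents."""
    sa, ea, _ = a
    sb, eb, _ = b
    if relation == "before":
        return ea <= sb if weak_before else ea < sb
    if relation == "after":
        return relation_holds("before", b, a, weak_before)
    if relation == "when":
        return sa == sb and ea == eb
    if relation == "while":  # punctate-in-durational is a special case of overlap
        return max(sa, sb) <= min(ea, eb)
    if relation == "during":
        return sb <= sa and ea <= eb and (sb < sa or ea < eb)
    raise ValueError(f"unknown relation {relation!r}")


def assertion_holds(model: EventModel, assertion: TemporalAssertion,
                    weak_before: bool = False) -> bool:
    a = assertion.normalized()
    return relation_holds(a.relation, model.ordinal_extent(a.subject),
                          model.ordinal_extent(a.object), weak_before)


# ---------------------------------------------------------------------------
# Premise-based model building
# ---------------------------------------------------------------------------

def _mention_order(premises: Sequence[TemporalAssertion],
                   extra: Sequence[str] = ()) -> list[str]:
    labels: list[str] = []
    for p in premises:
        for lbl in (p.subject, p.object):
            if lbl not in labels:
                labels.append(lbl)
    for lbl in extra:
        if lbl not in labels:
            labels.append(lbl)
    return labels


def _infer_aspects(premises: Sequence[TemporalAssertion], labels: Sequence[str]) -> dict[str, bool]:
    """durational flag per label: hints win; otherwise objects of during/while
    are durational and everything else defaults to punctate."""
    durational = {lbl: False for lbl in labels}
    for p in premises:
        p = p.normalized()
        if p.relation in ("during", "while"):
            durational[p.object] = True
    for p in premises:
        if p.subject_durational is not None:
            durational[p.subject] = p.subject_durational
        if p.object_durational is not None:
            durational[p.object] = p.object_durational
    return durational


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _boundary_variables(labels: Sequence[str],
                        durational: dict[str, bool],
                        premises: Sequence[TemporalAssertion]):
    """Map each event to start/end boundary variables, merging via 'when'."""
    variables: dict[str, tuple[str, str]] = {}
    for lbl in labels:
        if durational[lbl]:
            variables[lbl] = (f"{lbl}.s", f"{lbl}.e")
        else:
            variables[lbl] = (f"{lbl}.s", f"{lbl}.s")
    uf = _UnionFind([v for pair in variables.values() for v in pair])
    for p in premises:
        if p.normalized().relation == "when":
            a, b = p.subject, p.object
            uf.union(variables[a][0], variables[b][0])
            uf.union(variables[a][1], variables[b][1])
    return variables, uf


def _enumerate_arrangements(labels, variables, uf, durational):
    """Yield extent maps {label: (start, end, punctate)} for every strict
    order of the merged boundary variables."""
    reps = sorted({uf.find(v) for pair in variables.values() for v in pair})
    for perm in permutations(reps):
        pos = {rep: i + 1 for i, rep in enumerate(perm)}
        extents = {}
        ok = True
        for lbl in labels:
            s = pos[uf.find(variables[lbl][0])]
            e = pos[uf.find(variables[lbl][1])]
            if durational[lbl] and not s < e:
                ok = False
                break
            extents[lbl] = (s, float(e), not durational[lbl])
        if ok:
            yield extents


def _extents_to_model(extents: dict[str, tuple[int, float, bool]]) -> EventModel:
    events = []
    for lbl, (s, e, punct) in sorted(extents.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0])):
        events.append(Event(label=lbl, trigger_channel=None, entity=None,
                            start_marker=None, end_marker=None,
                            start_time=float(s), end_time=float(e), punctate=punct))
    _assign_partonomy(events, (), max_depth=4)
    boundaries = sorted({e.start_time for e in events} | {e.end_time for e in events})
    positions = {t: i + 1 for i, t in enumerate(boundaries)}
    return EventModel(events, positions, mode="veridical")


def build_models(premises: Sequence[TemporalAssertion],
                 max_models: int = 8,
                 weak_before: bool = False,
                 extra_labels: Sequence[str] = ()) -> ModelSet:
    """Enumerate the event models consistent with the premises.

    The first model is the deterministic initial model (events appear in
    premise mention order where the premises leave the order open); the rest
    enumerate all remaining distinct ordinal arrangements, up to
    ``max_models``.  Contradictory premises yield an empty, inconsistent set.
    """
    premises = [p.normalized() for p in premises]
    labels = _mention_order(premises, extra_labels)
    if not labels:
        raise ValueError("premises must reference at least one event")
    if len(labels) > 8:
        raise ModelError(f"refusing to enumerate models over {len(labels)} events")
    durational = _infer_aspects(premises, labels)
    variables, uf = _boundary_variables(labels, durational, premises)
    n_reps = len({uf.find(v) for pair in variables.values() for v in pair})
    if n_reps > 9:
        raise ModelError(f"refusing to enumerate arrangements of {n_reps} event boundaries")
    mention_rank = {lbl: i for i, lbl in enumerate(labels)}

    survivors = []
    for extents in _enumerate_arrangements(labels, variables, uf, durational):
        if all(relation_holds(p.relation, extents[p.subject], extents[p.object], weak_before)
               for p in premises):
            survivors.append(extents)

    def initial_key(extents):
        seq = sorted(extents, key=lambda lbl: (extents[lbl][0], extents[lbl][1], mention_rank[lbl]))
        return (tuple(mention_rank[lbl] for lbl in seq),
                tuple(sorted((lbl, ext) for lbl, ext in extents.items())))

    survivors.sort(key=initial_key)
    models = [_extents_to_model(x) for x in survivors[:max_models]]
    return ModelSet(models=models, total_count=len(survivors),
                    inconsistent=not survivors, truncated=len(survivors) > max_models)


# ---------------------------------------------------------------------------
# Query, revision, and the exhaustive oracle
# ---------------------------------------------------------------------------

ModelsLike = Union[ModelSet, Sequence[EventModel], EventModel]


def query(models: ModelsLike, assertion: TemporalAssertion,
          weak_before: bool = False, max_witnesses: int = 8) -> Verdict:
    """Scan each model for the assertion and aggregate the modal status."""
    if isinstance(models, EventModel):
        model_list, truncated, inconsistent = [models], False, False
    elif isinstance(models, ModelSet):
        model_list, truncated, inconsistent = models.models, models.truncated, models.inconsistent
    else:
        model_list, truncated, inconsistent = list(models), False, False

    if inconsistent:
        return Verdict(INCONSISTENT, [], model_count=0)
    if not model_list:
        return Verdict(INCONSISTENT, [], model_count=0)

    a = assertion.normalized()
    for lbl in (a.subject, a.object):
        if lbl not in model_list[0].labels:
            raise ValueError(f"unknown event label {lbl!r}")

    holding = [m for m in model_list if assertion_holds(m, a, weak_before)]
    if len(holding) == len(model_list):
        status = "necessary"
    elif not holding:
        status = "impossible"
    else:
        status = "possible"
    bounded = truncated and status in ("necessary", "impossible")
    witnesses = holding[:max_witnesses]
    return Verdict(status, witnesses, model_count=len(model_list), bounded=bounded)


def revise(model: EventModel, label: str,
           new_start: float, new_end: Optional[float] = None) -> EventModel:
    """Return a new model with one event repositioned; the original is untouched.

    All other events keep their positions; ordinals and the partonomy are
    recomputed for the new arrangement.
    """
    out = copy.deepcopy(model)
    event = out.by_label(label)
    if event.punctate:
        if new_end is not None and new_end != new_start:
            raise ModelError(f"{label!r} is punctate: start and end must coincide")
        new_end = new_start
    if new_end is not None and new_end < new_start:
        raise ModelError(f"invalid interval for {label!r}: start {new_start} > end {new_end}")
    if new_end is None and event.end_time is not None:
        new_end = new_start + (event.end_time - event.start_time)  # preserve extent
    event.start_time = float(new_start)
    event.end_time = None if new_end is None else float(new_end)
    _assign_partonomy(out.events, out.priority_order, out.max_depth)
    boundaries = sorted({e.start_time for e in out.events}
                        | {e.end_time for e in out.events if e.end_time is not None})
    out.positions = {t: i + 1 for i, t in enumerate(boundaries)}
    return out


def move_after(model: EventModel, label: str, other_label: str, gap: float = 1.0) -> EventModel:
    """Counterfactually move an event so it starts after another event ends."""
    moved = model.by_label(label)
    other = model.by_label(other_label)
    if other.end_time is None:
        raise ModelError(f"cannot place {label!r} after open event {other_label!r}")
    new_start = other.end_time + gap
    if moved.end_time is None:
        return revise(model, label, new_start, None)
    duration = moved.end_time - moved.start_time
    return revise(model, label, new_start, new_start + duration)


def brute_force_verdict(premises: Sequence[TemporalAssertion],
                        assertion: TemporalAssertion,
                        weak_before: bool = False) -> Verdict:
    """Reference oracle: exhaustively enumerate every strict arrangement of
    event boundaries on a minimal ordinal grid, filter by the premises, and
    evaluate the assertion in each survivor.

    Independent of build_models/query: enumeration and evaluation are done
    inline over raw integer positions.
    """
    premises = [p.normalized() for p in premises]
    assertion = assertion.normalized()
    labels = _mention_order(premises, extra=(assertion.subject, assertion.object))
    if len(labels) > 6:
        raise ValueError(f"brute force refuses problems over {len(labels)} events (got >6)")
    durational = _infer_aspects(premises, labels)

    # Boundary tokens with 'when'-forced co-positions (inline union-find).
    tokens = {}
    for lbl in labels:
        tokens[(lbl, "s")] = (lbl, "s")
        tokens[(lbl, "e")] = (lbl, "s") if not durational[lbl] else (lbl, "e")
    parent = {t: t for t in set(tokens.values())}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for p in premises:
        if p.relation == "when":
            for part in ("s", "e"):
                ra = find(tokens[(p.subject, part)])
                rb = find(tokens[(p.object, part)])
                if ra != rb:
                    parent[rb] = ra

    reps = sorted({find(t) for t in parent})
    rep_index = {r: i for i, r in enumerate(reps)}
    var_of = {lbl: (rep_index[find(tokens[(lbl, "s")])],
                    rep_index[find(tokens[(lbl, "e")])]) for lbl in labels}
    n_vars = len(reps)

    def holds(rel: str, ea: tuple[int, int], eb: tuple[int, int]) -> bool:
        (sa, en_a), (sb, en_b) = ea, eb
        if rel == "before":
            return en_a <= sb if weak_before else en_a < sb
        if rel == "when":
            return sa == sb and en_a == en_b
        if rel == "while":
            return max(sa, sb) <= min(en_a, en_b)
        if rel == "during":
            return sb <= sa and en_a <= en_b and (sb < sa or en_a < en_b)
        raise ValueError(rel)

    n_consistent = 0
    n_holding = 0
    witness_extents = []
    for perm in permutations(range(1, n_vars + 1)):
        ext = {}
        ok = True
        for lbl in labels:
            s, e = perm[var_of[lbl][0]], perm[var_of[lbl][1]]
            if durational[lbl] and not s < e:
                ok = False
                break
            ext[lbl] = (s, e)
        if not ok:
            continue
        if not all(holds(p.relation, ext[p.subject], ext[p.object]) for p in premises):
            continue
        n_consistent += 1
        if holds(assertion.relation, ext[assertion.subject], ext[assertion.object]):
            n_holding += 1
            if len(witness_extents) < 8:
                witness_extents.append(dict(ext))

    if n_consistent == 0:
        return Verdict(INCONSISTENT, [], model_count=0)
    if n_holding == n_consistent:
        status = "necessary"
    elif n_holding == 0:
        status = "impossible"
    else:
        status = "possible"
    witnesses = [
        _extents_to_model({lbl: (s, float(e), not durational[lbl]) for lbl, (s, e) in ext.items()})
        for ext in witness_extents
    ]
    return Verdict(status, witnesses, model_count=n_consistent)
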