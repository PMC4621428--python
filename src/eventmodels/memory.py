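"""Episodic store with activation decay, retrieval spikes, and spreading.

Markers enter the store highly active (more so the more changes they encode)
and fade with a base-level-learning law; retrieving a marker spikes its
activation and spreads a fraction of the spike to associated markers (those
sharing its goal context or tracking the same change channels).  With the
default threshold of -inf and an unbounded temporal limit, retrieval is
lossless, so reconstruction downstream is exact unless forgetting is opted
into.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from eventmodels.segmentation import EpisodicMarker


@dataclass
class MemoryConfig:
    decay_d: float = 0.5
    beta: float = 1.0
    spread_fraction: float = 0.5
    epsilon: float = 1e-3
    retrieval_threshold: float = float("-inf")
    temporal_limit: float = float("inf")

    def __post_init__(self) -> None:
        if self.decay_d <= 0:
            raise ValueError("decay_d must be positive")
        if not 0.0 <= self.spread_fraction <= 1.0:
            raise ValueError("spread_fraction must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.temporal_limit < 0:
            raise ValueError("temporal_limit must be non-negative")


@dataclass
class ActivationState:
    """Access history and parameters determining one marker's activation.

    Accesses are (time, weight) pairs: creation and retrieval spikes carry
    weight 1, spread from an associate's retrieval carries a fractional
    weight.
    """

    accesses: list[tuple[float, float]]
    strength_offset: float = 0.0
    decay: float = 0.5
    epsilon: float = 1e-3

    @property
    def creation_time(self) -> float:
        return self.accesses[0][0]

    def activation(self, now: float) -> float:
        """Base-level activation: offset + ln sum_j w_j (now - t_j)^-d."""
        if now < self.creation_time:
            raise ValueError(f"activation queried at t={now}, before creation at t={self.creation_time}")
        total = sum(w * max(now - t, self.epsilon) ** (-self.decay) for t, w in self.accesses)
        return self.strength_offset + math.log(total)

    def record_access(self, now: float, weight: float = 1.0) -> None:
        self.accesses.append((now, weight))


@dataclass(frozen=True)
class RetrievalCue:
    """Optional constraints a retrieved marker must satisfy."""

    goal_context: Optional[str] = None
    channel: Optional[str] = None
    time_window: Optional[tuple[float, float]] = None

    def matches(self, marker: EpisodicMarker) -> bool:
        if self.goal_context is not None and marker.goal_context != self.goal_context:
            return False
        if self.channel is not None and self.channel not in marker.channels:
            return False
        if self.time_window is not None:
            lo, hi = self.time_window
            if not lo <= marker.time <= hi:
                return False
        return True


class EpisodicStore:
    """Holds markers with their activation states; gates reconstruction."""

    def __init__(self, markers: Sequence[EpisodicMarker], config: Optional[MemoryConfig] = None):
        self.config = config or MemoryConfig()
        self.markers: list[EpisodicMarker] = sorted(markers, key=lambda m: m.index)
        self.states: dict[str, ActivationState] = {
            m.id: ActivationState(
                accesses=[(m.time, 1.0)],
                strength_offset=m.encoding_strength,
                decay=self.config.decay_d,
                epsilon=self.config.epsilon,
            )
            for m in self.markers
        }

    def activation(self, marker_id: str, now: float) -> float:
        return self.states[marker_id].activation(now)

    def _associates(self, marker: EpisodicMarker) -> list[EpisodicMarker]:
        out = []
        for other in self.markers:
            if other.id == marker.id:
                continue
            same_context = marker.goal_context is not None and other.goal_context == marker.goal_context
            shared_channel = bool(marker.channels & other.channels)
            if same_context or shared_channel:
                out.append(other)
        return out

    def retrieve(self,
                 cue: Optional[RetrievalCue] = None,
                 now: Optional[float] = None,
                 threshold: Optional[float] = None,
                 temporal_limit: Optional[float] = None) -> list[EpisodicMarker]:
        """Return cue-matching markers above threshold, in time order.

        Each retrieved marker's activation spikes (a fresh full-weight
        access) and one step of spread adds a fractional access to each of
        its associates.  Marker contents are never modified.
        """
        if not self.markers:
            return []
        if now is None:
            now = max(m.time for m in self.markers)
        if threshold is None:
            threshold = self.config.retrieval_threshold
        if temporal_limit is None:
            temporal_limit = self.config.temporal_limit
        cue = cue or RetrievalCue()

        retrieved = []
        for m in self.markers:
            if m.time > now or (now - m.time) > temporal_limit:
                continue
            if not cue.matches(m):
                continue
            if threshold != float("-inf") and self.states[m.id].activation(now) < threshold:
                continue
            retrieved.append(m)
        retrieved.sort(key=lambda m: (m.time, m.index))

        for m in retrieved:
            self.states[m.id].record_access(now, 1.0)
            if self.config.spread_fraction > 0:
                for assoc in self._associates(m):
                    if assoc.time <= now:  # cannot spread to not-yet-encoded markers
                        self.states[assoc.id].record_access(now, self.config.spread_fraction)
        return retrieved
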