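"""Spatial memory for inhibition of return, with feature binding.

Every saccade deposits (or refreshes) an entry holding the egocentric
gaze coordinate ``p`` that was fixated, the time of entry, the feature
vector acquired at fixation (the "what"/"where" binding) and the saliency
the stimulus had when it was saccaded to.

Entries decay linearly: the memory activation of an entry of age ``t`` is

    f_sm = 1 - t / t_max        for 0 <= t <= t_max,

and entries older than ``t_max`` are pruned.  Subtracting ``f_sm`` from
the bottom-up activation of a re-observed stimulus implements inhibition
of return: a just-visited location is fully suppressed and recovers its
original activation exactly at ``t_max``.

Because gaze coordinates are continuous, matching a stimulus against the
memory needs a spatial tolerance ``eps_match``; a re-saccade within the
tolerance refreshes the existing entry (restarting its decay) rather than
duplicating it, and an equidistant match resolves to the *older* entry so
that inhibition is maximally conservative.  The memory never reads wall
clock time — the attention loop owns the single simulated clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .oculomotor import GazeCoordinate, gaze_distance
from .vision import FeatureVector

__all__ = ["SpatialMemory", "SpatialMemoryEntry", "decay_activation"]


@dataclass
class SpatialMemoryEntry:
    """One previously saccaded location with its bound feature vector."""

    p: GazeCoordinate
    t_entry: float
    feature: FeatureVector
    s_at_entry: float


def decay_activation(entry: SpatialMemoryEntry, t_now: float, t_max: float) -> float:
    """Linear memory activation ``1 - age / t_max`` of an entry.

    Defined for ages in ``[0, t_max]``; older entries must be pruned
    before being evaluated.
    """
    age = t_now - entry.t_entry
    if age < 0:
        raise ValueError(f"entry lies in the future (age {age})")
    if age > t_max:
        raise ValueError(f"entry age {age} exceeds t_max {t_max}; prune first")
    return 1.0 - age / t_max


@dataclass
class SpatialMemory:
    """The set of previously saccaded gaze coordinates (IOR sources)."""

    t_max: float = 20.0
    eps_match: float = 0.02
    entries: list[SpatialMemoryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.t_max <= 0 or self.eps_match <= 0:
            raise ValueError("t_max and eps_match must be positive")

    def __len__(self) -> int:
        return len(self.entries)

    def add_or_refresh(
        self,
        p: GazeCoordinate,
        feature: FeatureVector,
        s: float,
        t_now: float,
    ) -> "SpatialMemory":
        """Record a saccade to ``p``: refresh a matching entry or append."""
        if any(t_now < e.t_entry for e in self.entries):
            raise ValueError("t_now precedes an existing entry time")
        entry = self.match(p)
        if entry is not None:
            entry.p = p
            entry.t_entry = t_now
            entry.feature = feature
            entry.s_at_entry = s
        else:
            self.entries.append(
                SpatialMemoryEntry(p=p, t_entry=t_now, feature=feature, s_at_entry=s)
            )
        return self

    def activation(self, entry: SpatialMemoryEntry, t_now: float) -> float:
        return decay_activation(entry, t_now, self.t_max)

    def prune(self, t_now: float) -> "SpatialMemory":
        """Drop every entry whose age exceeds ``t_max``."""
        self.entries = [e for e in self.entries if t_now - e.t_entry <= self.t_max]
        return self

    def match(self, p: GazeCoordinate) -> SpatialMemoryEntry | None:
        """The entry nearest ``p`` within ``eps_match``, or None.

        Ties on distance resolve to the older entry (deterministic and
        maximally conservative for inhibition).
        """
        best: SpatialMemoryEntry | None = None
        best_key: tuple[float, float] | None = None
        for entry in self.entries:
            d = gaze_distance(entry.p, p)
            if d >= self.eps_match:
                continue
            key = (d, entry.t_entry)
            if best_key is None or key < best_key:
                best, best_key = entry, key
        return best
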