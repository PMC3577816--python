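"""Priority map: convergence of salience, inhibition of return and task.

This is the model's analogue of the lateral intraparietal (LIP) priority
map.  Every control step, the currently visible stimuli and the spatial
memory are merged into one set of activation records in gaze space, and a
threshold function turns the continually modulated activations into motor
output: a saccade is triggered to the highest activation exceeding the
threshold ``theta``.

Task relevance is a 2x4 matrix ``M`` of excitation (E) and inhibition (H)
values per feature class.  Because a stimulus' class is a one-hot vector,
the vector-matrix product that derives its (E, H) collapses to a column
lookup.  Top-down modulation can only apply to locations that have been
saccaded to before — only fixation creates a feature binding — so
never-visited stimuli carry their raw bottom-up saliency.

Modulated activation of a previously visited stimulus of age ``t``:

    f = s * (1 + E - H) - (1 - t / t_max) * (1 - E + H),   floored at -1.

The exact algebraic combination of decay and task relevance is a design
choice of this package, fixed by the behavioural constraints the model
must satisfy rather than by a canonical formula; it

* reduces to plain IOR subtraction ``f = s - (1 - t/t_max)`` when E = H = 0,
* returns exactly to ``f = s`` at ``t = t_max`` in that neutral case,
* is monotone increasing in E and decreasing in H at every age,
* for E >> H starts high with a near-zero time gradient, while for H > E
  the gradient is steep and the initial value is negative.

The form is isolated in :func:`modulate` so alternatives can be swapped;
the constraint suite in the tests, not the formula, is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .memory import SpatialMemory, decay_activation
from .oculomotor import GazeCoordinate, pixel_to_gaze
from .vision import FeatureClass, RetinotopicStimulus, SaliencyWeights
from .world import CameraIntrinsics, CameraPose

__all__ = [
    "ActivationRecord",
    "AttentionParams",
    "RelevanceMatrix",
    "build_global",
    "compute_EH",
    "modulate",
    "select_record",
    "select_saccade",
]


@dataclass(frozen=True)
class RelevanceMatrix:
    """Task matrix M: excitation and inhibition per feature class.

    Row order is (RED, GREEN, BLUE, UNDEFINED); all entries are >= 0.
    """

    excitation: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    inhibition: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.excitation) != 4 or len(self.inhibition) != 4:
            raise ValueError("relevance matrix must be exactly 2x4")
        if any(v < 0 for v in (*self.excitation, *self.inhibition)):
            raise ValueError("relevance entries must be non-negative")

    @classmethod
    def for_classes(
        cls,
        excite: dict[FeatureClass, float] | None = None,
        inhibit: dict[FeatureClass, float] | None = None,
    ) -> "RelevanceMatrix":
        e = [0.0] * 4
        h = [0.0] * 4
        for c, v in (excite or {}).items():
            e[int(c)] = v
        for c, v in (inhibit or {}).items():
            h[int(c)] = v
        return cls(excitation=tuple(e), inhibition=tuple(h))

    def as_matrix(self) -> np.ndarray:
        return np.array([self.excitation, self.inhibition])


def compute_EH(cls: FeatureClass, m: RelevanceMatrix) -> tuple[float, float]:
    """(E, H) of a feature class: the one-hot vector-matrix product,
    collapsed to a column lookup."""
    return m.excitation[int(cls)], m.inhibition[int(cls)]


@dataclass(frozen=True)
class AttentionParams:
    """Parameters of the attention stage: threshold, IOR horizon, task."""

    theta: float = 0.1
    t_max: float = 20.0
    relevance: RelevanceMatrix = field(default_factory=RelevanceMatrix)
    weights: SaliencyWeights = field(default_factory=SaliencyWeights)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie strictly between 0 and 1")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


def modulate(
    s: float,
    age: float | None,
    t_max: float,
    e: float = 0.0,
    h: float = 0.0,
) -> float:
    """Activation of a stimulus after IOR decay and task modulation.

    ``age`` is the time since the location was last saccaded to, or None
    for a never-visited stimulus (which keeps its raw saliency: top-down
    modulation requires a stored feature binding).
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("saliency must lie in [0, 1]")
    if age is None:
        return s
    if age < 0:
        raise ValueError("age must be non-negative")
    if age > t_max:
        raise ValueError(f"age {age} exceeds t_max {t_max}; prune first")
    f = s * (1.0 + e - h) - (1.0 - age / t_max) * (1.0 - e + h)
    return max(f, -1.0)


@dataclass(frozen=True)
class ActivationRecord:
    """One candidate location on the priority map.

    ``source`` says where the record came from: a currently visible
    stimulus ("stimulus"), a memory entry with no visible counterpart
    ("memory"), or a visible stimulus matched to memory ("both").
    ``cls`` is None for never-visited stimuli (no feature binding, so no
    task modulation was applied).
    """

    p: GazeCoordinate
    f: float
    s: float
    cls: FeatureClass | None
    age: float | None
    source: str


def build_global(
    stimuli: list[RetinotopicStimulus],
    pose: CameraPose,
    memory: SpatialMemory | None,
    params: AttentionParams,
    t_now: float,
    intrinsics: CameraIntrinsics = CameraIntrinsics(),
) -> list[ActivationRecord]:
    """Merge visible stimuli and spatial memory into one gaze-space map.

    Each visible stimulus is converted to its egocentric coordinate and
    matched against the (pruned) memory: matched stimuli are modulated by
    IOR decay and the stored class's (E, H); unmatched ones keep their
    raw saliency.  Memory entries with no visible counterpart contribute
    purely inhibitory records ``f = -(1 - age/t_max)``, which can never
    exceed a positive threshold — they persist as IOR sources only.

    Record order is stimulus order (descending saliency) followed by the
    leftover memory entries, which makes threshold tie-breaking
    deterministic.  Pass ``memory=None`` to ablate spatial memory.
    """
    records: list[ActivationRecord] = []
    matched: set[int] = set()
    for st in stimuli:
        p = pixel_to_gaze(pose, st.x, st.y, intrinsics)
        entry = memory.match(p) if memory is not None else None
        if entry is not None:
            age = t_now - entry.t_entry
            e, h = compute_EH(entry.feature.cls, params.relevance)
            f = modulate(st.s, age, params.t_max, e, h)
            records.append(
                ActivationRecord(
                    p=p, f=f, s=st.s, cls=entry.feature.cls, age=age, source="both"
                )
            )
            matched.add(id(entry))
        else:
            records.append(
                ActivationRecord(p=p, f=st.s, s=st.s, cls=None, age=None, source="stimulus")
            )
    if memory is not None:
        for entry in memory.entries:
            if id(entry) in matched:
                continue
            age = t_now - entry.t_entry
            f = -decay_activation(entry, t_now, params.t_max)
            records.append(
                ActivationRecord(
                    p=entry.p,
                    f=f,
                    s=0.0,
                    cls=entry.feature.cls,
                    age=age,
                    source="memory",
                )
            )
    return records


def select_record(
    records: list[ActivationRecord], theta: float
) -> ActivationRecord | None:
    """The record with the highest activation strictly above ``theta``.

    Ties resolve to the earliest record in list order (which build_global
    makes deterministic); None if nothing exceeds the threshold.
    """
    best: ActivationRecord | None = None
    for rec in records:
        if rec.f > theta and (best is None or rec.f > best.f):
            best = rec
    return best


def select_saccade(
    records: list[ActivationRecord], theta: float
) -> GazeCoordinate | None:
    """Saccade target selected by the threshold function, or None."""
    rec = select_record(records, theta)
    return rec.p if rec is not None else None
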