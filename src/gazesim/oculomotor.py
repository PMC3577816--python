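"""Retinotopic-to-egocentric mapping and saccade execution.

A stimulus located at pixel ``(x, y)`` is converted to the *relative*
motor movement that would centre it, and then — by adding the camera's
absolute motor position — to an *egocentric* gaze-space coordinate ``p``:
the common currency of spatial information shared across viewpoints.

The mapping is the closed-form inverse of the renderer's pinhole
projection (a physical head would learn it from sampled fixations):

    d_verge = -atan((x - cx) / f)      d_tilt = -atan((y - cy) / f)

With the projection ``x = cx - f tan(az - verge)`` this gives
``verge + d_verge = az`` exactly, so the same static object yields the
same gaze coordinate from every pose that sees it (egocentric
invariance), up to stimulus-localisation error.

Saccades are instantaneous repositionings; the attention loop charges a
configurable saccade duration to the simulated clock and processes no
frames in between (saccadic suppression).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .world import CameraIntrinsics, CameraPose

__all__ = [
    "GazeCoordinate",
    "MotorDelta",
    "execute_saccade",
    "gaze_distance",
    "pixel_to_gaze",
    "retinotopic_to_delta",
    "to_egocentric",
]


@dataclass(frozen=True)
class MotorDelta:
    """Relative (verge, tilt) motor movement in radians."""

    d_verge: float
    d_tilt: float


@dataclass(frozen=True)
class GazeCoordinate:
    """Egocentric (verge, tilt) motor-space point ``p``, in radians."""

    verge: float
    tilt: float


def gaze_distance(a: GazeCoordinate, b: GazeCoordinate) -> float:
    """Euclidean distance between two gaze coordinates, in radians."""
    return math.hypot(a.verge - b.verge, a.tilt - b.tilt)


def retinotopic_to_delta(
    x: float, y: float, intrinsics: CameraIntrinsics = CameraIntrinsics()
) -> MotorDelta:
    """Relative motor movement that brings pixel ``(x, y)`` to the centre."""
    if not (0.0 <= x <= intrinsics.width and 0.0 <= y <= intrinsics.height):
        raise ValueError(
            f"pixel ({x}, {y}) outside image bounds "
            f"{intrinsics.width}x{intrinsics.height}"
        )
    return MotorDelta(
        d_verge=-math.atan((x - intrinsics.cx) / intrinsics.focal_px),
        d_tilt=-math.atan((y - intrinsics.cy) / intrinsics.focal_px),
    )


def to_egocentric(pose: CameraPose, delta: MotorDelta) -> GazeCoordinate:
    """Egocentric stimulus position: absolute pose plus relative movement."""
    return GazeCoordinate(pose.verge + delta.d_verge, pose.tilt + delta.d_tilt)


def pixel_to_gaze(
    pose: CameraPose,
    x: float,
    y: float,
    intrinsics: CameraIntrinsics = CameraIntrinsics(),
) -> GazeCoordinate:
    """Convenience composition of :func:`retinotopic_to_delta` and
    :func:`to_egocentric`."""
    return to_egocentric(pose, retinotopic_to_delta(x, y, intrinsics))


def execute_saccade(
    pose: CameraPose,
    target: GazeCoordinate,
    intrinsics: CameraIntrinsics = CameraIntrinsics(),
) -> CameraPose:
    """Reposition the camera at the target gaze coordinate.

    Targets outside the motor limits are clamped with a warning.  The
    saccade itself is instantaneous; time accounting is the caller's job.
    """
    verge = target.verge
    tilt = target.tilt
    if abs(verge) > intrinsics.verge_limit or abs(tilt) > intrinsics.tilt_limit:
        warnings.warn(
            f"saccade target ({verge:.3f}, {tilt:.3f}) outside motor limits; clamping",
            stacklevel=2,
        )
        verge = max(-intrinsics.verge_limit, min(intrinsics.verge_limit, verge))
        tilt = max(-intrinsics.tilt_limit, min(intrinsics.tilt_limit, tilt))
    return CameraPose(verge=verge, tilt=tilt)
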