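"""Early-vision front end: two data streams, saliency and foveal features.

Each retinal frame is split into the two classic processing streams:

* a low-resolution peri-foveal stream (the "where" pathway) obtained by
  block-averaging the frame onto a coarse lattice, filtered for red, green
  and blue content and for frame-to-frame movement, and combined into a
  normalised saliency map;
* a full-resolution foveal patch (the "what" pathway) from which a feature
  vector with a discrete colour class is extracted.

Colour intensity is *channel dominance* — the channel value minus the
maximum of the other two, floored at zero — so a pure colour scores 1 and
any grey scores 0 under every filter.  Raw channel values would make a
white or grey background maximally salient in all three colour filters,
which is exactly the behaviour a colour pop-out system must not have.

Per-cell saliency is the weight-normalised sum

    s = (w_R I_R + w_G I_G + w_B I_B + w_mov I_mov) / (w_R + w_G + w_B + w_mov)

where the denominator is the maximum the scalar product can achieve for
intensities in [0, 1], so s is always in [0, 1] and rescaling all weights
by a common positive factor leaves the map unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .world import RetinalImage

__all__ = [
    "FeatureClass",
    "FeatureVector",
    "IntensityMaps",
    "RetinotopicStimulus",
    "SaliencyWeights",
    "colour_filter",
    "compute_saliency",
    "extract_feature_vector",
    "extract_stimuli",
    "movement_filter",
    "split_streams",
]


class FeatureClass(IntEnum):
    """The four disjunct feature classes of the foveal classifier."""

    RED = 0
    GREEN = 1
    BLUE = 2
    UNDEFINED = 3


@dataclass(frozen=True)
class SaliencyWeights:
    """Bottom-up weights for the four filter attributes (Q = 4)."""

    w_red: float = 1.0
    w_green: float = 0.0
    w_blue: float = 1.0
    w_mov: float = 0.0

    Q = 4

    def __post_init__(self) -> None:
        for w in self.as_array():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weights must lie in [0, 1]: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_red, self.w_green, self.w_blue, self.w_mov])


@dataclass(frozen=True)
class IntensityMaps:
    """Filter outputs on the peri-foveal lattice, each in [0, 1]."""

    i_red: np.ndarray
    i_green: np.ndarray
    i_blue: np.ndarray
    i_mov: np.ndarray

    def __post_init__(self) -> None:
        shape = self.i_red.shape
        for grid in (self.i_green, self.i_blue, self.i_mov):
            if grid.shape != shape:
                raise ValueError("all intensity grids must share one shape")


@dataclass(frozen=True)
class RetinotopicStimulus:
    """A located peri-foveal stimulus: full-resolution pixel coordinates
    (x rightward, y downward) and a saliency value in [0, 1]."""

    x: float
    y: float
    s: float


@dataclass(frozen=True)
class FeatureVector:
    """Foveal feature vector: mean RGB dominance and a discrete class."""

    intensities: tuple[float, float, float]
    cls: FeatureClass

    @property
    def onehot(self) -> np.ndarray:
        c = np.zeros(4)
        c[int(self.cls)] = 1.0
        return c


def split_streams(
    image: RetinalImage, lattice_factor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split a frame into the foveal patch and the low-res peri-foveal image.

    The foveal patch is the full-resolution centred window.  The
    peri-foveal image is the *whole* frame block-averaged by
    ``lattice_factor`` (the fovea region included: peri-foveal here means
    near-peri-foveal, i.e. it retains colour everywhere).  Any remainder
    rows/columns that do not fill a complete block are cropped at the
    bottom/right edge before averaging.
    """
    if lattice_factor < 1:
        raise ValueError("lattice_factor must be >= 1")
    h, w = image.pixels.shape[:2]
    if lattice_factor > min(h, w):
        raise ValueError(
            f"lattice_factor {lattice_factor} exceeds image dimensions {h}x{w}"
        )
    hh = (h // lattice_factor) * lattice_factor
    ww = (w // lattice_factor) * lattice_factor
    cropped = image.pixels[:hh, :ww]
    lowres = cropped.reshape(
        hh // lattice_factor, lattice_factor, ww // lattice_factor, lattice_factor, 3
    ).mean(axis=(1, 3))
    return image.fovea.copy(), lowres


def _dominance(rgb: np.ndarray) -> np.ndarray:
    """Channel dominance per pixel/cell: C - max(other two), floored at 0."""
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    out = np.stack(
        [
            r - np.maximum(g, b),
            g - np.maximum(r, b),
            b - np.maximum(r, g),
        ],
        axis=-1,
    )
    return np.clip(out, 0.0, 1.0)


def colour_filter(lowres: np.ndarray) -> IntensityMaps:
    """Filter a low-res RGB image for red/green/blue dominance content.

    The movement grid of the returned maps is all zeros; see
    :func:`movement_filter`.
    """
    dom = _dominance(np.asarray(lowres, dtype=float))
    zero = np.zeros(dom.shape[:-1])
    return IntensityMaps(dom[..., 0], dom[..., 1], dom[..., 2], zero)


def movement_filter(frame: np.ndarray, previous: np.ndarray | None) -> np.ndarray:
    """Per-cell movement intensity: mean absolute channel difference.

    The first frame of a run (``previous is None``) yields all zeros.
    """
    frame = np.asarray(frame, dtype=float)
    if previous is None:
        return np.zeros(frame.shape[:-1])
    previous = np.asarray(previous, dtype=float)
    if previous.shape != frame.shape:
        raise ValueError("consecutive frames must share one shape")
    return np.clip(np.abs(frame - previous).mean(axis=-1), 0.0, 1.0)


def compute_saliency(maps: IntensityMaps, weights: SaliencyWeights) -> np.ndarray:
    """Weight-normalised per-cell saliency in [0, 1]."""
    w = weights.as_array()
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one saliency weight must be positive")
    s = (
        w[0] * maps.i_red + w[1] * maps.i_green + w[2] * maps.i_blue + w[3] * maps.i_mov
    ) / total
    return np.clip(s, 0.0, 1.0)


#: 4-connectivity structuring element for stimulus segmentation.
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def extract_stimuli(
    smap: np.ndarray, s_min: float = 0.05, lattice_factor: int = 1
) -> list[RetinotopicStimulus]:
    """Segment a saliency map into discrete located stimuli.

    Connected components (4-connectivity) of cells with ``s > s_min`` each
    yield one stimulus at their saliency-weighted centroid, mapped back to
    full-resolution pixel coordinates; the stimulus saliency is the
    component's maximum cell value.  Stimuli are ordered by descending
    saliency, ties broken by (row, column) of the centroid.
    """
    if not 0.0 <= s_min < 1.0:
        raise ValueError("s_min must lie in [0, 1)")
    smap = np.asarray(smap, dtype=float)
    labels, n = ndimage.label(smap > s_min, structure=_FOUR_CONN)
    stimuli = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        cell_s = smap[rows, cols]
        total = cell_s.sum()
        y = float(((rows + 0.5) * cell_s).sum() / total) * lattice_factor
        x = float(((cols + 0.5) * cell_s).sum() / total) * lattice_factor
        stimuli.append(RetinotopicStimulus(x=x, y=y, s=float(cell_s.max())))
    stimuli.sort(key=lambda st: (-st.s, st.y, st.x))
    return stimuli


def extract_feature_vector(
    patch: np.ndarray,
    background: tuple[float, float, float] = (0.5, 0.5, 0.5),
    d_min: float = 0.2,
    min_coverage: float = 0.5,
) -> FeatureVector:
    """Classify the foveal patch into one of the four feature classes.

    Intensities are channel-dominance values averaged over non-background
    pixels.  The class is the unique channel whose mean dominance exceeds
    ``d_min``; if no channel or more than one qualifies the class is
    UNDEFINED.  Classification also degrades to UNDEFINED when the object
    covers less than ``min_coverage`` of the fovea — the surrogate for a
    physical system's imperfectly centred ("unknown") fixations.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("foveal patch must be non-empty")
    bg = np.asarray(background, dtype=float)
    nonbg = np.any(np.abs(patch - bg) > 1e-6, axis=-1)
    coverage = float(nonbg.mean())
    if coverage == 0.0:
        return FeatureVector(intensities=(0.0, 0.0, 0.0), cls=FeatureClass.UNDEFINED)
    dom = _dominance(patch)[nonbg].mean(axis=0)
    intensities = tuple(float(v) for v in dom)
    if coverage < min_coverage:
        return FeatureVector(intensities=intensities, cls=FeatureClass.UNDEFINED)
    above = np.nonzero(dom > d_min)[0]
    if len(above) == 1:
        cls = FeatureClass(int(above[0]))
    else:
        cls = FeatureClass.UNDEFINED
    return FeatureVector(intensities=intensities, cls=cls)
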