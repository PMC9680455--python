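"""Live/dead viability quantification from two-channel fluorescence z-stacks.

Pipeline: per-channel maximum-intensity z-projection over the focal
planes, prominence-based spot detection on each projection (green spots
count as live cells, red as dead), then viability as
``100 * live / (live + dead)``.

The spot detector mirrors the ImageJ "Find Maxima" semantics: a local
maximum is suppressed when a path exists to a strictly higher pixel
along which the intensity never drops below ``peak - noise_tolerance``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidParameterError

__all__ = [
    "ZStack",
    "MaximaSet",
    "ViabilityResult",
    "z_project_max",
    "find_maxima",
    "count_live_dead",
    "viability_percent",
    "pooled_viability",
    "DEFAULT_NOISE_TOLERANCE",
]

DEFAULT_NOISE_TOLERANCE = 20.0

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class ZStack:
    """Multi-plane two-channel image stack.

    ``intensities`` has shape ``(n_planes, n_channels, height, width)``
    with non-negative integer counts.  ``channel_roles`` maps the two
    stain roles to channel indices, e.g. ``{"green": 0, "red": 1}``
    (green = Calcein / live, red = EthD / dead).
    """

    intensities: np.ndarray
    channel_roles: dict = field(default_factory=lambda: {"green": 0, "red": 1})
    z_range_um: float = 100.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 4:
            raise InvalidParameterError(
                f"stack must be (planes, channels, H, W), got shape {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise InvalidParameterError("stack needs at least one plane")
        if arr.size and arr.min() < 0:
            raise InvalidParameterError("intensities must be non-negative")
        for role in ("green", "red"):
            if role not in self.channel_roles:
                raise InvalidParameterError(f"channel_roles missing {role!r}")
            if not 0 <= self.channel_roles[role] < arr.shape[1]:
                raise InvalidParameterError(
                    f"channel index {self.channel_roles[role]} for {role!r} out of range"
                )
        self.intensities = arr

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]


@dataclass(frozen=True)
class MaximaSet:
    """Accepted maxima of one channel projection."""

    channel: str
    points: list  # (x, y, peak_value) with x = column, y = row
    noise_tolerance: float

    def __len__(self) -> int:
        return len(self.points)


def z_project_max(stack: ZStack) -> np.ndarray:
    """Per-channel maximum-intensity projection, shape ``(C, H, W)``."""
    return stack.intensities.max(axis=0)


_NO_CENTER = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)


def _plateau_maxima(image: np.ndarray):
    """Candidate maxima as plateaus: connected equal-valued regions none of
    whose 8-neighbours is strictly higher.

    Two 8-adjacent peak pixels necessarily share the same value (otherwise
    the lower one would have a strictly higher neighbour), so connected
    components of the peak-pixel mask are exactly the plateaus.

    Returns a list of ``(value, centroid_row, centroid_col, rep_row, rep_col)``
    where the representative is a pixel guaranteed to lie on the plateau.
    """
    nb_max = ndi.maximum_filter(
        image, footprint=_NO_CENTER, mode="constant", cval=-np.inf
    )
    is_peak_px = image >= nb_max
    labels, n = ndi.label(is_peak_px, structure=_EIGHT_CONN)
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    centroids = ndi.center_of_mass(is_peak_px, labels, idx)
    # first flat-index occurrence of each label = representative member pixel
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    rep_of = dict(zip(uniq.tolist(), first.tolist()))
    w = image.shape[1]
    out = []
    for lab, (cy, cx) in zip(idx, centroids):
        fi = rep_of[int(lab)]
        rr, rc = divmod(fi, w)
        out.append((float(image[rr, rc]), cy, cx, rr, rc))
    return out


def find_maxima(
    image: np.ndarray,
    noise_tolerance: float = DEFAULT_NOISE_TOLERANCE,
    channel: str = "unknown",
) -> MaximaSet:
    """Prominence-filtered local maxima of a 2-D image.

    A candidate plateau of value ``v`` (8-connected, equal-valued, with no
    strictly higher neighbour) is accepted iff the connected region of
    pixels with value ``>= v - noise_tolerance`` containing it holds no
    pixel strictly above ``v`` — i.e. no path to a higher pixel stays
    within the tolerance band.  Accepted plateaus are reported as their
    centroid rounded to the nearest pixel, ordered by raster position.
    """
    if noise_tolerance < 0:
        raise InvalidParameterError("noise_tolerance must be >= 0")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError(f"image must be 2-D, got shape {img.shape}")
    points = []
    if img.size == 0 or np.ptp(img) == 0:
        return MaximaSet(channel=channel, points=points, noise_tolerance=noise_tolerance)

    candidates = _plateau_maxima(img)
    # the acceptance rule for one candidate does not depend on the others,
    # so candidates sharing a peak value can share one threshold labelling
    by_value: dict[float, list] = {}
    for v, cy, cx, rr, rc in candidates:
        by_value.setdefault(v, []).append((cy, cx, rr, rc))
    for v, cents in by_value.items():
        comp, _ = ndi.label(img >= v - noise_tolerance, structure=_EIGHT_CONN)
        comp_ids = comp[[c[2] for c in cents], [c[3] for c in cents]]
        comp_max = ndi.maximum(img, labels=comp, index=comp_ids)
        for (cy, cx, _, _), m in zip(cents, np.atleast_1d(comp_max)):
            if m > v:
                continue  # within tolerance of a strictly higher pixel
            points.append((int(round(cx)), int(round(cy)), float(v)))
    points.sort(key=lambda p: (p[1], p[0]))
    return MaximaSet(channel=channel, points=points, noise_tolerance=noise_tolerance)


@dataclass(frozen=True)
class ViabilityResult:
    live: int
    dead: int
    viability: float | None  # percent; None when live + dead == 0
    image_id: str = ""


def count_live_dead(
    stack: ZStack, noise_tolerance: float = DEFAULT_NOISE_TOLERANCE
) -> tuple[int, int]:
    """Spot counts on the green (live) and red (dead) projections."""
    proj = z_project_max(stack)
    live = len(find_maxima(proj[stack.channel_roles["green"]], noise_tolerance, "green"))
    dead = len(find_maxima(proj[stack.channel_roles["red"]], noise_tolerance, "red"))
    return live, dead


def viability_percent(live: int, dead: int) -> float | None:
    """``100 * live / (live + dead)``; ``None`` when both counts are zero."""
    if live < 0 or dead < 0:
        raise InvalidParameterError("counts must be non-negative")
    total = live + dead
    if total == 0:
        return None
    return 100.0 * live / total


def pooled_viability(results) -> float | None:
    """Pooled viability: total live over total counted, across images.

    This is NOT the mean of per-image percentages; images with more cells
    weigh more.  ``None`` when no image contains any cell.
    """
    live = sum(r.live for r in results)
    dead = sum(r.dead for r in results)
    return viability_percent(live, dead)


def analyze_stack(
    stack: ZStack,
    noise_tolerance: float = DEFAULT_NOISE_TOLERANCE,
    image_id: str = "",
) -> ViabilityResult:
    """Full per-stack pipeline: projection, counting, viability."""
    live, dead = count_live_dead(stack, noise_tolerance)
    return ViabilityResult(
        live=live, dead=dead, viability=viability_percent(live, dead), image_id=image_id
    )
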