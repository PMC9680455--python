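"""Grid-scaffold pore segmentation and print-quality metrics.

A printed square lattice is segmented from a top-view image; the
openings (pores) strictly inside its outer boundary are labelled,
matched to the designed lattice cells, and summarised as the normalized
pore number (percentage of designed pores successfully realised) and
pore-area statistics in mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .calibration import DEFAULT_PIXELS_PER_MM
from .errors import InvalidParameterError, SegmentationError

__all__ = [
    "GridSpec",
    "PoreRecord",
    "GridMetrics",
    "segment_pores",
    "match_pores_to_grid",
    "normalized_pore_number",
    "pore_area_stats",
    "analyze_grid_image",
]

#: pores smaller than this fraction of the analytic open-cell area are specks
MIN_AREA_FRACTION = 0.05


@dataclass(frozen=True)
class GridSpec:
    """Designed lattice geometry: a square of ``span`` mm split into
    ``cells_per_side`` × ``cells_per_side`` open cells by printed lines of
    ``line_width`` mm."""

    span: float = 20.0
    cells_per_side: int = 11
    line_width: float = 0.4
    calibration: float = DEFAULT_PIXELS_PER_MM  # px per mm

    def __post_init__(self) -> None:
        if self.cells_per_side < 1:
            raise InvalidParameterError("cells_per_side must be >= 1")
        if not self.calibration > 0:
            raise InvalidParameterError("calibration must be > 0")
        if not self.span > self.cells_per_side * self.line_width:
            raise InvalidParameterError(
                "span must exceed total printed line width (pores would be closed)"
            )

    @property
    def expected_pores(self) -> int:
        return self.cells_per_side**2

    @property
    def pitch(self) -> float:
        """Cell-to-cell spacing, mm."""
        return self.span / self.cells_per_side

    @property
    def open_cell_area(self) -> float:
        """Analytic open area of one designed cell, mm²."""
        return (self.pitch - self.line_width) ** 2


@dataclass(frozen=True)
class PoreRecord:
    pore_id: int
    centroid: tuple  # (x_mm, y_mm)
    area: float  # mm²
    cell_index: tuple | None  # (row, col) or None if unmatched
    status: str  # ok | merged | missing | filled
    spanned_cells: tuple = ()  # all designed cells this pore covers


@dataclass(frozen=True)
class GridMetrics:
    normalized_pore_number: float  # percent of designed pores with status ok
    mean_pore_area: float  # mm², nan if no ok pores
    sd_pore_area: float  # mm², nan if < 2 ok pores
    n_ok: int
    n_merged: int
    n_missing: int
    stage_label: str = ""


def _foreground(image: np.ndarray, invert: bool = False) -> np.ndarray:
    """Binary printed-material mask: red-contrast channel for RGB input,
    Otsu threshold, bright material by default (``invert`` for dark)."""
    img = np.asarray(image)
    if img.ndim == 3:
        signal = img[..., 0].astype(float) - img[..., 1].astype(float)
    elif img.ndim == 2:
        signal = img.astype(float)
    else:
        raise InvalidParameterError(f"expected 2-D or RGB image, got shape {img.shape}")
    if np.ptp(signal) == 0:
        # a uniformly bright frame is all material (fully spread ink);
        # a uniformly dark/zero frame has no grid at all
        if signal.flat[0] > 0 and not invert:
            return np.ones_like(signal, dtype=bool)
        raise SegmentationError("flat image: no grid boundary detectable")
    thr = threshold_otsu(signal)
    fg = signal < thr if invert else signal > thr
    return fg


def segment_pores(
    image: np.ndarray, spec: GridSpec, invert: bool = False
) -> np.ndarray:
    """Label map of pore openings strictly inside the grid boundary.

    The printed material is thresholded (Otsu on the red-contrast
    channel), closed with a 3-px disk, and the background components not
    touching the image border are returned as labelled pores.
    """
    fg = _foreground(image, invert=invert)
    fg = closing(fg, disk(3)).astype(bool)
    if not fg.any():
        raise SegmentationError("no foreground: no grid boundary detectable")
    holes, _ = ndi.label(~fg)
    # drop background connected to the image border (exterior)
    border = np.unique(
        np.concatenate([holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]])
    )
    mask = np.isin(holes, border[border > 0])
    holes[mask] = 0
    # relabel compactly
    out, _ = ndi.label(holes > 0)
    return out


def _grid_bbox(image: np.ndarray, invert: bool) -> tuple[int, int, int, int]:
    """Bounding box (r0, r1, c0, c1) of the largest foreground component."""
    fg = closing(_foreground(image, invert=invert), disk(3)).astype(bool)
    labels, n = ndi.label(fg)
    if n == 0:
        raise SegmentationError("no grid boundary detectable")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    big = labels == (1 + int(np.argmax(sizes)))
    rows, cols = np.nonzero(big)
    return rows.min(), rows.max(), cols.min(), cols.max()


def match_pores_to_grid(
    labels: np.ndarray,
    spec: GridSpec,
    image: np.ndarray | None = None,
    bbox: tuple[int, int, int, int] | None = None,
    invert: bool = False,
) -> list[PoreRecord]:
    """Assign each labelled pore to designed cells and classify every cell.

    The designed lattice is registered to the outer bounding box of the
    printed grid (from ``image`` or given explicitly as ``bbox``).  A
    cell is ``ok`` when exactly one pore lies in it and spans no other
    cell, ``merged`` when a pore spans two or more cells, ``missing``
    otherwise.  Areas are reported in mm² via the calibration.
    """
    if bbox is None:
        if image is None:
            raise InvalidParameterError("match_pores_to_grid needs image or bbox")
        bbox = _grid_bbox(image, invert)
    n = spec.cells_per_side
    # the bounding box spans line centre to line centre plus half a line
    # width each side; cell boundaries sit on the line centres
    half_lw = spec.line_width * spec.calibration / 2.0
    r0, r1, c0, c1 = bbox
    r0, r1 = r0 + half_lw, r1 - half_lw
    c0, c1 = c0 + half_lw, c1 - half_lw
    cell_h = (r1 - r0) / n
    cell_w = (c1 - c0) / n
    if cell_h <= 0 or cell_w <= 0:
        raise SegmentationError("degenerate grid bounding box")
    px_area = spec.calibration**2  # px² per mm²
    floor_px = MIN_AREA_FRACTION * spec.open_cell_area * px_area
    # overlap smaller than this fraction of a cell does not count as spanning
    span_floor_px = max(floor_px, 1.0)

    def cell_of(rr: np.ndarray, cc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ri = np.clip(((rr - r0) / cell_h).astype(int), 0, n - 1)
        ci = np.clip(((cc - c0) / cell_w).astype(int), 0, n - 1)
        return ri, ci

    status = np.full((n, n), "missing", dtype=object)
    claims: dict[tuple[int, int], list] = {}
    pores = []
    n_labels = int(labels.max())
    for lab in range(1, n_labels + 1):
        rr, cc = np.nonzero(labels == lab)
        area_px = len(rr)
        if area_px < span_floor_px:
            continue  # speck
        ri, ci = cell_of(rr, cc)
        flat = ri * n + ci
        uniq, counts = np.unique(flat, return_counts=True)
        spanned = [
            (int(f) // n, int(f) % n)
            for f, cnt in zip(uniq, counts)
            if cnt >= span_floor_px
        ]
        if not spanned:  # straddles cells but dominates none; use centroid cell
            ri0, ci0 = cell_of(np.array([rr.mean()]), np.array([cc.mean()]))
            spanned = [(int(ri0[0]), int(ci0[0]))]
        centroid_mm = (cc.mean() / spec.calibration, rr.mean() / spec.calibration)
        area_mm2 = area_px / px_area
        pores.append((lab, centroid_mm, area_mm2, spanned))
        for cell in spanned:
            claims.setdefault(cell, []).append(lab)

    records: list[PoreRecord] = []
    pore_status: dict[int, tuple[str, tuple | None]] = {}
    for lab, centroid, area, spanned in pores:
        if len(spanned) >= 2:
            st = "merged"
            for cell in spanned:
                status[cell] = "merged"
            pore_status[lab] = (st, None)
        else:
            cell = spanned[0]
            # a cell also spanned by a merged pore stays merged
            pore_status[lab] = ("ok", cell)
    # second pass: single-cell pores in a cell claimed by a merged pore, or
    # sharing a cell with another single-cell pore, are not clean prints
    for lab, centroid, area, spanned in pores:
        st, cell = pore_status[lab]
        if st != "ok":
            continue
        cell = spanned[0]
        others = [o for o in claims[cell] if o != lab]
        if status[cell] == "merged" or others:
            pore_status[lab] = ("merged", None)
            status[cell] = "merged"
        elif status[cell] == "missing":
            status[cell] = "ok"
    pid = 0
    for lab, centroid, area, spanned in pores:
        st, cell = pore_status[lab]
        pid += 1
        records.append(
            PoreRecord(pore_id=pid, centroid=centroid, area=area,
                       cell_index=cell, status=st, spanned_cells=tuple(spanned))
        )
    # cells never touched by any pore
    for row in range(n):
        for col in range(n):
            if status[row, col] == "missing":
                pid += 1
                cy = (r0 + (row + 0.5) * cell_h) / spec.calibration
                cx = (c0 + (col + 0.5) * cell_w) / spec.calibration
                records.append(
                    PoreRecord(pore_id=pid, centroid=(cx, cy), area=0.0,
                               cell_index=(row, col), status="missing",
                               spanned_cells=((row, col),))
                )
    return records


def cell_status_counts(records: list[PoreRecord]) -> tuple[int, int, int]:
    """Per-cell (ok, merged, missing) counts; they sum to the designed total."""
    ok = sum(1 for r in records if r.status == "ok")
    merged_cells = set()
    for r in records:
        if r.status == "merged":
            merged_cells.update(r.spanned_cells)
    missing = sum(1 for r in records if r.status in ("missing", "filled"))
    return ok, len(merged_cells), missing


def normalized_pore_number(records: list[PoreRecord], spec: GridSpec) -> float:
    """Percentage of designed pores realised cleanly: 100 · #ok / expected."""
    n_ok = sum(1 for r in records if r.status == "ok")
    return 100.0 * n_ok / spec.expected_pores


def pore_area_stats(records: list[PoreRecord]) -> tuple[float, float]:
    """Mean and sample SD (mm²) over ok pores; ``(nan, nan)`` if none."""
    areas = np.array([r.area for r in records if r.status == "ok"], dtype=float)
    if len(areas) == 0:
        return float("nan"), float("nan")
    mean = float(areas.mean())
    sd = float(areas.std(ddof=1)) if len(areas) > 1 else 0.0
    return mean, sd


def analyze_grid_image(
    image: np.ndarray, spec: GridSpec, stage_label: str = "", invert: bool = False
) -> tuple[list[PoreRecord], GridMetrics]:
    """Full pipeline: segment, match, summarise one grid image."""
    labels = segment_pores(image, spec, invert=invert)
    records = match_pores_to_grid(labels, spec, image=image, invert=invert)
    mean, sd = pore_area_stats(records)
    n_ok, n_merged, n_missing = cell_status_counts(records)
    metrics = GridMetrics(
        normalized_pore_number=normalized_pore_number(records, spec),
        mean_pore_area=mean,
        sd_pore_area=sd,
        n_ok=n_ok,
        n_merged=n_merged,
        n_missing=n_missing,
        stage_label=stage_label,
    )
    return records, metrics
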