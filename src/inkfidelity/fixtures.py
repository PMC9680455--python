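"""Ground-truthed synthetic inputs for every analysis pipeline.

Three generators, all seed-deterministic, whose "truth" is analytic
(computed from the generating parameters, never measured back from the
rendered pixels):

* sagging-filament side-view image series driven by the beam model,
* grid-pattern images with controlled defects (merged/filled/spread),
* two-channel fluorescence z-stacks with known spot counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import beam
from .calibration import DEFAULT_PIXELS_PER_MM
from .errors import FixtureSpecError, InvalidParameterError
from .grid import GridSpec, PoreRecord
from .viability import ZStack

__all__ = [
    "FilamentSeriesSpec",
    "FilamentFrame",
    "make_filament_series",
    "GridFixtureSpec",
    "make_grid_image",
    "ZStackFixtureSpec",
    "make_zstack",
]

DEFAULT_RHO = 1026.0  # kg/m^3, 4% alginate
PAPER_GAPS_MM = (1.0, 2.0, 4.0, 8.0, 16.0)

_BG_LEVEL = 230  # light background, 8-bit
_FG_LEVEL = 25  # dark (dyed) filament


# ---------------------------------------------------------------------------
# filament series


@dataclass(frozen=True)
class FilamentSeriesSpec:
    """Parameters of a rendered filament-collapse experiment."""

    E_true: float  # Pa
    P: float  # N, axial tension
    r0: float  # mm, initial radius
    shrink_rate: float = 0.0  # mm/min, linear radius decay
    rho: float = DEFAULT_RHO  # kg/m^3
    gaps: tuple = PAPER_GAPS_MM  # mm
    frame_interval: float = 60.0  # s
    n_frames: int = 5
    calibration: float = DEFAULT_PIXELS_PER_MM  # px/mm
    noise_sigma: float = 0.0  # 8-bit intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise FixtureSpecError("n_frames must be >= 1")
        duration_min = (self.n_frames - 1) * self.frame_interval / 60.0
        if self.r0 - self.shrink_rate * duration_min <= 0:
            raise FixtureSpecError("radius would reach zero within the series")

    def radius_at(self, t_s: float) -> float:
        """Radius in mm at time ``t_s`` seconds."""
        return self.r0 - self.shrink_rate * t_s / 60.0


@dataclass
class FilamentFrame:
    """One rendered frame plus its analytic ground truth."""

    gap_mm: float
    t_s: float
    image: np.ndarray
    supports: tuple  # (x_left, x_right) columns of the support points
    truth: dict = field(default_factory=dict)


def _render_curve(
    L_mm: float,
    profile_mm,  # callable x_mm -> sag_mm
    r_mm: float,
    calibration: float,
    noise_sigma: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple]:
    """Render a thick anti-aliased curve between two supports.

    Dark stroke on a light background, quantised to 8-bit.  Returns the
    image and the support column positions.
    """
    cal = calibration
    r_px = r_mm * cal
    L_px = L_mm * cal
    margin = int(math.ceil(r_px)) + 8
    x0 = float(margin)
    y0 = margin + r_px

    xs_px = np.arange(0.0, L_px + 0.25, 0.25)
    w_px = np.asarray(profile_mm(xs_px / cal), dtype=float) * cal
    pts = np.column_stack([x0 + xs_px, y0 + w_px])

    W = int(math.ceil(L_px + 2 * margin))
    H = int(math.ceil(y0 + float(w_px.max()) + r_px)) + margin
    tree = cKDTree(pts)
    yy, xx = np.mgrid[0:H, 0:W]
    # query points are (x, y) pairs to match the polyline layout
    dist, _ = tree.query(np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5]))
    coverage = np.clip(r_px + 0.5 - dist.reshape(H, W), 0.0, 1.0)
    img = _BG_LEVEL + (_FG_LEVEL - _BG_LEVEL) * coverage
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    supports = (int(round(x0)), int(round(x0 + L_px)))
    return img, supports


def make_filament_series(spec: FilamentSeriesSpec) -> list[FilamentFrame]:
    """Render a filament-collapse image series for every gap in the spec.

    Per frame the radius follows the linear shrink schedule, the sag
    profile is the beam-model solution at ``(E_true, r(t))``, and the
    truth records the analytic mid-span deflection and support tangent
    angles (degrees).
    """
    rng = np.random.default_rng(spec.seed)
    frames: list[FilamentFrame] = []
    for gap in spec.gaps:
        for i in range(spec.n_frames):
            t_s = i * spec.frame_interval
            r_mm = spec.radius_at(t_s)
            params = beam.BeamParameters(
                E=spec.E_true, P=spec.P, r=r_mm * 1e-3, rho=spec.rho, L=gap * 1e-3
            )
            sol = beam.solve(params)

            def profile_mm(x_mm, _sol=sol):
                return beam.deflection_profile(_sol, np.asarray(x_mm) * 1e-3) * 1e3

            image, supports = _render_curve(
                gap, profile_mm, r_mm, spec.calibration, spec.noise_sigma, rng
            )
            theta1, theta2 = beam.support_angles_deg(params)
            frames.append(
                FilamentFrame(
                    gap_mm=gap,
                    t_s=t_s,
                    image=image,
                    supports=supports,
                    truth={
                        "t_s": t_s,
                        "r_mm": r_mm,
                        "E_true_Pa": spec.E_true,
                        "P_N": spec.P,
                        "w_max_mm": beam.midpoint_deflection(params) * 1e3,
                        "theta1_deg": theta1,
                        "theta2_deg": theta2,
                        "mode": sol.mode,
                    },
                )
            )
    return frames


# ---------------------------------------------------------------------------
# grid fixtures


@dataclass(frozen=True)
class GridFixtureSpec:
    """A designed lattice plus a controlled defect list.

    ``defects`` entries are tuples: ``("merge", (r, c), (r2, c2))`` removes
    the wall between two edge-adjacent cells; ``("fill", (r, c))`` closes a
    cell.  ``spread_fraction`` >= 1 widens every line (emulating a
    low-viscosity ink spreading), narrowing or closing the pores.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    defects: tuple = ()
    spread_fraction: float = 1.0
    margin_px: int = 20
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.grid.cells_per_side
        if self.spread_fraction < 1.0:
            raise FixtureSpecError("spread_fraction must be >= 1")
        filled = set()
        merged_cells = set()
        for d in self.defects:
            kind = d[0]
            if kind == "fill":
                (_, cell) = d
                _check_cell(cell, n)
                filled.add(cell)
            elif kind == "merge":
                (_, a, b) = d
                _check_cell(a, n)
                _check_cell(b, n)
                if abs(a[0] - b[0]) + abs(a[1] - b[1]) != 1:
                    raise FixtureSpecError(f"merge cells must be edge-adjacent: {a}, {b}")
                merged_cells.update((a, b))
            else:
                raise FixtureSpecError(f"unknown defect kind {kind!r}")
        if filled & merged_cells:
            raise FixtureSpecError(
                f"contradictory defects (fill + merge) on cells {sorted(filled & merged_cells)}"
            )

    @property
    def effective_line_width(self) -> float:
        return self.grid.line_width * self.spread_fraction


def _check_cell(cell, n: int) -> None:
    r, c = cell
    if not (0 <= r < n and 0 <= c < n):
        raise FixtureSpecError(f"cell {cell} outside {n}x{n} lattice")


def _stripe_coverage(length: int, centers: np.ndarray, half_width: float) -> np.ndarray:
    """Per-pixel coverage (0..1) of a union of stripes along one axis."""
    pos = np.arange(length, dtype=float)
    cov = np.zeros(length)
    for c in centers:
        lo, hi = c - half_width, c + half_width
        cov = np.maximum(cov, np.clip(np.minimum(hi, pos + 1.0) - np.maximum(lo, pos), 0.0, 1.0))
    return cov


def make_grid_image(spec: GridFixtureSpec) -> tuple[np.ndarray, list[PoreRecord]]:
    """Render the lattice (bright lines on dark background) and its truth.

    The truth is a per-cell :class:`~inkfidelity.grid.PoreRecord` list with
    analytic open areas: ``ok`` cells carry ``(pitch - line_width_eff)²``,
    merged pairs carry the union area of the joined opening, filled or
    closed cells carry zero.
    """
    g = spec.grid
    n = g.cells_per_side
    cal = g.calibration
    rng = np.random.default_rng(spec.seed)
    lw_eff = spec.effective_line_width
    pitch = g.pitch
    open_w = pitch - lw_eff  # mm, may be <= 0 when spread closes pores

    span_px = g.span * cal
    lw_px = lw_eff * cal
    m = spec.margin_px
    size = int(math.ceil(span_px)) + 2 * m
    centers = m + np.arange(n + 1) * (span_px / n)

    cov1d = _stripe_coverage(size, centers, lw_px / 2.0)
    fg = np.maximum(cov1d[None, :], cov1d[:, None])

    closed = open_w * cal < 1.0  # opening below one pixel: pores unresolvable

    def cell_open_box(r: int, c: int) -> tuple[float, float, float, float]:
        """(y_lo, y_hi, x_lo, x_hi) of the open area of cell (r, c), px."""
        y_lo = centers[r] + lw_px / 2.0
        y_hi = centers[r + 1] - lw_px / 2.0
        x_lo = centers[c] + lw_px / 2.0
        x_hi = centers[c + 1] - lw_px / 2.0
        return y_lo, y_hi, x_lo, x_hi

    def paint_box(y_lo, y_hi, x_lo, x_hi, value) -> None:
        ys = slice(int(math.floor(y_lo)), int(math.ceil(y_hi)))
        xs = slice(int(math.floor(x_lo)), int(math.ceil(x_hi)))
        fg[ys, xs] = value

    status = np.full((n, n), "ok" if not closed else "filled", dtype=object)
    area = np.full((n, n), 0.0 if closed else open_w**2)

    for d in spec.defects:
        if d[0] == "fill":
            (_, (r, c)) = d
            paint_box(*cell_open_box(r, c), 1.0)
            status[r, c] = "filled"
            area[r, c] = 0.0
        else:
            (_, a, b) = d
            if closed:
                continue  # nothing to merge once spreading closed the pores
            (r1, c1), (r2, c2) = sorted([a, b])
            # erase the shared wall segment between the two open areas
            if r1 == r2:  # horizontal neighbours share a vertical wall
                y_lo, y_hi, _, _ = cell_open_box(r1, c1)
                xw = centers[c1 + 1]
                paint_box(y_lo, y_hi, xw - lw_px / 2.0, xw + lw_px / 2.0, 0.0)
            else:  # vertical neighbours share a horizontal wall
                _, _, x_lo, x_hi = cell_open_box(r1, c1)
                yw = centers[r1 + 1]
                paint_box(yw - lw_px / 2.0, yw + lw_px / 2.0, x_lo, x_hi, 0.0)
            union_area = 2.0 * open_w**2 + lw_eff * open_w
            for cell in (a, b):
                status[cell] = "merged"
                area[cell] = union_area

    img = 255.0 * fg
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth: list[PoreRecord] = []
    pid = 0
    for r in range(n):
        for c in range(n):
            pid += 1
            cy = (m + (r + 0.5) * span_px / n) / cal
            cx = (m + (c + 0.5) * span_px / n) / cal
            truth.append(
                PoreRecord(
                    pore_id=pid,
                    centroid=(cx, cy),
                    area=float(area[r, c]),
                    cell_index=(r, c),
                    status=str(status[r, c]),
                )
            )
    return img, truth


# ---------------------------------------------------------------------------
# z-stack fixtures


@dataclass(frozen=True)
class ZStackFixtureSpec:
    """Two-channel fluorescence stack with known spot ground truth."""

    n_live: int
    n_dead: int
    shape: tuple = (256, 256)  # (H, W)
    spot_sigma: float = 2.0  # px
    amplitude: float = 180.0  # peak height above background
    min_separation: float = 12.0  # px, between any two spots
    n_planes: int = 6
    z_range_um: float = 100.0
    background: float = 10.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # gaussian | poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_live < 0 or self.n_dead < 0:
            raise FixtureSpecError("spot counts must be >= 0")
        if self.n_planes < 1:
            raise FixtureSpecError("n_planes must be >= 1")
        if self.noise_model not in ("gaussian", "poisson"):
            raise FixtureSpecError(f"unknown noise model {self.noise_model!r}")


def _place_spots(
    n: int, shape: tuple, margin: float, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample ``n`` positions honouring a minimum separation."""
    H, W = shape
    if H - 2 * margin <= 0 or W - 2 * margin <= 0:
        raise FixtureSpecError("image too small for the requested spot margin")
    placed: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 20000 + 2000 * n
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise FixtureSpecError(
                f"could not place {n} spots with min separation {min_sep} "
                f"in a {H}x{W} image after {max_attempts} attempts"
            )
        y = rng.uniform(margin, H - margin)
        x = rng.uniform(margin, W - margin)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_sep**2 for py, px in placed):
            placed.append((y, x))
    return np.array(placed).reshape(n, 2)


def make_zstack(spec: ZStackFixtureSpec) -> tuple[ZStack, dict]:
    """Generate a two-channel z-stack of Gaussian spots with exact truth.

    Each spot is assigned one focal plane so the max projection recovers
    its full amplitude.  Spots of both channels share one global
    minimum-separation constraint.  8-bit output.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    margin = max(4.0 * spec.spot_sigma, 4.0)
    total = spec.n_live + spec.n_dead
    positions = (
        _place_spots(total, spec.shape, margin, spec.min_separation, rng)
        if total
        else np.empty((0, 2))
    )
    live_pos = positions[: spec.n_live]
    dead_pos = positions[spec.n_live :]

    stack = np.full((spec.n_planes, 2, H, W), spec.background, dtype=float)
    half = int(math.ceil(4.0 * spec.spot_sigma))
    for chan, pos in ((0, live_pos), (1, dead_pos)):
        planes = rng.integers(0, spec.n_planes, size=len(pos))
        for (y, x), p in zip(pos, planes):
            y0, x0 = int(round(y)), int(round(x))
            ys = slice(max(0, y0 - half), min(H, y0 + half + 1))
            xs = slice(max(0, x0 - half), min(W, x0 + half + 1))
            yy, xx = np.mgrid[ys, xs]
            blob = spec.amplitude * np.exp(
                -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * spec.spot_sigma**2)
            )
            stack[p, chan, ys, xs] += blob
    if spec.noise_model == "poisson":
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    elif spec.noise_sigma > 0:
        stack = stack + rng.normal(0.0, spec.noise_sigma, stack.shape)
    stack = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    z = ZStack(
        intensities=stack,
        channel_roles={"green": 0, "red": 1},
        z_range_um=spec.z_range_um,
    )
    truth = {
        "live_count": spec.n_live,
        "dead_count": spec.n_dead,
        "live_positions": live_pos.tolist(),
        "dead_positions": dead_pos.tolist(),
    }
    return z, truth
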