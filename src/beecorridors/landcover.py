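"""Derivation of seminatural linear landscape structures (LLS) from a
categorical land-cover raster.

The land-cover model follows the CLC+ backbone convention: a 10-m integer
raster with classes sealed (1), woody needle-leaved (2), woody broadleaved
deciduous (3), woody broadleaved evergreen (4), low woody (5), permanent
herbaceous (6), periodically herbaceous / cropland (7), lichens & mosses
(8), sparsely vegetated (9), water (10), snow & ice (11).

Seminatural LLS are the boundary lines of patches of forest (2, 3), low
woody vegetation (5), permanent herbaceous (6), and sparsely vegetated
areas (9); forest edges are the boundaries of classes 2 and 3 alone.  Each
class group is polygonized separately and its boundary faces collected;
the union (with exact duplicates counted once) forms the "all seminatural"
line map, so a forest–grassland face contributes a single segment.

Conventions
-----------
Arrays are row-major with row 0 at the *top* of the map; ``origin`` is the
(x, y) of the lower-left corner in a projected metric CRS.  Faces on the
raster border or adjacent to nodata cells are never edges: boundaries are
only drawn between two valid in-bounds cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: CLC+-style class codes used throughout.
CLC_CODES = frozenset(range(1, 12))
FOREST_CLASSES = frozenset({2, 3})
LOW_WOODY_CLASSES = frozenset({5})
HERBACEOUS_CLASSES = frozenset({6})
SPARSE_CLASSES = frozenset({9})
GRASSLAND_CODE = 6

#: The four class groups whose patch boundaries form seminatural LLS.
SEMINATURAL_CLASS_SETS = (
    FOREST_CLASSES,
    LOW_WOODY_CLASSES,
    HERBACEOUS_CLASSES,
    SPARSE_CLASSES,
)


@dataclass
class LandCoverGrid:
    """Categorical land-cover raster in a projected metric CRS.

    Parameters
    ----------
    values
        2-D integer array of class codes; row 0 is the northernmost row.
    cell_size
        Cell edge length in meters (> 0).
    origin
        ``(x0, y0)`` of the lower-left corner, meters.
    nodata
        Integer code marking invalid cells (default ``-1``).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("land-cover raster must be a non-empty 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("land-cover raster must hold integer class codes")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, as 2-D arrays."""
        n_rows, n_cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(n_cols) + 0.5) * self.cell_size
        ys = y0 + (n_rows - np.arange(n_rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def contains(self, x: float, y: float) -> bool:
        n_rows, n_cols = self.shape
        x0, y0 = self.origin
        return (
            x0 <= x <= x0 + n_cols * self.cell_size
            and y0 <= y <= y0 + n_rows * self.cell_size
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; points exactly on the
        upper/right boundary belong to the last cell."""
        n_rows, n_cols = self.shape
        x0, y0 = self.origin
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) lies outside the raster")
        col = min(int((x - x0) // self.cell_size), n_cols - 1)
        row = min(int((y - y0) // self.cell_size), n_rows - 1)
        return n_rows - 1 - row, col


@dataclass
class LineSet:
    """A collection of polylines in projected meters.

    ``segments`` is a list of ``(k, 2)`` float arrays (``k >= 2``).
    ``class_tag`` records which class grouping produced the lines
    (``"all-seminatural"``, ``"forest"``, ``"nonforest"``, or free-form).
    """

    segments: list[np.ndarray]
    class_tag: str = ""
    #: face bookkeeping from :func:`extract_boundaries` — ``(orient, row,
    #: col)`` index triples on the source grid, used as a fast exact path
    #: by :func:`rasterize_lines`.  ``None`` for generic line sets.
    faces: np.ndarray | None = field(default=None, repr=False)
    source_cell_size: float | None = field(default=None, repr=False)
    source_origin: tuple[float, float] | None = field(default=None, repr=False)
    source_shape: tuple[int, int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.segments = [np.asarray(s, dtype=float) for s in self.segments]
        for s in self.segments:
            if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] != 2:
                raise ValueError("each segment needs >= 2 (x, y) vertices")

    @property
    def total_length(self) -> float:
        """Sum of Euclidean lengths of all segments, meters."""
        p, q = self._stacked()
        if p.size == 0:
            return 0.0
        return float(np.hypot(*(q - p).T).sum())

    def _stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All 2-point pieces as (start, end) arrays; cached."""
        cached = getattr(self, "_stacked_cache", None)
        if cached is None:
            if self.segments:
                p = np.concatenate([s[:-1] for s in self.segments], axis=0)
                q = np.concatenate([s[1:] for s in self.segments], axis=0)
            else:
                p = q = np.empty((0, 2))
            cached = (p, q)
            object.__setattr__(self, "_stacked_cache", cached)
        return cached

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class BinaryFeatureGrid:
    """0/1 raster marking cells touched by linear features."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary grid values must be 0 or 1")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ProportionGrid:
    """Coarse raster of fine-cell feature fractions in [0, 1].

    Each value is the share of fine cells inside the coarse cell that were
    1 in the source :class:`BinaryFeatureGrid`; ``factor`` is the number of
    fine cells per coarse cell along each axis, so ``value * factor**2`` is
    an integer count and the total count is conserved exactly.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    factor: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min(initial=0.0) < 0 or self.values.max(initial=0.0) > 1:
            raise ValueError("proportions must lie in [0, 1]")
        if self.factor < 1:
            raise ValueError("factor must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        n_rows, n_cols = self.shape
        x0, y0 = self.origin
        col = int((x - x0) // self.cell_size)
        row_from_bottom = int((y - y0) // self.cell_size)
        if not (0 <= col < n_cols and 0 <= row_from_bottom < n_rows):
            raise ValueError(f"point ({x}, {y}) lies outside the raster")
        return n_rows - 1 - row_from_bottom, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        n_rows, _ = self.shape
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.cell_size,
            y0 + (n_rows - row - 0.5) * self.cell_size,
        )


# ---------------------------------------------------------------------------
# boundary extraction


def _class_faces(grid: LandCoverGrid, class_set: frozenset | set) -> np.ndarray:
    """Interior faces separating a class-set cell from a non-member cell.

    Returns an ``(m, 3)`` int array of ``(orient, row, col)`` where
    ``orient == 0`` is the vertical face between ``(row, col)`` and
    ``(row, col + 1)`` and ``orient == 1`` the horizontal face between
    ``(row, col)`` and ``(row + 1, col)``.  Raster-border and nodata faces
    are excluded by construction.
    """
    vals = grid.values
    member = np.isin(vals, list(class_set))
    valid = vals != grid.nodata

    # vertical faces: horizontally adjacent pairs
    vdiff = member[:, :-1] != member[:, 1:]
    vok = vdiff & valid[:, :-1] & valid[:, 1:]
    vr, vc = np.nonzero(vok)

    # horizontal faces: vertically adjacent pairs
    hdiff = member[:-1, :] != member[1:, :]
    hok = hdiff & valid[:-1, :] & valid[1:, :]
    hr, hc = np.nonzero(hok)

    faces = np.empty((vr.size + hr.size, 3), dtype=np.int64)
    faces[: vr.size, 0] = 0
    faces[: vr.size, 1] = vr
    faces[: vr.size, 2] = vc
    faces[vr.size :, 0] = 1
    faces[vr.size :, 1] = hr
    faces[vr.size :, 2] = hc
    return faces


def _faces_to_segments(
    faces: np.ndarray, grid: LandCoverGrid
) -> list[np.ndarray]:
    """Convert face index triples to 2-point segments in map coordinates."""
    n_rows, _ = grid.shape
    cs = grid.cell_size
    x0, y0 = grid.origin
    orient, rows, cols = faces.T
    m = faces.shape[0]
    seg = np.empty((m, 2, 2))
    # vertical face: shared edge at x = x0 + (col+1)*cs spanning the row
    v = orient == 0
    xv = x0 + (cols[v] + 1) * cs
    y_top = y0 + (n_rows - rows[v]) * cs
    seg[v, 0, 0] = xv
    seg[v, 0, 1] = y_top - cs
    seg[v, 1, 0] = xv
    seg[v, 1, 1] = y_top
    # horizontal face: shared edge at y = bottom of row `row`
    h = orient == 1
    yh = y0 + (n_rows - 1 - rows[h]) * cs
    x_left = x0 + cols[h] * cs
    seg[h, 0, 0] = x_left
    seg[h, 0, 1] = yh
    seg[h, 1, 0] = x_left + cs
    seg[h, 1, 1] = yh
    return list(seg)


def extract_boundaries(
    grid: LandCoverGrid,
    class_sets: frozenset | set | list | tuple = SEMINATURAL_CLASS_SETS,
    class_tag: str = "",
) -> LineSet:
    """Boundary lines of land-cover patches for one or more class groups.

    Each class set is polygonized separately: every interior raster face
    between a member cell and a non-member cell yields one unit segment of
    length ``cell_size``.  The union over class sets is deduplicated, so a
    face shared by two groups (e.g. forest–grassland) counts once.  Faces
    on the raster border or touching nodata cells are excluded.

    Parameters
    ----------
    grid
        Land-cover raster.
    class_sets
        A single set of class codes, or a sequence of sets (one per patch
        group).  Defaults to the four seminatural groups.
    class_tag
        Label stored on the returned :class:`LineSet`.
    """
    if isinstance(class_sets, (set, frozenset)):
        class_sets = [class_sets]
    if len(class_sets) == 0:
        raise ValueError("class_sets must be nonempty")
    declared = CLC_CODES | set(np.unique(grid.values).tolist())
    for cs_ in class_sets:
        if len(set(cs_) - declared) > 0:
            raise ValueError(f"unknown class codes: {sorted(set(cs_) - declared)}")

    all_faces = [ _class_faces(grid, set(cs_)) for cs_ in class_sets ]
    faces = np.unique(np.concatenate(all_faces, axis=0), axis=0)
    segments = _faces_to_segments(faces, grid)
    return LineSet(
        segments,
        class_tag=class_tag,
        faces=faces,
        source_cell_size=grid.cell_size,
        source_origin=grid.origin,
        source_shape=grid.shape,
    )


def nonforest_length(all_lls: LineSet, forest: LineSet) -> float:
    """Length of nonforest seminatural LLS, meters.

    The length of forest edges is subtracted from the length of all
    seminatural LLS; floored at zero.
    """
    return max(all_lls.total_length - forest.total_length, 0.0)


# ---------------------------------------------------------------------------
# rasterization


def _segment_cells(
    p: np.ndarray, q: np.ndarray, cell_size: float, origin: tuple[float, float],
    n_rows: int, n_cols: int,
) -> list[tuple[int, int]]:
    """Closed-square cells intersected by segment p–q (Liang–Barsky clip).

    Cells are closed, so a segment running along the shared edge of two
    cells marks both.
    """
    x0, y0 = origin
    eps = 1e-9 * cell_size
    lo = np.minimum(p, q)
    hi = np.maximum(p, q)
    c_min = max(int(np.floor((lo[0] - x0 - eps) / cell_size)), 0)
    c_max = min(int(np.floor((hi[0] - x0 + eps) / cell_size)), n_cols - 1)
    rb_min = max(int(np.floor((lo[1] - y0 - eps) / cell_size)), 0)
    rb_max = min(int(np.floor((hi[1] - y0 + eps) / cell_size)), n_rows - 1)
    d = q - p
    out = []
    for rb in range(rb_min, rb_max + 1):
        ylo, yhi = y0 + rb * cell_size, y0 + (rb + 1) * cell_size
        for c in range(c_min, c_max + 1):
            xlo, xhi = x0 + c * cell_size, x0 + (c + 1) * cell_size
            t0, t1 = 0.0, 1.0
            ok = True
            for axis, (alo, ahi) in enumerate(((xlo, xhi), (ylo, yhi))):
                if abs(d[axis]) < eps:
                    if p[axis] < alo - eps or p[axis] > ahi + eps:
                        ok = False
                        break
                else:
                    ta = (alo - p[axis]) / d[axis]
                    tb = (ahi - p[axis]) / d[axis]
                    if ta > tb:
                        ta, tb = tb, ta
                    t0 = max(t0, ta)
                    t1 = min(t1, tb)
            if ok and t0 <= t1 + 1e-12:
                out.append((n_rows - 1 - rb, c))
    return out


def rasterize_lines(
    lines: LineSet,
    cell_size: float,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> BinaryFeatureGrid:
    """Burn polylines into a 0/1 raster: a cell is 1 iff any segment
    intersects its closed square.

    When ``origin``/``shape`` are omitted they are taken from the source
    grid of a boundary-extracted line set, or otherwise derived from the
    bounding box of the lines.  Boundary faces extracted from a raster of
    the same geometry are marked exactly (each face marks the two cells
    that share it).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if origin is None and lines.source_origin is not None:
        origin = lines.source_origin
        if shape is None and cell_size == lines.source_cell_size:
            shape = lines.source_shape
    if shape is None:
        if len(lines.segments) == 0:
            return BinaryFeatureGrid(np.zeros((1, 1)), cell_size, origin or (0.0, 0.0))
        allv = np.concatenate(lines.segments, axis=0)
        if origin is None:
            origin = (
                float(np.floor(allv[:, 0].min() / cell_size) * cell_size),
                float(np.floor(allv[:, 1].min() / cell_size) * cell_size),
            )
        n_cols = max(int(np.ceil((allv[:, 0].max() - origin[0]) / cell_size)), 1)
        n_rows = max(int(np.ceil((allv[:, 1].max() - origin[1]) / cell_size)), 1)
        shape = (n_rows, n_cols)
    n_rows, n_cols = shape
    values = np.zeros(shape, dtype=np.uint8)

    # exact fast path for boundary faces on the same grid geometry: a
    # face marks the two cells sharing it, and (closed-cell semantics)
    # the cells whose corners touch its endpoints
    if (
        lines.faces is not None
        and lines.source_cell_size == cell_size
        and lines.source_origin == origin
        and lines.source_shape == shape
    ):
        orient, rows, cols = lines.faces.T
        v = orient == 0
        h = orient == 1
        for dr, dc in ((dr, dc) for dr in (-1, 0, 1) for dc in (0, 1)):
            r = rows[v] + dr
            c = cols[v] + dc
            ok = (r >= 0) & (r < n_rows) & (c >= 0) & (c < n_cols)
            values[r[ok], c[ok]] = 1
        for dr, dc in ((dr, dc) for dr in (0, 1) for dc in (-1, 0, 1)):
            r = rows[h] + dr
            c = cols[h] + dc
            ok = (r >= 0) & (r < n_rows) & (c >= 0) & (c < n_cols)
            values[r[ok], c[ok]] = 1
        return BinaryFeatureGrid(values, cell_size, origin)

    for seg in lines.segments:
        for p, q in zip(seg[:-1], seg[1:]):
            for r, c in _segment_cells(p, q, cell_size, origin, n_rows, n_cols):
                values[r, c] = 1
    return BinaryFeatureGrid(values, cell_size, origin)


def aggregate_proportion(fine: BinaryFeatureGrid, factor: int) -> ProportionGrid:
    """Aggregate a fine 0/1 grid into a coarse grid of fractions.

    Each coarse cell holds the count of fine 1-cells in its
    ``factor x factor`` block divided by ``factor**2``.  Grids not
    divisible by the factor are zero-padded at the top and right, which
    never adds 1-cells, so the total count is conserved exactly.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    vals = fine.values
    n_rows, n_cols = vals.shape
    pad_r = (-n_rows) % factor
    pad_c = (-n_cols) % factor
    if pad_r or pad_c:
        vals = np.pad(vals, ((pad_r, 0), (0, pad_c)))
    nr, nc = vals.shape[0] // factor, vals.shape[1] // factor
    counts = vals.reshape(nr, factor, nc, factor).sum(axis=(1, 3))
    return ProportionGrid(
        counts / factor**2,
        cell_size=fine.cell_size * factor,
        origin=fine.origin,
        factor=factor,
    )


# ---------------------------------------------------------------------------
# per-site landscape metrics


def length_within_radius(
    lines: LineSet, center: tuple[float, float], radius: float
) -> float:
    """Total length (m) of line segments clipped to the closed disc of
    ``radius`` around ``center``.

    Clipping is analytic: each segment's in-disc parameter interval is the
    solution of one quadratic, so the result is exact up to floating point.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0 or len(lines.segments) == 0:
        return 0.0
    cx, cy = center
    p0, q0 = lines._stacked()
    p = p0 - (cx, cy)
    q = q0 - (cx, cy)
    d = q - p
    a = (d**2).sum(axis=1)
    b = (p * d).sum(axis=1)
    c = (p**2).sum(axis=1) - radius**2
    deg = a <= 0  # zero-length pieces contribute nothing
    disc = b**2 - a * c
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(np.maximum(disc, 0.0))
        t0 = np.clip((-b - sq) / np.where(a > 0, a, 1.0), 0.0, 1.0)
        t1 = np.clip((-b + sq) / np.where(a > 0, a, 1.0), 0.0, 1.0)
    inside = (disc > 0) & ~deg
    seg_len = np.sqrt(a, where=a > 0, out=np.zeros_like(a))
    length = float(((t1 - t0) * seg_len)[inside].sum())
    return length


def grassland_proportion(
    grid: LandCoverGrid,
    center: tuple[float, float],
    radius: float,
    grassland_code: int = GRASSLAND_CODE,
) -> float:
    """Fraction of valid cells with centers inside the disc that carry the
    grassland (permanent herbaceous) code."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    xs, ys = grid.cell_centers()
    cx, cy = center
    in_disc = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    valid = in_disc & (grid.values != grid.nodata)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("disc contains no cell centers")
    return float((grid.values[valid] == grassland_code).sum() / n)
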