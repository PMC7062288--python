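"""Brain tissue domain: gray/white/empty raster plus the two overlay lattices.

The simulated brain is a 2D raster in which every pixel is gray matter,
white matter, or empty space (ventricles, outside the brain).  Two lattices
are laid over the raster:

* a coarse square *density mesh* (100 μm spacing) used for carrying-capacity
  / quiescence checks, and
* a fine *hexagonal lattice* (node radius 12.5 μm = one cell radius, so
  25 μm center-to-center) carrying the PDGF concentration field.

Continuous cell positions are in μm with the origin at the raster top-left,
x increasing rightwards and y downwards (image convention).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

EMPTY = 0
GRAY = 1
WHITE = 2

#: grayscale encoding used by the raster files we read and write
RASTER_ENCODING = {0: EMPTY, 128: GRAY, 255: WHITE}
RASTER_DECODING = {EMPTY: 0, GRAY: 128, WHITE: 255}

CELL_RADIUS_UM = 12.5
HEX_SPACING_UM = 2.0 * CELL_RADIUS_UM  # one cell diameter between node centers
DENSITY_SPACING_UM = 100.0

_SQRT3_2 = math.sqrt(3.0) / 2.0


class OutsideTissueError(ValueError):
    """A position fell on an EMPTY pixel or outside the raster."""


@dataclasses.dataclass
class TissueDomain:
    """Tissue raster plus the square density mesh and hexagonal PDGF mesh.

    The hexagonal lattice is "pointy-top" with rows spaced ``h*sqrt(3)/2``
    apart and odd rows shifted by ``h/2``; nodes whose center pixel is EMPTY
    are masked out of the lattice.  Node ids are flat ``row*ncols + col``
    indices into the full rectangular array; masked nodes keep their id but
    never appear as a nearest node and carry no field value.
    """

    tissue_class: np.ndarray  # (H, W) uint8 of EMPTY/GRAY/WHITE
    px_size: float  # μm per pixel

    def __post_init__(self) -> None:
        self.tissue_class = np.ascontiguousarray(self.tissue_class, dtype=np.uint8)
        if self.px_size <= 0:
            raise ValueError("px_size must be positive")
        self.height_px, self.width_px = self.tissue_class.shape
        self.width_um = self.width_px * self.px_size
        self.height_um = self.height_px * self.px_size
        self._build_hex_lattice()
        self._build_density_mesh()

    # ------------------------------------------------------------------ hex
    def _build_hex_lattice(self) -> None:
        h = HEX_SPACING_UM
        self.hex_spacing = h
        row_pitch = h * _SQRT3_2
        self.hex_nrows = int(self.height_um / row_pitch) + 1
        self.hex_ncols = int(self.width_um / h) + 1
        rows = np.arange(self.hex_nrows)
        cols = np.arange(self.hex_ncols)
        cgrid, rgrid = np.meshgrid(cols, rows)
        self.hex_x = cgrid * h + (rgrid % 2) * (h / 2.0)
        self.hex_y = rgrid * row_pitch
        cls = self._class_at_pixels(self.hex_x.ravel(), self.hex_y.ravel())
        self.hex_in_tissue = (cls != EMPTY).reshape(self.hex_nrows, self.hex_ncols)
        self.n_hex = self.hex_nrows * self.hex_ncols
        self._build_hex_neighbors()

    def _build_hex_neighbors(self) -> None:
        """(n_hex, 6) flat neighbor ids; -1 where the neighbor is missing."""
        R, C = self.hex_nrows, self.hex_ncols
        rgrid, cgrid = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
        parity = rgrid % 2
        # pointy-top, odd rows shifted right: E, W, NE, NW, SE, SW
        offs_r = [rgrid, rgrid,
                  rgrid - 1, rgrid - 1, rgrid + 1, rgrid + 1]
        offs_c = [cgrid + 1, cgrid - 1,
                  cgrid + parity, cgrid + parity - 1,
                  cgrid + parity, cgrid + parity - 1]
        nbr = np.empty((R, C, 6), dtype=np.int64)
        in_tissue = self.hex_in_tissue
        for k, (nr, nc) in enumerate(zip(offs_r, offs_c)):
            valid = (nr >= 0) & (nr < R) & (nc >= 0) & (nc < C)
            flat = np.where(valid, nr.clip(0, R - 1) * C + nc.clip(0, C - 1), -1)
            # neighbors outside tissue are treated as missing (no-flux)
            ok = valid & in_tissue[nr.clip(0, R - 1), nc.clip(0, C - 1)]
            nbr[..., k] = np.where(ok, flat, -1)
        nbr[~in_tissue] = -1
        self.hex_neighbors = nbr.reshape(-1, 6)

    def nearest_hex_node(self, x, y):
        """Flat id of the nearest in-tissue hex node; ties -> lowest id.

        Raises :class:`OutsideTissueError` for positions on EMPTY pixels.
        """
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        y = np.atleast_1d(np.asarray(y, dtype=np.float64))
        if np.any(self._class_at_pixels(x, y) == EMPTY):
            raise OutsideTissueError("position outside tissue")
        idx = self._nearest_hex_unchecked(x, y)
        return idx if idx.size > 1 else int(idx[0])

    def _nearest_hex_unchecked(self, x, y):
        h = self.hex_spacing
        row_pitch = h * _SQRT3_2
        r0 = np.rint(y / row_pitch).astype(np.int64)
        c0 = np.rint((x - (r0 % 2) * (h / 2.0)) / h).astype(np.int64)
        best_d = np.full(x.shape, np.inf)
        best_id = np.full(x.shape, -1, dtype=np.int64)
        R, C = self.hex_nrows, self.hex_ncols
        flat_x = self.hex_x.ravel()
        flat_y = self.hex_y.ravel()
        flat_ok = self.hex_in_tissue.ravel()
        # candidates scanned in increasing flat id so that a strict '<'
        # implements the ties-to-lowest-id rule
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r = r0 + dr
                c = c0 + dc
                valid = (r >= 0) & (r < R) & (c >= 0) & (c < C)
                fid = np.where(valid, r.clip(0, R - 1) * C + c.clip(0, C - 1), 0)
                ok = valid & flat_ok[fid]
                d = np.where(ok, (flat_x[fid] - x) ** 2 + (flat_y[fid] - y) ** 2, np.inf)
                upd = d < best_d
                best_d = np.where(upd, d, best_d)
                best_id = np.where(upd, fid, best_id)
        if np.any(best_id < 0):
            raise OutsideTissueError("no in-tissue hex node near position")
        return best_id

    # -------------------------------------------------------------- density
    def _build_density_mesh(self) -> None:
        s = DENSITY_SPACING_UM
        self.density_spacing = s
        self.dens_nrows = int(math.ceil(self.height_um / s))
        self.dens_ncols = int(math.ceil(self.width_um / s))
        self.n_density = self.dens_nrows * self.dens_ncols
        # node class by majority vote over its non-empty pixels; pixels are
        # assigned to nodes through their centers so non-divisor px sizes
        # cannot drift
        H, W = self.tissue_class.shape
        px_x = (np.arange(W) + 0.5) * self.px_size
        px_y = (np.arange(H) + 0.5) * self.px_size
        node_c = np.floor(px_x / s).astype(np.int64).clip(0, self.dens_ncols - 1)
        node_r = np.floor(px_y / s).astype(np.int64).clip(0, self.dens_nrows - 1)
        flat = (node_r[:, None] * self.dens_ncols + node_c[None, :]).ravel()
        tc = self.tissue_class.ravel()
        n_gray = np.bincount(flat[tc == GRAY], minlength=self.n_density)
        n_white = np.bincount(flat[tc == WHITE], minlength=self.n_density)
        cls = np.where(n_gray + n_white == 0, EMPTY,
                       np.where(n_white > n_gray, WHITE, GRAY)).astype(np.uint8)
        self.density_class = cls.reshape(self.dens_nrows, self.dens_ncols)

    def nearest_density_node(self, x, y):
        """Flat id of the density node containing/nearest the position.

        Node centers sit at ``(i+0.5)*100 μm``; points exactly on a node
        boundary resolve to the lower node id.
        """
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        y = np.atleast_1d(np.asarray(y, dtype=np.float64))
        if np.any(self._class_at_pixels(x, y) == EMPTY):
            raise OutsideTissueError("position outside tissue")
        idx = self._nearest_density_unchecked(x, y)
        return idx if idx.size > 1 else int(idx[0])

    def _nearest_density_unchecked(self, x, y):
        s = self.density_spacing
        cx = x / s
        cy = y / s
        c = np.floor(cx).astype(np.int64)
        r = np.floor(cy).astype(np.int64)
        # exact boundary -> lower id
        c = np.where((cx == c) & (c > 0), c - 1, c)
        r = np.where((cy == r) & (r > 0), r - 1, r)
        c = c.clip(0, self.dens_ncols - 1)
        r = r.clip(0, self.dens_nrows - 1)
        return r * self.dens_ncols + c

    def capacity_map(self, kappa: float) -> np.ndarray:
        """Per-density-node carrying capacity: κ in gray, 2κ/3 in white."""
        cap = np.zeros(self.n_density, dtype=np.float64)
        cls = self.density_class.ravel()
        cap[cls == GRAY] = kappa
        cap[cls == WHITE] = 2.0 * kappa / 3.0
        return cap

    # ---------------------------------------------------------------- pixel
    def _class_at_pixels(self, x, y):
        px = np.floor(np.asarray(x) / self.px_size).astype(np.int64)
        py = np.floor(np.asarray(y) / self.px_size).astype(np.int64)
        inside = (px >= 0) & (px < self.width_px) & (py >= 0) & (py < self.height_px)
        out = np.full(np.shape(px), EMPTY, dtype=np.uint8)
        pxc = px.clip(0, self.width_px - 1)
        pyc = py.clip(0, self.height_px - 1)
        out[...] = np.where(inside, self.tissue_class[pyc, pxc], EMPTY)
        return out

    def tissue_class_at(self, x, y):
        """GRAY/WHITE/EMPTY label at continuous positions (μm)."""
        return self._class_at_pixels(np.atleast_1d(x), np.atleast_1d(y))

    def in_tissue(self, x, y):
        return self.tissue_class_at(x, y) != EMPTY

    # ------------------------------------------------------------------- io
    def write_raster(self, path) -> None:
        """Write the tissue raster as an ASCII (P2) PGM file."""
        img = np.zeros_like(self.tissue_class)
        for label, value in RASTER_DECODING.items():
            img[self.tissue_class == label] = value
        with open(path, "w") as fh:
            fh.write(f"P2\n{self.width_px} {self.height_px}\n255\n")
            for row in img:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")


def _read_gray_image(path) -> np.ndarray:
    text_magic = None
    with open(path, "rb") as fh:
        text_magic = fh.read(2)
    if text_magic == b"P2":  # ASCII PGM: trivial text format, parsed directly
        with open(path) as fh:
            tokens = []
            for line in fh:
                line = line.split("#", 1)[0]
                tokens.extend(line.split())
        if tokens[0] != "P2":
            raise ValueError("not a P2 PGM file")
        w, h = int(tokens[1]), int(tokens[2])
        data = np.array(tokens[4: 4 + w * h], dtype=np.int64)
        return data.reshape(h, w)
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img.astype(np.int64)


def load_tissue_raster(path, px_size: float) -> TissueDomain:
    """Load a gray/white/empty tissue raster (PGM or PNG).

    Label encoding: 0 = EMPTY, 128 = GRAY, 255 = WHITE.  Any other pixel
    value is rejected.
    """
    if px_size <= 0:
        raise ValueError("px_size must be positive")
    img = _read_gray_image(path)
    values = np.unique(img)
    bad = [int(v) for v in values if int(v) not in RASTER_ENCODING]
    if bad:
        raise ValueError(
            f"unknown raster labels {bad}; admissible encoding is "
            "0=EMPTY, 128=GRAY, 255=WHITE"
        )
    if len(values) < 2:
        raise ValueError("raster must contain at least two distinct labels")
    cls = np.zeros_like(img, dtype=np.uint8)
    for value, label in RASTER_ENCODING.items():
        cls[img == value] = label
    return TissueDomain(tissue_class=cls, px_size=px_size)


def default_synthetic_brain(seed: int = 0) -> TissueDomain:
    """The package's standard synthetic brain slice: 10 x 8 mm of gray
    matter crossed by a 1-mm white-matter band through the center (where
    tumors are injected), at 25 μm/px."""
    return make_synthetic_brain(
        10.0, 8.0,
        tract_spec={"center_frac": 0.5, "thickness_mm": 1.0},
        seed=seed,
    )


def make_synthetic_brain(
    width_mm: float,
    height_mm: float,
    tract_spec: dict | None = None,
    ventricle_spec: list[dict] | None = None,
    seed: int = 0,
    px_size: float = 25.0,
) -> TissueDomain:
    """Generate a synthetic tissue map: gray field + white-matter band + holes.

    ``tract_spec`` describes one horizontal white-matter band (a synthetic
    corpus callosum): ``{"center_frac": 0.5, "thickness_mm": 1.0,
    "wobble_mm": 0.0}``; ``wobble_mm`` adds a seeded smooth sinusoidal
    undulation of the band edges.  ``ventricle_spec`` is a list of circular
    EMPTY holes: ``{"x_frac": .., "y_frac": .., "radius_mm": ..}``.
    """
    if width_mm <= 0 or height_mm <= 0:
        raise ValueError("domain dimensions must be positive")
    rng = np.random.default_rng(seed)
    W = int(round(width_mm * 1000.0 / px_size))
    H = int(round(height_mm * 1000.0 / px_size))
    cls = np.full((H, W), GRAY, dtype=np.uint8)
    if tract_spec is not None:
        center = float(tract_spec.get("center_frac", 0.5)) * H
        half = float(tract_spec["thickness_mm"]) * 1000.0 / px_size / 2.0
        if 2 * half > H:
            raise ValueError("tract thicker than the domain")
        wobble_px = float(tract_spec.get("wobble_mm", 0.0)) * 1000.0 / px_size
        phase = rng.uniform(0, 2 * np.pi)
        xs = np.arange(W)
        mid = center + wobble_px * np.sin(2 * np.pi * xs / W + phase)
        ys = np.arange(H)[:, None]
        band = np.abs(ys - mid[None, :]) <= half
        cls[band] = WHITE
    for hole in ventricle_spec or []:
        cx = float(hole["x_frac"]) * W
        cy = float(hole["y_frac"]) * H
        r = float(hole["radius_mm"]) * 1000.0 / px_size
        if cx - r < 0 or cx + r > W or cy - r < 0 or cy + r > H:
            raise ValueError("ventricle does not fit inside the domain")
        ys, xs = np.ogrid[:H, :W]
        cls[(xs - cx) ** 2 + (ys - cy) ** 2 <= r**2] = EMPTY
    return TissueDomain(tissue_class=cls, px_size=px_size)
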