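"""Confluent layered polyhedral tissues built from periodic Voronoi diagrams.

A tissue is a space-filling collection of polyhedral cells in a slab that is
periodic in x and y.  The slab is closed at the bottom (basement membrane
floor, ``z_min``) and top (ghost-layer ceiling, ``z_max``) by mirror seeds,
which produce exactly planar wall faces.  Bulk tissues used for droplet
rheometry are periodic in all three directions instead.

The degrees of freedom are the shared Voronoi vertices.  Topology (which
vertices bound which face, which faces bound which cell) is frozen between
re-tessellations; neighbour exchanges happen when the tessellation is rebuilt
from the current cell centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

from ._kernels import cell_geometry_kernel, face_area_kernel

# cell type codes
BASEMENT, BASAL, SUPRABASAL, GHOST, DROPLET = 0, 1, 2, 3, 4
TYPE_NAMES = {BASEMENT: "basement", BASAL: "basal", SUPRABASAL: "suprabasal",
              GHOST: "ghost", DROPLET: "droplet"}
TYPE_CODES = {v: k for k, v in TYPE_NAMES.items()}

WALL_BOTTOM, WALL_TOP = -1, -2


class TessellationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PeriodicBox:
    """Simulation box: periodic in x-y, a bounded slab in z (or fully periodic)."""

    Lx: float
    Ly: float
    z_min: float
    z_max: float
    periodic_z: bool = False

    def __post_init__(self):
        if self.Lx <= 0 or self.Ly <= 0 or self.z_max <= self.z_min:
            raise ValueError("degenerate box")

    @property
    def Lz(self) -> float:
        return self.z_max - self.z_min

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.Lz

    @property
    def lattice(self) -> np.ndarray:
        """Lattice translation lengths per axis (0 for the non-periodic z of a slab)."""
        return np.array([self.Lx, self.Ly, self.Lz if self.periodic_z else 0.0])

    def minimal_image(self, d: np.ndarray) -> np.ndarray:
        """Minimal-image convention applied to displacement vectors (last axis xyz)."""
        d = np.asarray(d, dtype=float).copy()
        d[..., 0] -= self.Lx * np.round(d[..., 0] / self.Lx)
        d[..., 1] -= self.Ly * np.round(d[..., 1] / self.Ly)
        if self.periodic_z:
            d[..., 2] -= self.Lz * np.round(d[..., 2] / self.Lz)
        return d


@dataclass
class Cell:
    """View of one cell's metadata (the arrays in Tessellation are authoritative)."""

    id: int
    type: str
    seed: np.ndarray
    V0: float
    S0: float
    alpha: float
    face_ids: np.ndarray


@dataclass
class EllipsoidFit:
    semi_axes: np.ndarray          # descending
    principal_axes: np.ndarray     # rows, orthonormal, matching semi_axes
    theta_long: float              # angle of longest axis to the basal plane, [0, pi/2]
    degenerate: bool


class Tessellation:
    """Periodic polyhedral complex with per-cell metadata.

    Attributes (arrays indexed by compact cell index unless stated):
      verts          (Nv,3) vertex positions, the dynamical degrees of freedom
      pinned         (Nv,) bool
      face_offsets   (F+1,) CSR offsets into face_vidx/face_shift
      face_vidx      vertex ids per face, wound outward from face_cells[:,0]
      face_shift     per-reference lattice displacement vectors
      face_cells     (F,2) adjacent cell indices; WALL_BOTTOM/WALL_TOP for slab walls
      face_pair_shift (F,3) translation: c2's copy of the face = stored - pair_shift
      cell_ids, cell_type, seed, V0, S0, alpha : per-cell metadata
    """

    def __init__(self, box, verts, pinned, face_offsets, face_vidx, face_shift,
                 face_cells, face_pair_shift, cell_ids, cell_type, seed, V0, S0, alpha):
        self.box = box
        self.verts = np.ascontiguousarray(verts, dtype=np.float64)
        self.pinned = np.asarray(pinned, dtype=bool)
        self.face_offsets = np.ascontiguousarray(face_offsets, dtype=np.int64)
        self.face_vidx = np.ascontiguousarray(face_vidx, dtype=np.int64)
        self.face_shift = np.ascontiguousarray(face_shift, dtype=np.float64)
        self.face_cells = np.ascontiguousarray(face_cells, dtype=np.int64)
        self.face_pair_shift = np.ascontiguousarray(face_pair_shift, dtype=np.float64)
        self.cell_ids = np.asarray(cell_ids, dtype=np.int64)
        self.cell_type = np.asarray(cell_type, dtype=np.int64)
        self.seed = np.ascontiguousarray(seed, dtype=np.float64)
        self.V0 = np.asarray(V0, dtype=np.float64)
        self.S0 = np.asarray(S0, dtype=np.float64)
        self.alpha = np.asarray(alpha, dtype=np.float64)
        self.id_to_index = {int(cid): i for i, cid in enumerate(self.cell_ids)}
        self._build_cell_faces()
        self._geom_cache = None

    # -- construction helpers ------------------------------------------------

    def _build_cell_faces(self):
        C = len(self.cell_ids)
        F = len(self.face_cells)
        inner = self.face_cells[:, 1] >= 0
        cells = np.concatenate([self.face_cells[:, 0], self.face_cells[inner, 1]])
        faces = np.concatenate([np.arange(F), np.arange(F)[inner]])
        sides = np.concatenate([np.ones(F, dtype=np.int64),
                                -np.ones(int(inner.sum()), dtype=np.int64)])
        order = np.argsort(cells, kind="stable")
        self.cf_faces = faces[order]
        self.cf_side = sides[order]
        counts = np.bincount(cells, minlength=C)
        self.cf_offsets = np.zeros(C + 1, dtype=np.int64)
        np.cumsum(counts, out=self.cf_offsets[1:])

    # -- geometry ------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_vertices(self) -> int:
        return len(self.verts)

    def invalidate(self):
        self._geom_cache = None

    def geometry(self):
        """(volumes, surface areas, centroids) for all cells, cached per vertex state."""
        if self._geom_cache is None:
            vol, area, cen = cell_geometry_kernel(
                self.verts, self.face_offsets, self.face_vidx, self.face_shift,
                self.face_pair_shift, self.cf_offsets, self.cf_faces, self.cf_side,
                self.seed,
            )
            self._geom_cache = (vol, area, cen)
        return self._geom_cache

    def face_areas(self) -> np.ndarray:
        return face_area_kernel(self.verts, self.face_offsets, self.face_vidx,
                                self.face_shift)

    def cell(self, cell_id: int) -> Cell:
        i = self.id_to_index[int(cell_id)]
        faces = self.cf_faces[self.cf_offsets[i]:self.cf_offsets[i + 1]]
        return Cell(id=int(cell_id), type=TYPE_NAMES[int(self.cell_type[i])],
                    seed=self.seed[i].copy(), V0=float(self.V0[i]),
                    S0=float(self.S0[i]), alpha=float(self.alpha[i]),
                    face_ids=faces.copy())

    def cell_vertex_positions(self, index: int) -> np.ndarray:
        """Unique vertex positions of one cell, in that cell's local frame."""
        rows = []
        seen = set()
        for j in range(self.cf_offsets[index], self.cf_offsets[index + 1]):
            f = self.cf_faces[j]
            side = self.cf_side[j]
            b0, b1 = self.face_offsets[f], self.face_offsets[f + 1]
            for k in range(b0, b1):
                p = self.verts[self.face_vidx[k]] + self.face_shift[k]
                if side < 0:
                    p = p - self.face_pair_shift[f]
                key = (round(p[0], 9), round(p[1], 9), round(p[2], 9))
                if key in seen:
                    continue
                seen.add(key)
                rows.append(p)
        return np.array(rows)

    def cell_vertex_ids(self, index: int) -> np.ndarray:
        j0, j1 = self.cf_offsets[index], self.cf_offsets[index + 1]
        ids = []
        for j in range(j0, j1):
            f = self.cf_faces[j]
            ids.append(self.face_vidx[self.face_offsets[f]:self.face_offsets[f + 1]])
        return np.unique(np.concatenate(ids))

    def neighbors(self, index: int) -> np.ndarray:
        """Adjacent cell indices (walls excluded)."""
        out = []
        for j in range(self.cf_offsets[index], self.cf_offsets[index + 1]):
            f = self.cf_faces[j]
            c1, c2 = self.face_cells[f]
            other = c2 if c1 == index else c1
            if other >= 0:
                out.append(other)
        return np.unique(np.array(out, dtype=np.int64))

    def total_volume(self) -> float:
        vol, _, _ = self.geometry()
        return float(vol.sum())

    def confluence_defect(self) -> float:
        """Relative mismatch between summed cell volumes and the box volume."""
        return abs(self.total_volume() - self.box.volume) / self.box.volume

    # -- metadata mutation ---------------------------------------------------

    def set_type(self, index: int, type_code: int, s0: float | None = None):
        """Switch a cell's identity; optionally re-derive S0 from a target shape index."""
        self.cell_type[index] = type_code
        if s0 is not None:
            self.S0[index] = s0 * self.V0[index] ** (2.0 / 3.0)


# ---------------------------------------------------------------------------
# Voronoi mesh construction
# ---------------------------------------------------------------------------

def _extended_points(seeds: np.ndarray, box: PeriodicBox, margin: float):
    """Replicate seeds into periodic images (within `margin` of a boundary) and
    mirror seeds across z walls for slab geometry.

    Returns (points, orig, shift) where orig < 0 flags wall mirrors.
    """
    N = len(seeds)
    pts = [seeds]
    orig = [np.arange(N, dtype=np.int64)]
    shifts = [np.zeros((N, 3), dtype=np.int64)]
    zrange = (-1, 0, 1) if box.periodic_z else (0,)
    L = np.array([box.Lx, box.Ly, box.Lz])
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in zrange:
                if ix == 0 and iy == 0 and iz == 0:
                    continue
                p = seeds + np.array([ix, iy, iz]) * L
                keep = np.ones(N, dtype=bool)
                keep &= (p[:, 0] > -margin) & (p[:, 0] < box.Lx + margin)
                keep &= (p[:, 1] > -margin) & (p[:, 1] < box.Ly + margin)
                if box.periodic_z:
                    keep &= (p[:, 2] > box.z_min - margin) & (p[:, 2] < box.z_max + margin)
                if keep.any():
                    pts.append(p[keep])
                    orig.append(np.where(keep)[0].astype(np.int64))
                    s = np.tile(np.array([ix, iy, iz], dtype=np.int64), (int(keep.sum()), 1))
                    shifts.append(s)
    if not box.periodic_z:
        allp = np.concatenate(pts)
        # mirror across both walls to close the slab with planar faces
        for zwall, code in ((box.z_min, WALL_BOTTOM), (box.z_max, WALL_TOP)):
            near = np.abs(allp[:, 2] - zwall) < margin
            mir = allp[near].copy()
            mir[:, 2] = 2.0 * zwall - mir[:, 2]
            pts.append(mir)
            orig.append(np.full(len(mir), code, dtype=np.int64))
            shifts.append(np.zeros((len(mir), 3), dtype=np.int64))
    return np.concatenate(pts), np.concatenate(orig), np.concatenate(shifts)


def _build_mesh(seeds: np.ndarray, box: PeriodicBox, margin: float):
    """Build periodic mesh topology from seed points.

    Returns dict of arrays for the Tessellation constructor (minus metadata).
    Raises TessellationError when the image margin was insufficient.
    """
    N = len(seeds)
    pts, orig, shifts = _extended_points(seeds, box, margin)
    vor = Voronoi(pts)
    L = box.lattice
    rp = np.asarray(vor.ridge_points, dtype=np.int64)
    rv = vor.ridge_vertices
    R = len(rp)

    # normalize so that endpoint 0 is central where possible
    p = rp[:, 0].copy()
    q = rp[:, 1].copy()
    swap = (q < N) & (p >= N)
    p[swap], q[swap] = rp[swap, 1], rp[swap, 0]
    central = p < N
    o = orig[q]
    S = shifts[q]

    both = central & (q < N)
    wall = central & (o < 0)
    img = central & (q >= N) & (o >= 0)
    lexpos = (S[:, 0] > 0) | ((S[:, 0] == 0) & ((S[:, 1] > 0) |
             ((S[:, 1] == 0) & (S[:, 2] > 0))))
    keepimg = img & ((p < o) | ((p == o) & lexpos))
    dupimg = img & ~keepimg
    kept_mask = both | wall | keepimg

    kept_r = np.where(kept_mask)[0]
    canon = {}
    for r in kept_r[keepimg[kept_r]]:
        canon[(int(p[r]), int(o[r]), (int(S[r, 0]), int(S[r, 1]), int(S[r, 2])))] = r

    # ragged ridge-vertex storage -> flat + offsets for fast padded gathers
    rlens = np.fromiter((len(x) for x in rv), dtype=np.int64, count=R)
    roff = np.zeros(R + 1, dtype=np.int64)
    np.cumsum(rlens, out=roff[1:])
    rflat = np.fromiter((v for x in rv for v in x), dtype=np.int64, count=roff[-1])

    def _pad(ridx):
        m = rlens[ridx]
        mm = int(m.max()) if len(m) else 0
        idx = roff[ridx][:, None] + np.arange(mm)[None, :]
        valid = np.arange(mm)[None, :] < m[:, None]
        vals = rflat[np.where(valid, idx, 0)]
        return np.where(valid, vals, -1), valid

    # stitch periodic copies of shared vertices: each duplicate (non-canonical)
    # boundary ridge identifies its vertices with the canonical copy's, shifted
    # by a whole lattice vector
    nvor = len(vor.vertices)
    dup_rows = np.where(dupimg)[0]
    ea = eb = None
    if len(dup_rows):
        rc_list = np.empty(len(dup_rows), dtype=np.int64)
        for t, r in enumerate(dup_rows):
            # canonical face: between cell o (frame 0) and cell p at shift -S
            key = (int(o[r]), int(p[r]),
                   (-int(S[r, 0]), -int(S[r, 1]), -int(S[r, 2])))
            rc = canon.get(key, -1)
            rc_list[t] = rc
        if (rc_list < 0).any() or (rlens[rc_list] != rlens[dup_rows]).any():
            raise TessellationError("missing canonical partner ridge; margin too small")
        dv_pad, dmask = _pad(dup_rows)
        cv_pad, cmask = _pad(rc_list)
        if (dv_pad[dmask] < 0).any() or (cv_pad[cmask] < 0).any():
            raise TessellationError("unbounded boundary ridge; margin too small")
        # canonical translated into dup frame; copies agree to round-off while
        # distinct vertices are O(cell size) apart, so nearest matching is exact
        Svec = S[dup_rows].astype(float) * L
        cpos = vor.vertices[np.maximum(cv_pad, 0)] + Svec[:, None, :]
        dpos = vor.vertices[np.maximum(dv_pad, 0)]
        d2 = ((dpos[:, :, None, :] - cpos[:, None, :, :]) ** 2).sum(axis=3)
        d2 = np.where(cmask[:, None, :], d2, np.inf)
        match = d2.argmin(axis=2)
        mind = np.take_along_axis(d2, match[:, :, None], axis=2)[:, :, 0]
        if mind[dmask].max() > (1e-6 * max(1.0, L.max())) ** 2:
            raise TessellationError("ambiguous periodic vertex match")
        sm = np.sort(np.where(dmask, match, -1), axis=1)
        if ((sm[:, 1:] == sm[:, :-1]) & (sm[:, 1:] >= 0)).any():
            raise TessellationError("ambiguous periodic vertex match")
        ea = dv_pad[dmask]
        eb = np.take_along_axis(cv_pad, match, axis=1)[dmask]
    root_of = np.arange(nvor, dtype=np.int64)
    off_of = np.zeros((nvor, 3), dtype=np.int64)
    if ea is not None and len(ea):
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components
        g = coo_matrix((np.ones(len(ea)), (ea, eb)), shape=(nvor, nvor))
        _, labels = connected_components(g, directed=False)
        touched = np.unique(np.concatenate([ea, eb]))
        # representative per component = smallest touched vor index
        rep: dict[int, int] = {}
        for v in touched:
            lab = labels[v]
            if lab not in rep:
                rep[lab] = int(v)
        reps = np.array([rep[labels[v]] for v in touched], dtype=np.int64)
        root_of[touched] = reps
        # offsets are exact lattice multiples of the position differences
        Lsafe = np.where(L > 0, L, 1.0)
        diff = vor.vertices[touched] - vor.vertices[reps]
        offs = np.round(diff / Lsafe) * (L > 0)
        if np.abs(diff - offs * L).max() > 1e-6 * max(1.0, L.max()):
            raise TessellationError("periodic vertex stitch inconsistency")
        off_of[touched] = offs.astype(np.int64)

    # resolve kept faces through the stitched vertex set, compacting indices
    lengths = rlens[kept_r]
    good = lengths >= 3
    kept_r = kept_r[good]
    lengths = lengths[good]
    fpad, fmask = _pad(kept_r)
    flat = fpad[fmask]
    if (flat < 0).any():
        raise TessellationError("unbounded kept ridge; margin too small")
    used = np.unique(flat)
    roots = np.unique(root_of[used])
    compact = np.full(nvor, -1, dtype=np.int64)
    compact[roots] = np.arange(len(roots))
    verts = vor.vertices[roots].copy()

    flat_ids = compact[root_of[flat]]
    flat_shift = off_of[flat].astype(float) * L
    face_offsets = np.zeros(len(kept_r) + 1, dtype=np.int64)
    np.cumsum(lengths, out=face_offsets[1:])

    F = len(kept_r)
    c1 = p[kept_r]
    c2 = np.where(both[kept_r], q[kept_r], o[kept_r])
    pair_shift = np.where(keepimg[kept_r][:, None], S[kept_r].astype(float) * L, 0.0)

    # batch polygon ordering (counter-clockwise about the c1->c2 axis)
    mmax = int(lengths.max()) if F else 3
    P = np.zeros((F, mmax, 3))
    mask = np.arange(mmax)[None, :] < lengths[:, None]
    P[mask] = verts[flat_ids] + flat_shift
    cen = P.sum(axis=1) / lengths[:, None]
    axis = np.where((c2 >= 0)[:, None],
                    seeds[np.maximum(c2, 0)] + pair_shift - seeds[c1],
                    np.column_stack([np.zeros(F), np.zeros(F),
                                     np.where(c2 == WALL_BOTTOM, -1.0, 1.0)]))
    n = axis / np.linalg.norm(axis, axis=1, keepdims=True)
    ref = np.where((np.abs(n[:, 0]) > 0.9)[:, None],
                   np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n, e1)
    d = P - cen[:, None, :]
    ang = np.arctan2((d * e2[:, None, :]).sum(axis=2),
                     (d * e1[:, None, :]).sum(axis=2))
    ang[~mask] = np.inf
    order = np.argsort(ang, axis=1)

    ids_pad = np.full((F, mmax), -1, dtype=np.int64)
    ids_pad[mask] = flat_ids
    shf_pad = np.zeros((F, mmax, 3))
    shf_pad[mask] = flat_shift
    rows = np.arange(F)[:, None]
    ids_sorted = ids_pad[rows, order]
    shf_sorted = shf_pad[rows, order]
    face_vidx = ids_sorted[mask]
    face_shift = shf_sorted[mask]

    pinned = np.zeros(len(verts), dtype=bool)
    for wcode in (WALL_BOTTOM, WALL_TOP):
        wf = np.where(c2 == wcode)[0]
        for f in wf:
            pinned[face_vidx[face_offsets[f]:face_offsets[f + 1]]] = True
    return dict(
        verts=verts,
        pinned=pinned,
        face_offsets=face_offsets,
        face_vidx=face_vidx,
        face_shift=face_shift,
        face_cells=np.column_stack([c1, c2]).astype(np.int64),
        face_pair_shift=pair_shift,
    )


def tessellation_from_seeds(seeds, box, cell_ids, cell_type, V0, S0, alpha,
                            margin: float | None = None, max_retries: int = 3) -> Tessellation:
    """Periodic Voronoi tessellation of seed points carrying cell metadata.

    Confluence is audited after construction; an insufficient image margin is
    retried with a larger one, duplicate seeds are perturbed.
    """
    seeds = np.asarray(seeds, dtype=float)
    if margin is None:
        margin = 1.8 * (box.volume / max(len(seeds), 1)) ** (1.0 / 3.0)
    last = None
    for attempt in range(max_retries):
        try:
            mesh = _build_mesh(seeds, box, margin * (1.0 + 0.7 * attempt))
            tess = Tessellation(box=box, cell_ids=cell_ids, cell_type=cell_type,
                                seed=seeds, V0=V0, S0=S0, alpha=alpha, **mesh)
            defect = tess.confluence_defect()
            if defect > 1e-8:
                raise TessellationError(f"confluence defect {defect:.2e}")
            return tess
        except Exception as exc:  # qhull errors included
            last = exc
            if "duplicate" in str(exc).lower() or "qhull" in str(exc).lower():
                rng = np.random.default_rng(12345 + attempt)
                seeds = seeds + rng.normal(scale=1e-7, size=seeds.shape)
    raise TessellationError(f"tessellation failed after {max_retries} attempts: {last}")


def _layer_grid(n: int, aspect: float):
    """Factor n into (nx, ny) with nx/ny as close as possible to `aspect`."""
    best = None
    for nx in range(1, n + 1):
        if n % nx:
            continue
        ny = n // nx
        score = abs(np.log(nx / (ny * aspect)))
        if best is None or score < best[0]:
            best = (score, nx, ny)
    return best[1], best[2]


def build_initial_tissue(n_basal: int, n_suprabasal_layers: int = 2,
                         box_aspect: float = 1.0, jitter: float = 0.2,
                         seed: int = 0, s0_by_type: dict | None = None) -> Tessellation:
    """Layered slab tissue: basement, one basal monolayer, suprabasal layers, ghosts.

    Cell target volume is 1 (nondimensional length unit = cell size), so the box
    is ``nx x ny`` laterally with one unit of height per layer.  Seeds start on
    a cubic grid with uniform jitter; the bottom (and ceiling) wall vertices are
    pinned.
    """
    if n_basal < 4:
        raise ValueError("need at least 4 basal cells")
    if n_suprabasal_layers < 1:
        raise ValueError("need at least one suprabasal layer")
    from .mechanics import DEFAULT_S0  # late import to avoid cycle
    s0_by_type = s0_by_type or DEFAULT_S0
    nx, ny = _layer_grid(n_basal, box_aspect)
    n_layers = 2 + n_suprabasal_layers + 1  # basement + basal + supra + ghost
    box = PeriodicBox(Lx=float(nx), Ly=float(ny), z_min=0.0, z_max=float(n_layers))
    rng = np.random.default_rng(seed)
    layer_types = [BASEMENT, BASAL] + [SUPRABASAL] * n_suprabasal_layers + [GHOST]
    seeds = []
    types = []
    for li, t in enumerate(layer_types):
        gx, gy = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(),
                               np.full(nx * ny, li + 0.5)])
        if jitter > 0:
            pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
            pts[:, 2] = np.clip(pts[:, 2], li + 0.05, li + 0.95)
        seeds.append(pts)
        types.extend([t] * (nx * ny))
    seeds = np.concatenate(seeds)
    types = np.array(types, dtype=np.int64)
    n = len(seeds)
    V0 = np.ones(n)
    S0 = np.array([s0_by_type[TYPE_NAMES[t]] for t in types])
    alpha = np.zeros(n)
    last = None
    for attempt in range(5):
        try:
            return tessellation_from_seeds(seeds, box, np.arange(n), types, V0, S0, alpha)
        except TessellationError as exc:
            last = exc
            seeds = seeds + rng.normal(scale=1e-4, size=seeds.shape)
    raise TessellationError(f"initial tissue build failed: {last}")


def build_bulk_tissue(nx: int, ny: int, nz: int, jitter: float = 0.25,
                      seed: int = 0, s0: float = 5.8) -> Tessellation:
    """Fully periodic bulk tissue of identical cells (droplet rheometry substrate)."""
    box = PeriodicBox(Lx=float(nx), Ly=float(ny), z_min=0.0, z_max=float(nz),
                      periodic_z=True)
    rng = np.random.default_rng(seed)
    gx, gy, gz = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5,
                             np.arange(nz) + 0.5, indexing="ij")
    seeds = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if jitter > 0:
        seeds = seeds + rng.uniform(-jitter, jitter, size=seeds.shape)
    n = len(seeds)
    types = np.full(n, BASAL, dtype=np.int64)
    V0 = np.ones(n)
    S0 = np.full(n, s0)
    return tessellation_from_seeds(seeds, box, np.arange(n), types, V0, S0,
                                   np.zeros(n))


def retessellate(tess: Tessellation) -> Tessellation:
    """Rebuild topology from the periodic Voronoi diagram of current centroids.

    Cell identities, types, targets, and growth coefficients are preserved;
    seeds are refreshed to the current geometric centroids (wrapped into the
    box).  This is how neighbour exchanges (T1-equivalent moves) happen.
    """
    _, _, cen = tess.geometry()
    seeds = cen.copy()
    box = tess.box
    seeds[:, 0] %= box.Lx
    seeds[:, 1] %= box.Ly
    if box.periodic_z:
        seeds[:, 2] = box.z_min + (seeds[:, 2] - box.z_min) % box.Lz
    else:
        seeds[:, 2] = np.clip(seeds[:, 2], box.z_min + 1e-6, box.z_max - 1e-6)
    return tessellation_from_seeds(seeds, box, tess.cell_ids, tess.cell_type.copy(),
                                   tess.V0.copy(), tess.S0.copy(), tess.alpha.copy())


# ---------------------------------------------------------------------------
# Per-cell measurements
# ---------------------------------------------------------------------------

def cell_geometry(tess: Tessellation, cell_id: int):
    """(volume, surface_area, centroid) of one (non-ghost) cell."""
    i = tess.id_to_index[int(cell_id)]
    if tess.cell_type[i] == GHOST:
        raise ValueError("geometry of a ghost cell is not defined")
    vol, area, cen = tess.geometry()
    return float(vol[i]), float(area[i]), cen[i].copy()


def fit_ellipsoid(tess: Tessellation, cell_id: int, degeneracy_tol: float = 1e-3) -> EllipsoidFit:
    """Gyration-tensor ellipsoid fit of a cell's vertices.

    theta_long is the angle between the longest principal axis and the basal
    (x-y) plane, folded into [0, pi/2]; it is flagged degenerate when the two
    leading eigenvalues coincide within tolerance.
    """
    i = tess.id_to_index[int(cell_id)]
    pos = tess.cell_vertex_positions(i)
    if len(pos) < 4:
        raise ValueError("need at least 4 vertices")
    d = pos - pos.mean(axis=0)
    G = d.T @ d / len(d)
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    semi = np.sqrt(np.maximum(w, 0.0))
    nz = abs(v[2, 0])
    theta = float(np.arcsin(min(nz, 1.0)))
    degenerate = (w[0] - w[1]) <= degeneracy_tol * max(w[0], 1e-30)
    return EllipsoidFit(semi_axes=semi, principal_axes=v.T.copy(),
                        theta_long=theta, degenerate=degenerate)


def _cross_section_polygon(tess: Tessellation, index: int, z: float):
    """Intersection polygon of a cell with the horizontal plane at height z.

    Segment endpoints are collected from every face crossing the plane and
    ordered by angle about their mean (cells are near-convex).
    """
    pts = []
    for j in range(tess.cf_offsets[index], tess.cf_offsets[index + 1]):
        f = tess.cf_faces[j]
        side = tess.cf_side[j]
        b0, b1 = tess.face_offsets[f], tess.face_offsets[f + 1]
        P = tess.verts[tess.face_vidx[b0:b1]] + tess.face_shift[b0:b1]
        if side < 0:
            P = P - tess.face_pair_shift[f]
        m = len(P)
        for k in range(m):
            a, b = P[k], P[(k + 1) % m]
            da, db = a[2] - z, b[2] - z
            if da == 0.0 and db == 0.0:
                continue
            if (da < 0) != (db < 0):
                t = da / (da - db)
                pts.append(a + t * (b - a))
    if len(pts) < 3:
        return None
    pts = np.unique(np.round(np.array(pts), 9), axis=0)
    if len(pts) < 3:
        return None
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    return pts[np.argsort(ang)]


def shape_indices(tess: Tessellation, cell_id: int):
    """(s3d, s2d) observed shape indices.

    s3d = S V^(-2/3) of the polyhedron; s2d = P A^(-1/2) of the cross-section
    polygon in the plane parallel to the basement membrane through the cell
    centroid.  s2d is None when the section is empty or the cell is not basal.
    """
    i = tess.id_to_index[int(cell_id)]
    vol, area, cen = tess.geometry()
    s3d = float(area[i] * vol[i] ** (-2.0 / 3.0))
    s2d = None
    if tess.cell_type[i] == BASAL or tess.cell_type[i] == DROPLET:
        poly = _cross_section_polygon(tess, i, float(cen[i, 2]))
        if poly is not None:
            x, y = poly[:, 0], poly[:, 1]
            A = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
            Pm = np.sqrt(np.diff(np.vstack([poly, poly[:1]])[:, :2], axis=0) ** 2
                         @ np.ones(2)).sum()
            if A > 1e-12:
                s2d = float(Pm / np.sqrt(A))
    return s3d, s2d
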