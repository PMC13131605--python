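"""Geometry of the layered periodic tessellation: confluence, face pairing,
per-cell measurements, ellipsoid fits, and shape indices."""

import numpy as np
import pytest

from epivertex import tissue_geometry as tg


def test_build_layers_and_counts():
    tess = tg.build_initial_tissue(9, 2, jitter=0.15, seed=3)
    counts = {name: int((tess.cell_type == code).sum())
              for code, name in tg.TYPE_NAMES.items()}
    assert counts["basal"] == 9
    assert counts["basement"] == 9
    assert counts["suprabasal"] == 18
    assert counts["ghost"] == 9


def test_confluence_total_volume(tiny_tissue):
    # summed cell volumes tile the slab exactly
    assert tiny_tissue.confluence_defect() < 1e-6


def test_confluence_survives_vertex_motion(tiny_tissue, rng):
    # shared-face triangulation cancels interior contributions identically,
    # so confluence holds for any interior vertex displacement
    tess = tg.retessellate(tiny_tissue)
    tess.verts[~tess.pinned] += 0.05 * rng.standard_normal(
        tess.verts[~tess.pinned].shape)
    tess.invalidate()
    assert tess.confluence_defect() < 1e-6


def test_every_internal_face_shared_by_two_cells(small_tissue):
    fc = small_tissue.face_cells
    inner = fc[:, 1] >= 0
    assert (fc[inner, 0] != fc[inner, 1]).all()
    # adjacency audit: count faces per unordered cell pair; no pair repeats
    # with identical pair shift
    keys = set()
    for f in np.where(inner)[0]:
        key = (int(fc[f, 0]), int(fc[f, 1]),
               tuple(np.round(small_tissue.face_pair_shift[f], 6)))
        assert key not in keys
        keys.add(key)


def test_cells_close_into_polyhedra(small_tissue):
    # Euler characteristic V - E + F = 2 per cell (vertices keyed by position
    # in the cell's own frame, so periodic copies unify correctly)
    tess = small_tissue
    for i in range(tess.n_cells):
        j0, j1 = tess.cf_offsets[i], tess.cf_offsets[i + 1]
        nF = j1 - j0
        edges = set()
        verts = set()
        for j in range(j0, j1):
            f = tess.cf_faces[j]
            side = tess.cf_side[j]
            b0, b1 = tess.face_offsets[f], tess.face_offsets[f + 1]
            P = tess.verts[tess.face_vidx[b0:b1]] + tess.face_shift[b0:b1]
            if side < 0:
                P = P - tess.face_pair_shift[f]
            ring = [tuple(np.round(p, 6)) for p in P]
            for a, b in zip(ring, ring[1:] + ring[:1]):
                edges.add(frozenset((a, b)))
                verts.add(a)
        assert len(verts) - len(edges) + nF == 2


def test_periodicity_of_measures(tiny_tissue):
    # translating the whole tissue by one lattice vector changes nothing
    vol0, area0, _ = tiny_tissue.geometry()
    tess = tg.retessellate(tiny_tissue)
    tess.verts[:, 0] += tess.box.Lx
    tess.invalidate()
    vol1, area1, _ = tess.geometry()
    base_vol, base_area, _ = tg.retessellate(tiny_tissue).geometry()
    np.testing.assert_allclose(vol1, base_vol, rtol=1e-9)
    np.testing.assert_allclose(area1, base_area, rtol=1e-9)


def test_retessellation_preserves_identity_and_confluence(small_tissue):
    new = tg.retessellate(small_tissue)
    assert new.confluence_defect() < 1e-6
    np.testing.assert_array_equal(new.cell_ids, small_tissue.cell_ids)
    np.testing.assert_array_equal(new.cell_type, small_tissue.cell_type)
    np.testing.assert_allclose(new.V0, small_tissue.V0)


def test_retessellation_idempotent_at_fixed_seeds(small_tissue):
    # rebuilding from the same (generic, jittered) seeds is a fixed point of
    # the topology: the mesh IS the Voronoi diagram of its seeds
    t = small_tissue
    new = tg.tessellation_from_seeds(t.seed, t.box, t.cell_ids, t.cell_type,
                                     t.V0, t.S0, t.alpha)

    def signature(x):
        inner = x.face_cells[:, 1] >= 0
        return {(int(a), int(b)) for a, b in x.face_cells[inner]}

    assert signature(new) == signature(t)
    assert new.n_cells == t.n_cells


def test_jitter_zero_gives_equal_prisms():
    tess = tg.build_initial_tissue(9, 1, jitter=0.0, seed=0)
    vol, area, _ = tess.geometry()
    np.testing.assert_allclose(vol, 1.0, rtol=1e-9)


def test_cell_geometry_unit_prisms():
    tess = tg.build_initial_tissue(4, 1, jitter=0.0, seed=0)
    i = int(np.where(tess.cell_type == tg.BASAL)[0][0])
    v, s, c = tg.cell_geometry(tess, int(tess.cell_ids[i]))
    assert v == pytest.approx(1.0, rel=1e-9)
    assert s == pytest.approx(6.0, rel=1e-9)


def test_cell_geometry_matches_divergence_theorem_oracle(small_tissue):
    # independent quadrature: V = (1/3) sum_faces integral x.n dA over each
    # triangle, using an absolute origin (no centroid fan)
    tess = small_tissue
    cid = int(tess.cell_ids[np.where(tess.cell_type == tg.BASAL)[0][2]])
    i = tess.id_to_index[cid]
    vol_oracle = 0.0
    for j in range(tess.cf_offsets[i], tess.cf_offsets[i + 1]):
        f = tess.cf_faces[j]
        side = tess.cf_side[j]
        b0, b1 = tess.face_offsets[f], tess.face_offsets[f + 1]
        P = tess.verts[tess.face_vidx[b0:b1]] + tess.face_shift[b0:b1]
        if side < 0:
            P = P - tess.face_pair_shift[f]
        fc = P.mean(axis=0)
        m = len(P)
        for k in range(m):
            a, b = P[k], P[(k + 1) % m]
            n = np.cross(a - fc, b - fc) * side
            vol_oracle += np.dot(fc + a + b, n) / 18.0
    v, _, _ = tg.cell_geometry(tess, cid)
    assert abs(v - vol_oracle) < 1e-10


def test_ghost_cell_geometry_rejected(tiny_tissue):
    gid = int(tiny_tissue.cell_ids[np.where(tiny_tissue.cell_type == tg.GHOST)[0][0]])
    with pytest.raises(ValueError):
        tg.cell_geometry(tiny_tissue, gid)


def test_fit_ellipsoid_z_stretched_prism():
    tess = tg.build_initial_tissue(4, 1, jitter=0.0, seed=0)
    i = int(np.where(tess.cell_type == tg.BASAL)[0][0])
    cid = int(tess.cell_ids[i])
    # stretching z (the non-periodic axis) elongates the prisms vertically
    tess.verts[:, 2] *= 2.0
    tess.invalidate()
    fit = tg.fit_ellipsoid(tess, cid)
    assert not fit.degenerate
    assert fit.theta_long == pytest.approx(np.pi / 2, abs=1e-6)


def test_fit_ellipsoid_x_elongated_prism():
    # corner cloud of a 2 x 1 x 1 cuboid: long axis in the basal plane
    corners = np.array([[x, y, z] for x in (0, 2.0) for y in (0, 1.0)
                        for z in (0, 1.0)])

    class FakeTess:
        id_to_index = {0: 0}

        def cell_vertex_positions(self, index):
            return corners

    fit = tg.fit_ellipsoid(FakeTess(), 0)
    assert not fit.degenerate
    assert fit.theta_long == pytest.approx(0.0, abs=1e-9)


def test_fit_ellipsoid_constructed_cloud():
    # ellipsoidal point cloud, axes (3,2,1), long axis tilted 30 deg from plane
    rng = np.random.default_rng(5)
    n = 4000
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = u * np.array([3.0, 2.0, 1.0])
    th = np.pi / 6
    R = np.array([[np.cos(th), 0, -np.sin(th)], [0, 1, 0],
                  [np.sin(th), 0, np.cos(th)]])
    pts = pts @ R.T

    class FakeTess:
        id_to_index = {0: 0}

        def cell_vertex_positions(self, index):
            return pts

    fit = tg.fit_ellipsoid(FakeTess(), 0)
    assert fit.theta_long == pytest.approx(np.pi / 6, abs=1e-2)
    assert fit.semi_axes[0] > fit.semi_axes[1] > fit.semi_axes[2]


def test_shape_indices_cube_limits():
    tess = tg.build_initial_tissue(4, 1, jitter=0.0, seed=0)
    cid = int(tess.cell_ids[np.where(tess.cell_type == tg.BASAL)[0][0]])
    s3d, s2d = tg.shape_indices(tess, cid)
    assert s3d == pytest.approx(6.0, rel=1e-9)       # unit cube
    assert s2d == pytest.approx(4.0, rel=1e-9)       # unit-square section
    # reference limits for sphere and circle
    assert (36 * np.pi) ** (1 / 3) == pytest.approx(4.836, abs=1e-3)
    assert 2 * np.sqrt(np.pi) == pytest.approx(3.545, abs=1e-3)


def test_minimal_image_bounds(rng):
    box = tg.PeriodicBox(Lx=4.0, Ly=6.0, z_min=0.0, z_max=3.0)
    d = rng.uniform(-20, 20, size=(500, 3))
    m = box.minimal_image(d)
    assert (np.abs(m[:, 0]) <= 2.0 + 1e-12).all()
    assert (np.abs(m[:, 1]) <= 3.0 + 1e-12).all()
    np.testing.assert_allclose(m[:, 2], d[:, 2])
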