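"""Shape-based vertex-model energetics and overdamped Langevin dynamics.

The energy of the tissue is

    E = sum_cells K_V (V - V0)^2 + sum_cells K_S (S - S0)^2
        + sum_{heterotypic faces} sigma_ij A_face

where V, S are the polyhedral volume and surface area of each non-ghost cell
and sigma_ij is an extra interfacial tension on faces shared by cells of
different types (basal-suprabasal contractility, basal-basement wetting,
droplet-tissue tension).  Ghost cells contribute to none of the three sums.

Vertices evolve by Euler-Maruyama integration of

    dr_i = mu F_i dt + sqrt(2 D_t dt) xi

with F_i = -grad_i E (analytic) and xi standard normal per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import tissue_geometry as tg
from ._kernels import forces_kernel

#: default target shape indices per cell type; the basal value is the
#: reference s0_ref from which the stage stiffness shift delta_s is subtracted
#: (5.40 sits near the 3D rigidity transition of this model family).
S0_REF_BASAL = 5.40
DEFAULT_S0 = {
    "basement": 5.40,
    "basal": S0_REF_BASAL,
    "suprabasal": 5.50,
    "ghost": 5.40,      # placeholder only; ghosts carry no energy
    "droplet": 5.80,
}


@dataclass
class StageParams:
    """Stage triplet: heterotypic tension sigma_a (basal-suprabasal), wetting
    tension sigma_b (basal-basement), and basal stiffness shift delta_s."""

    sigma_a: float
    sigma_b: float
    delta_s: float

    @classmethod
    def preset(cls, name: str) -> "StageParams":
        presets = {
            "E14": cls(0.044, 0.062, 0.0),
            "E16": cls(0.116, 0.067, 0.14),
        }
        try:
            return presets[name.upper()]
        except KeyError:
            raise ValueError(f"unknown stage preset {name!r}; know {sorted(presets)}")


@dataclass
class MechanicalParams:
    """Moduli, mobilities, and the tension matrix over unordered type pairs."""

    K_V: float = 1.0
    K_S: float = 1.0
    mu: float = 1.0
    D_t: float = 0.02
    dt: float = 0.01
    tol: float = 1e-3
    s0: dict = field(default_factory=lambda: dict(DEFAULT_S0))
    sigma: dict = field(default_factory=dict)  # {frozenset({type_a, type_b}): value}

    def sigma_matrix(self) -> np.ndarray:
        M = np.zeros((5, 5))
        for pair, val in self.sigma.items():
            a, b = sorted(tg.TYPE_CODES[t] for t in pair)
            M[a, b] = M[b, a] = val
        return M

    def copy(self) -> "MechanicalParams":
        return replace(self, s0=dict(self.s0), sigma=dict(self.sigma))


def stage_to_params(stage: StageParams | str,
                    base: MechanicalParams | None = None) -> MechanicalParams:
    """Fold a developmental-stage triplet into mechanical parameters.

    sigma_a is placed on basal-suprabasal interfaces, sigma_b on
    basal-basement interfaces, and delta_s lowers the basal target shape index
    from the reference (stiffening the basal layer).
    """
    if isinstance(stage, str):
        stage = StageParams.preset(stage)
    params = (base or MechanicalParams()).copy()
    params.sigma[frozenset({"basal", "suprabasal"})] = stage.sigma_a
    params.sigma[frozenset({"basal", "basement"})] = stage.sigma_b
    s0_basal = params.s0.get("basal", S0_REF_BASAL) - stage.delta_s
    if s0_basal <= 0:
        raise ValueError("delta_s produces a negative basal target shape index")
    params = params.copy()
    params.s0["basal"] = s0_basal
    return params


def _face_sigma(tess: tg.Tessellation, params: MechanicalParams) -> np.ndarray:
    """Per-face heterotypic tension; zero for homotypic, wall, and ghost faces."""
    M = params.sigma_matrix()
    c1 = tess.face_cells[:, 0]
    c2 = tess.face_cells[:, 1]
    t1 = tess.cell_type[c1]
    out = np.zeros(len(c1))
    inner = c2 >= 0
    t2 = tess.cell_type[c2[inner]]
    sig = M[t1[inner], t2]
    ghost = (t1[inner] == tg.GHOST) | (t2 == tg.GHOST)
    sig[ghost] = 0.0
    out[inner] = sig
    return out


def _active(tess: tg.Tessellation) -> np.ndarray:
    return tess.cell_type != tg.GHOST


def energy_and_forces(tess: tg.Tessellation, params: MechanicalParams):
    """(E, F) with F = -grad E per vertex; pinned vertices get zero force."""
    E, grad = forces_kernel(
        tess.verts, tess.face_offsets, tess.face_vidx, tess.face_shift,
        tess.face_cells, tess.face_pair_shift,
        tess.cf_offsets, tess.cf_faces, tess.cf_side, tess.seed,
        tess.V0, tess.S0, _active(tess), _face_sigma(tess, params),
        params.K_V, params.K_S,
    )
    if not np.isfinite(grad).all():
        bad = np.where(~np.isfinite(grad).all(axis=1))[0]
        raise FloatingPointError(f"non-finite force at vertices {bad[:5]}")
    F = -grad
    F[tess.pinned] = 0.0
    return float(E), F


def energy(tess: tg.Tessellation, params: MechanicalParams) -> float:
    vol, area, _ = tess.geometry()
    act = _active(tess)
    dv = (vol - tess.V0)[act]
    ds = (area - tess.S0)[act]
    het = _face_sigma(tess, params)
    E = params.K_V * (dv @ dv) + params.K_S * (ds @ ds)
    nz = het != 0
    if nz.any():
        E += float(het[nz] @ tess.face_areas()[nz])
    return float(E)


def forces(tess: tg.Tessellation, params: MechanicalParams) -> np.ndarray:
    return energy_and_forces(tess, params)[1]


def langevin_step(tess: tg.Tessellation, params: MechanicalParams,
                  rng: np.random.Generator,
                  external_force: np.ndarray | None = None,
                  max_disp: float = 0.5) -> None:
    """One Euler-Maruyama step, in place.  Pinned vertices do not move."""
    _, F = energy_and_forces(tess, params)
    if external_force is not None:
        F = F + external_force
        F[tess.pinned] = 0.0
    disp = params.mu * F * params.dt
    if params.D_t > 0:
        noise = np.sqrt(2.0 * params.D_t * params.dt) * rng.standard_normal(F.shape)
        noise[tess.pinned] = 0.0
        disp = disp + noise
    step = np.abs(disp).max() if len(disp) else 0.0
    if step > max_disp:
        raise FloatingPointError(
            f"vertex displacement {step:.3g} exceeds {max_disp}; step exploded")
    tess.verts += disp
    tess.invalidate()


def minimize(tess: tg.Tessellation, params: MechanicalParams,
             tol: float | None = None, max_iter: int = 2000) -> dict:
    """Noise-free relaxation by FIRE (fast inertial relaxation engine), in place.

    Stops when the largest force component falls below `tol`, returning the
    final energy, residual, and iteration count.  Hitting the iteration cap
    returns the best state found with ``converged=False``.
    """
    tol = params.tol if tol is None else tol
    dt = params.dt
    dt_max = 10.0 * dt
    a_start, f_inc, f_dec, f_a, n_min = 0.1, 1.1, 0.5, 0.99, 5
    a = a_start
    n_good = 0
    v = np.zeros_like(tess.verts)
    _, F = energy_and_forces(tess, params)
    res = np.abs(F).max() if len(F) else 0.0
    it = 0
    while res > tol and it < max_iter:
        P = float((F * v).sum())
        if P > 0:
            n_good += 1
            vn = np.linalg.norm(v)
            fn = np.linalg.norm(F)
            if fn > 0:
                v = (1.0 - a) * v + a * vn * F / fn
            if n_good > n_min:
                dt = min(dt * f_inc, dt_max)
                a *= f_a
        else:
            v[:] = 0.0
            dt *= f_dec
            a = a_start
            n_good = 0
        v = v + dt * F
        disp = dt * v
        mx = np.abs(disp).max()
        if mx > 0.2:  # cap single-iteration motion at a fraction of a cell
            disp *= 0.2 / mx
        tess.verts += disp
        tess.invalidate()
        _, F = energy_and_forces(tess, params)
        res = np.abs(F).max() if len(F) else 0.0
        it += 1
    return {"energy": energy(tess, params), "residual": float(res),
            "iterations": it, "converged": bool(res <= tol)}
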