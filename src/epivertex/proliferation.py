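"""Growth, division scheduling, oriented cell division, and rate conversions.

One basal cell at a time carries a non-zero volume growth coefficient alpha;
its target volume increases as V0 <- V0 + alpha*dt.  Every division interval
t_div the designated growing cell is replaced by two daughter Voronoi seeds
displaced along the prescribed mitotic axis

    n = (cos(theta) cos(phi), cos(theta) sin(phi), sin(theta))

where theta is measured from the basal plane (theta=0: in-plane/symmetric
division, theta=pi/2: perpendicular/asymmetric).  The full tessellation is
recomputed, daughter target volumes split the parent's conserved V0, both
daughters inherit the basal identity, and the energy is re-minimized before
dynamics resume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tissue_geometry as tg
from . import mechanics as mech

#: minutes per simulation time unit, calibrated against droplet rheometry
TAU_MINUTES = 0.1
#: simulation time units per estimated day at tau = 0.1 min
TAU_PER_DAY = 24 * 60 / TAU_MINUTES  # = 14400


@dataclass
class DivisionSpec:
    """Mitotic-axis prescription and division timing."""

    theta: float                 # division-plane angle to basal plane, [0, pi/2]
    phi: float = 0.0             # azimuth (rotationally symmetric; 0 w.l.o.g.)
    t_div: float = 200.0         # division interval in tau
    ell_sep: float = 0.3         # daughter-seed separation (units of V0^(1/3))

    def __post_init__(self):
        if not 0.0 <= self.theta <= np.pi / 2 + 1e-12:
            raise ValueError("theta must lie in [0, pi/2]")
        if self.t_div <= 0:
            raise ValueError("t_div must be positive")

    @property
    def axis(self) -> np.ndarray:
        ct = np.cos(self.theta)
        return np.array([ct * np.cos(self.phi), ct * np.sin(self.phi),
                         np.sin(self.theta)])


@dataclass
class DivisionEvent:
    t0: float
    parent: int
    d1: int
    d2: int
    theta: float
    phi: float
    pos_d1: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pos_d2: np.ndarray = field(default_factory=lambda: np.zeros(3))


def ensure_growing_cell(tess: tg.Tessellation, rng: np.random.Generator,
                        alpha: float) -> int:
    """Guarantee exactly one basal cell grows; returns its cell id.

    If no basal cell currently has alpha > 0 (fresh tissue, or the designated
    grower just stratified or divided), one is drawn uniformly at random.
    """
    basal = np.where(tess.cell_type == tg.BASAL)[0]
    if len(basal) == 0:
        raise RuntimeError("tissue collapsed: no basal cells left")
    growing = basal[tess.alpha[basal] > 0]
    if len(growing) == 1:
        return int(tess.cell_ids[growing[0]])
    tess.alpha[:] = 0.0
    pick = basal[rng.integers(len(basal))]
    tess.alpha[pick] = alpha
    return int(tess.cell_ids[pick])


def grow_step(tess: tg.Tessellation, dt: float, params: mech.MechanicalParams) -> None:
    """Advance target volumes of growing cells by alpha*dt, keeping s0 fixed."""
    growing = np.where(tess.alpha > 0)[0]
    for i in growing:
        tess.V0[i] += tess.alpha[i] * dt
        s0 = params.s0[tg.TYPE_NAMES[int(tess.cell_type[i])]]
        tess.S0[i] = s0 * tess.V0[i] ** (2.0 / 3.0)


def divide_cell(tess: tg.Tessellation, cell_id: int, spec: DivisionSpec,
                params: mech.MechanicalParams,
                minimize_tol: float | None = None):
    """Replace one basal cell by two daughter seeds along the mitotic axis.

    Returns (new_tessellation, DivisionEvent).  The parent's target volume is
    split equally between the daughters (conserved exactly); both daughters
    are basal; the energy is re-minimized before dynamics resume.
    """
    i = tess.id_to_index[int(cell_id)]
    if tess.cell_type[i] != tg.BASAL:
        raise ValueError("only basal cells divide")
    vol, _, cen = tess.geometry()
    box = tess.box
    n_hat = spec.axis
    half = 0.5 * spec.ell_sep * tess.V0[i] ** (1.0 / 3.0)
    p1 = cen[i] + half * n_hat
    p2 = cen[i] - half * n_hat
    if not box.periodic_z:
        lo, hi = box.z_min + 1e-6, box.z_max - 1e-6
        p1[2] = np.clip(p1[2], lo, hi)
        p2[2] = np.clip(p2[2], lo, hi)

    keep = np.ones(tess.n_cells, dtype=bool)
    keep[i] = False
    _, _, cen_all = tess.geometry()
    seeds = np.vstack([cen_all[keep], p1, p2])
    seeds[:, 0] %= box.Lx
    seeds[:, 1] %= box.Ly
    if box.periodic_z:
        seeds[:, 2] = box.z_min + (seeds[:, 2] - box.z_min) % box.Lz
    else:
        seeds[:, 2] = np.clip(seeds[:, 2], box.z_min + 1e-6, box.z_max - 1e-6)

    next_id = int(tess.cell_ids.max()) + 1
    d1, d2 = next_id, next_id + 1
    ids = np.concatenate([tess.cell_ids[keep], [d1, d2]])
    types = np.concatenate([tess.cell_type[keep], [tg.BASAL, tg.BASAL]])
    V0d = 0.5 * tess.V0[i]
    s0_basal = params.s0["basal"]
    S0d = s0_basal * V0d ** (2.0 / 3.0)
    V0 = np.concatenate([tess.V0[keep], [V0d, V0d]])
    S0 = np.concatenate([tess.S0[keep], [S0d, S0d]])
    alpha = np.concatenate([tess.alpha[keep], [0.0, 0.0]])

    new = tg.tessellation_from_seeds(seeds, box, ids, types, V0, S0, alpha)
    mech.minimize(new, params, tol=minimize_tol, max_iter=200)
    _, _, cen_new = new.geometry()
    event = DivisionEvent(
        t0=np.nan, parent=int(cell_id), d1=d1, d2=d2,
        theta=spec.theta, phi=spec.phi,
        pos_d1=cen_new[new.id_to_index[d1]].copy(),
        pos_d2=cen_new[new.id_to_index[d2]].copy(),
    )
    return new, event


class DivisionScheduler:
    """Fires exactly once per division interval, on the time step closest to
    each multiple of t_div; never twice in one step."""

    def __init__(self, t_div: float, dt: float):
        if t_div < dt:
            raise ValueError("t_div must be at least one time step")
        self.n = max(1, int(round(t_div / dt)))

    def due(self, step: int) -> bool:
        return step > 0 and step % self.n == 0


def rate_conversions(n_basal: int, t_div: float,
                     tau_minutes: float = TAU_MINUTES):
    """(lambda_sim, lambda_per_day): division rate per basal cell.

    lambda_sim is in divisions per cell per tau; lambda_per_day uses the
    tau = 0.1 min calibration (1 estimated day = 14400 tau).
    """
    if n_basal <= 0 or t_div <= 0 or tau_minutes <= 0:
        raise ValueError("all inputs must be positive")
    lam_sim = 1.0 / (n_basal * t_div)
    tau_per_day = 24 * 60 / tau_minutes
    return lam_sim, tau_per_day / (n_basal * t_div)


def t_div_for_rate(n_basal: int, lam_per_day: float) -> float:
    """Division interval (tau) realizing a physical rate in divisions/cell/day."""
    return TAU_PER_DAY / (n_basal * lam_per_day)


def kv_speed_conversion(speed_um_per_min: float = 0.55,
                        cell_size_um: float = 10.0,
                        tau_minutes: float = TAU_MINUTES):
    """(speed in l/min, speed in l/tau) for a characteristic migration speed.

    The reference point is the Kupffer's-vesicle speed 0.55 um/min with a
    typical cell size l = 10 um: 0.055 l/min, i.e. 0.0055 l/tau at
    tau = 0.1 min.
    """
    per_min = speed_um_per_min / cell_size_um
    return per_min, per_min * tau_minutes
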