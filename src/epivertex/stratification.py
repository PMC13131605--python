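"""Stratification detection, density homeostasis, and event bookkeeping.

Two routes move basal cells into the suprabasal compartment:

* homotypic (spontaneous) stratification -- a basal cell whose centroid has
  risen above the basal-suprabasal (BS) interface and which no longer touches
  the basement membrane instantly adopts suprabasal mechanical parameters
  (counted in N_homo);
* fate conversion -- under the homeostatic protocol, whenever the basal count
  exceeds its initial reference by more than two cells at a periodic check
  (interval t_pop), one uniformly random basal cell switches identity
  (counted in N_fate).

Each basal-to-suprabasal transition is paired with conversion of the top-most
suprabasal cell into a ghost placeholder, keeping the non-ghost tissue at
quasi-steady thickness while material fluxes upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tissue_geometry as tg
from . import mechanics as mech

HOMEOSTATIC = "homeostatic"
DENSIFYING = "densifying"


@dataclass
class EventLog:
    """Stratification/division records and the N_homo / N_fate / N_div counters."""

    protocol: str = HOMEOSTATIC
    t_pop: float = 100.0
    n_basal_ref: int = 0
    events: list = field(default_factory=list)   # dicts {time, cell, kind, ...}
    divisions: list = field(default_factory=list)  # DivisionEvent
    N_homo: int = 0
    N_fate: int = 0
    N_div: int = 0

    def record(self, time: float, cell: int, kind: str, **ctx):
        self.events.append({"time": time, "cell": int(cell), "kind": kind, **ctx})
        if kind == "homotypic":
            self.N_homo += 1
        elif kind == "fate":
            self.N_fate += 1

    def events_frame(self):
        import pandas as pd
        return pd.DataFrame(self.events)

    def divisions_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"t0": e.t0, "parent": e.parent, "d1": e.d1, "d2": e.d2,
              "theta": e.theta, "phi": e.phi} for e in self.divisions])


def compute_bs_interface(tess: tg.Tessellation) -> float:
    """Mean z of centroids of all faces shared between basal and suprabasal cells."""
    c1 = tess.face_cells[:, 0]
    c2 = tess.face_cells[:, 1]
    inner = c2 >= 0
    t1 = tess.cell_type[c1[inner]]
    t2 = tess.cell_type[c2[inner]]
    bs = ((t1 == tg.BASAL) & (t2 == tg.SUPRABASAL)) | \
         ((t1 == tg.SUPRABASAL) & (t2 == tg.BASAL))
    faces = np.where(inner)[0][bs]
    if len(faces) == 0:
        raise RuntimeError("no basal-suprabasal interface faces")
    zs = np.empty(len(faces))
    for k, f in enumerate(faces):
        b0, b1 = tess.face_offsets[f], tess.face_offsets[f + 1]
        zs[k] = (tess.verts[tess.face_vidx[b0:b1], 2]
                 + tess.face_shift[b0:b1, 2]).mean()
    return float(zs.mean())


def _touches_basement(tess: tg.Tessellation, index: int) -> bool:
    for j in range(tess.cf_offsets[index], tess.cf_offsets[index + 1]):
        f = tess.cf_faces[j]
        c1, c2 = tess.face_cells[f]
        other = c2 if c1 == index else c1
        if other >= 0 and tess.cell_type[other] == tg.BASEMENT:
            return True
    return False


def detect_homotypic(tess: tg.Tessellation, params: mech.MechanicalParams,
                     interface: float, log: EventLog, time: float,
                     recent_daughters: set | None = None) -> list[int]:
    """Detect and execute spontaneous stratification of basal cells.

    A basal cell stratifies when its centroid lies above the BS interface AND
    it no longer contacts the basement membrane; its parameters are switched
    to suprabasal instantly.  Returns the stratified cell ids.
    """
    _, _, cen = tess.geometry()
    out = []
    for i in np.where(tess.cell_type == tg.BASAL)[0]:
        if cen[i, 2] <= interface or _touches_basement(tess, i):
            continue
        tess.set_type(i, tg.SUPRABASAL, s0=params.s0["suprabasal"])
        tess.alpha[i] = 0.0
        cid = int(tess.cell_ids[i])
        trigger = "daughter" if recent_daughters and cid in recent_daughters \
            else "neighbor"
        log.record(time, cid, "homotypic", trigger=trigger,
                   n_basal=int((tess.cell_type == tg.BASAL).sum()))
        out.append(cid)
    return out


def homeostatic_check(tess: tg.Tessellation, params: mech.MechanicalParams,
                      log: EventLog, rng: np.random.Generator,
                      time: float) -> int | None:
    """Fate-convert one random basal cell when the basal count has expanded by
    more than two over the initial reference.  No spatial bias."""
    if log.protocol != HOMEOSTATIC:
        return None
    basal = np.where(tess.cell_type == tg.BASAL)[0]
    if len(basal) - log.n_basal_ref <= 2:
        return None
    pick = basal[rng.integers(len(basal))]
    tess.set_type(pick, tg.SUPRABASAL, s0=params.s0["suprabasal"])
    tess.alpha[pick] = 0.0
    cid = int(tess.cell_ids[pick])
    log.record(time, cid, "fate", n_basal=int(len(basal) - 1))
    return cid


def ghost_convert_top(tess: tg.Tessellation, exclude: set | None = None) -> int:
    """Convert the top-most suprabasal cell (largest centroid z) to a ghost.

    ``exclude`` protects cells converted in this same step (e.g. a freshly
    stratified cell should not immediately become the ghost).  Ties break by
    cell id.  Returns the converted cell id.
    """
    _, _, cen = tess.geometry()
    supra = np.where(tess.cell_type == tg.SUPRABASAL)[0]
    if exclude:
        supra = np.array([i for i in supra if int(tess.cell_ids[i]) not in exclude],
                         dtype=np.int64)
    if len(supra) == 0:
        raise RuntimeError("no suprabasal cell available for ghost conversion")
    order = np.lexsort((tess.cell_ids[supra], -cen[supra, 2]))
    top = supra[order[0]]
    tess.set_type(top, tg.GHOST)
    return int(tess.cell_ids[top])


def stratification_yield(log: EventLog):
    """(N_homo/N_div, N_fate/N_div); None when no division has occurred."""
    if log.N_div == 0:
        return None
    return log.N_homo / log.N_div, log.N_fate / log.N_div
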